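"""Synthetic multi-dataset expression generator with known ground truth.

Emulates the structure the prioritisation method exploits: donor-repeated
samples (a per-gene donor random effect shared by all of a donor's samples),
latent co-expression modules that may be active only in chosen developmental
periods, dataset-wide unwanted factors loading on every gene including the
housekeeping controls, and Gaussian noise. For a gene g and sample i of
donor d(i),

    x_gi = mu_g + delta_{g,d(i)} + sum_m lambda_gm f_mi 1[m active in period_i]
           + sum_u beta_gu u_ui + eps_gi

with f, u, eps standard-normal-based. With equal loadings lambda and an
always-active module, the theoretical intra-module correlation is
lambda^2 / (lambda^2 + sigma^2 + tau^2) where sigma is the noise sd and tau
the donor-effect sd; :func:`loading_for_correlation` inverts this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import ExpressionDataset, assign_period

__all__ = [
    "ModuleSpec",
    "SimulationConfig",
    "GroundTruth",
    "loading_for_correlation",
    "simulate_datasets",
    "simulate_null",
]

# representative age sampled uniformly within each period's interval
_PERIOD_AGE = {
    1: (4.0, 8.0, "PCW"),
    2: (8.0, 10.0, "PCW"),
    3: (10.0, 13.0, "PCW"),
    4: (13.0, 16.0, "PCW"),
    5: (16.0, 19.0, "PCW"),
    6: (19.0, 24.0, "PCW"),
    7: (24.0, 38.0, "PCW"),
    8: (0.0, 6.0, "M"),
    9: (6.0, 12.0, "M"),
    10: (1.0, 6.0, "Y"),
    11: (6.0, 12.0, "Y"),
    12: (12.0, 20.0, "Y"),
    13: (20.0, 40.0, "Y"),
    14: (40.0, 60.0, "Y"),
    15: (60.0, 90.0, "Y"),
}


def loading_for_correlation(
    r: float, noise_sd: float = 1.0, donor_sd: float | None = None
) -> float:
    """Equal module loading giving theoretical intra-module correlation ``r``.

    Solves r = lambda^2 / (lambda^2 + sigma^2 + tau^2). ``donor_sd`` defaults
    to the generator's default sqrt(0.1)·noise_sd.
    """
    if not 0 < r < 1:
        raise ValueError("r must be in (0, 1)")
    tau = math.sqrt(0.1) * noise_sd if donor_sd is None else donor_sd
    resid = noise_sd**2 + tau**2
    return math.sqrt(r / (1.0 - r) * resid)


@dataclass(frozen=True)
class ModuleSpec:
    """One latent co-expression module.

    ``genes`` are indices into the simulated gene list; ``loading`` is a
    single equal loading or one loading per gene; ``active_periods`` limits
    the module's factor to samples in those developmental periods (None =
    active everywhere).
    """

    genes: tuple[int, ...]
    loading: float | tuple[float, ...] = 1.0
    active_periods: frozenset[int] | None = None

    def loadings(self) -> np.ndarray:
        lam = self.loading
        if np.isscalar(lam):
            return np.full(len(self.genes), float(lam))
        lam = np.asarray(lam, dtype=float)
        if lam.size != len(self.genes):
            raise ValueError("one loading per module gene required")
        return lam


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for the generator.

    Defaults emulate a moderate multi-dataset design: 3 datasets of 1000
    genes × 120 samples, donors contributing 1–4 samples each, unit noise sd,
    a donor-effect variance of 0.1·sigma^2, 10% housekeeping genes, and
    sample ages spread over all 15 developmental periods.
    """

    n_datasets: int = 3
    n_genes: int = 1000
    n_samples: int = 120
    donor_sizes: tuple[int, ...] = (1, 1, 2, 4)
    modules: tuple[ModuleSpec, ...] = ()
    n_unwanted: int = 0
    unwanted_sd: float = 1.0
    noise_sd: float = 1.0
    donor_sd: float | None = None  # default sqrt(0.1) * noise_sd
    housekeeping_fraction: float = 0.1
    period_probs: dict[int, float] | None = None  # default uniform over 1..15
    baseline_mean: float = 8.0
    seed: int = 0

    def resolved_donor_sd(self) -> float:
        return math.sqrt(0.1) * self.noise_sd if self.donor_sd is None else self.donor_sd

    def gene_names(self) -> list[str]:
        n_hk = int(round(self.housekeeping_fraction * self.n_genes))
        n_reg = self.n_genes - n_hk
        return [f"G{i:05d}" for i in range(n_reg)] + [f"HK{i:04d}" for i in range(n_hk)]

    def housekeeping_genes(self) -> list[str]:
        return [g for g in self.gene_names() if g.startswith("HK")]

    def validate(self) -> None:
        if self.n_datasets < 1 or self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("n_datasets, n_genes and n_samples must be positive")
        if not self.donor_sizes or any(s < 1 for s in self.donor_sizes):
            raise ValueError("donor_sizes must be positive integers")
        if self.noise_sd <= 0 or self.unwanted_sd < 0:
            raise ValueError("noise_sd must be positive, unwanted_sd non-negative")
        if not 0 <= self.housekeeping_fraction < 1:
            raise ValueError("housekeeping_fraction must be in [0, 1)")
        n_hk = int(round(self.housekeeping_fraction * self.n_genes))
        hk_start = self.n_genes - n_hk
        for m in self.modules:
            if any(not 0 <= g < self.n_genes for g in m.genes):
                raise ValueError("module gene index out of range")
            if any(g >= hk_start for g in m.genes):
                raise ValueError("module genes may not overlap housekeeping controls")
            m.loadings()  # dimension check
        if self.period_probs is not None:
            if not set(self.period_probs) <= set(range(1, 16)):
                raise ValueError("period_probs keys must be periods 1..15")
            if abs(sum(self.period_probs.values()) - 1.0) > 1e-8:
                raise ValueError("period_probs must sum to 1")


@dataclass
class GroundTruth:
    """What the generator knows: module membership, loadings and implied correlations."""

    config: SimulationConfig
    genes: list[str]
    housekeeping: list[str]
    loadings: pd.DataFrame  # genes × modules
    module_genes: list[list[str]]

    def expected_correlation(self, genes: Iterable[str] | None = None) -> pd.DataFrame:
        """Implied biological (module-driven) correlation matrix.

        Assumes modules are active in every included sample; period-limited
        modules are attenuated in mixed-period data and this matrix then
        overstates their correlation.
        """
        sel = list(genes) if genes is not None else self.genes
        L = self.loadings.loc[sel].to_numpy(dtype=float)
        resid = self.config.noise_sd**2 + self.config.resolved_donor_sd() ** 2
        cov = L @ L.T + resid * np.eye(len(sel))
        d = np.sqrt(np.diag(cov))
        return pd.DataFrame(cov / np.outer(d, d), index=sel, columns=sel)


def _donor_blocks(
    n_samples: int, donor_sizes: Sequence[int], rng: np.random.Generator
) -> np.ndarray:
    """Per-sample donor index; block sizes drawn uniformly from donor_sizes."""
    donor_of = np.empty(n_samples, dtype=np.intp)
    i = donor = 0
    while i < n_samples:
        size = int(rng.choice(donor_sizes))
        size = min(size, n_samples - i)
        donor_of[i : i + size] = donor
        i += size
        donor += 1
    return donor_of


def _sample_meta(
    config: SimulationConfig, rng: np.random.Generator, name: str
) -> pd.DataFrame:
    donor_of = _donor_blocks(config.n_samples, config.donor_sizes, rng)
    if config.period_probs is None:
        periods_avail = np.arange(1, 16)
        probs = np.full(15, 1 / 15)
    else:
        periods_avail = np.array(sorted(config.period_probs))
        probs = np.array([config.period_probs[p] for p in periods_avail])
    # a donor has one age: draw per donor, broadcast to samples
    n_donors = donor_of.max() + 1
    donor_period = rng.choice(periods_avail, size=n_donors, p=probs)
    rows = []
    for i in range(config.n_samples):
        p = int(donor_period[donor_of[i]])
        lo, hi, unit = _PERIOD_AGE[p]
        age = float(lo + (hi - lo) * rng.random())
        rows.append(
            {
                "sample_id": f"{name}_s{i:03d}",
                "donor_id": f"{name}_d{donor_of[i]:03d}",
                "age_value": round(age, 3),
                "age_unit": unit,
            }
        )
    meta = pd.DataFrame(rows).set_index("sample_id")
    meta["period"] = [
        assign_period(v, u) for v, u in zip(meta["age_value"], meta["age_unit"])
    ]
    return meta


def _simulate_one(
    config: SimulationConfig,
    rng: np.random.Generator,
    name: str,
    beta: np.ndarray | None = None,
) -> ExpressionDataset:
    meta = _sample_meta(config, rng, name)
    genes = config.gene_names()
    n_g, n_s = config.n_genes, config.n_samples
    donor_codes = meta["donor_id"].astype("category").cat.codes.to_numpy()
    n_donors = donor_codes.max() + 1

    mu = rng.normal(config.baseline_mean, 1.0, size=n_g)
    X = np.tile(mu[:, None], (1, n_s))

    tau = config.resolved_donor_sd()
    if tau > 0:
        delta = rng.normal(0.0, tau, size=(n_g, n_donors))
        X += delta[:, donor_codes]

    periods = meta["period"].to_numpy()
    for m in config.modules:
        f = rng.normal(0.0, 1.0, size=n_s)
        active = (
            np.ones(n_s)
            if m.active_periods is None
            else np.isin(periods, sorted(m.active_periods)).astype(float)
        )
        lam = m.loadings()
        X[list(m.genes), :] += np.outer(lam, f * active)

    if config.n_unwanted > 0:
        u = rng.normal(0.0, 1.0, size=(config.n_unwanted, n_s))
        if beta is None:
            beta = rng.normal(0.0, config.unwanted_sd, size=(n_g, config.n_unwanted))
        X += beta @ u

    X += rng.normal(0.0, config.noise_sd, size=(n_g, n_s))

    expr = pd.DataFrame(X, index=genes, columns=meta.index)
    return ExpressionDataset(name=name, expr=expr, meta=meta)


def simulate_datasets(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Generate ``config.n_datasets`` datasets plus the generating ground truth.

    Datasets share the gene list and module structure but have independent
    donors, factors, unwanted-factor realisations and noise (independent
    per-dataset random streams derived from ``config.seed``). The
    gene-level unwanted loadings beta are drawn once and shared across
    datasets: they model persistent technical susceptibility of a gene
    (probe affinity, GC content, transcript length), which is a property of
    the gene, not of the experiment.
    """
    config.validate()
    genes = config.gene_names()
    root = np.random.SeedSequence(config.seed)
    gene_child, *children = root.spawn(config.n_datasets + 1)
    beta = None
    if config.n_unwanted > 0:
        gene_rng = np.random.default_rng(gene_child)
        beta = gene_rng.normal(
            0.0, config.unwanted_sd, size=(config.n_genes, config.n_unwanted)
        )
    datasets = [
        _simulate_one(config, np.random.default_rng(child), name=f"sim{k + 1}", beta=beta)
        for k, child in enumerate(children)
    ]
    loadings = pd.DataFrame(
        0.0,
        index=genes,
        columns=[f"module{m + 1}" for m in range(len(config.modules))],
    )
    module_genes = []
    for j, m in enumerate(config.modules):
        names = [genes[g] for g in m.genes]
        loadings.loc[names, f"module{j + 1}"] = m.loadings()
        module_genes.append(names)
    truth = GroundTruth(
        config=config,
        genes=genes,
        housekeeping=config.housekeeping_genes(),
        loadings=loadings,
        module_genes=module_genes,
    )
    return datasets, truth


def simulate_null(
    n_genes: int = 1000,
    n_samples: int = 120,
    donor_sizes: tuple[int, ...] = (1, 1, 2, 4),
    seed: int = 0,
    name: str = "null",
) -> ExpressionDataset:
    """Pure-noise dataset (no modules, no unwanted factors) for calibration tests.

    Donor effects are retained, so samples from one donor stay positively
    correlated within a gene, as in real repeated-measures data.
    """
    config = SimulationConfig(
        n_datasets=1,
        n_genes=n_genes,
        n_samples=n_samples,
        donor_sizes=tuple(donor_sizes),
        modules=(),
        n_unwanted=0,
        seed=seed,
    )
    config.validate()
    ds = _simulate_one(
        config, np.random.default_rng(np.random.SeedSequence(seed)), name=name
    )
    return ds
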