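"""Dataset cleaning: positivity/quantile normalisation and RUV with negative controls.

Two strategies are offered. The conventional route enforces positivity and
quantile-normalises all samples onto a common empirical distribution. The
RUV (removal of unwanted variation) route estimates unwanted factors from
negative-control genes — genes affected by technical/batch variation but not
by the biology of interest, housekeeping genes by default — and regresses
them out of every gene with a ridge-style regularization that protects
biological signal correlated with the unwanted factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.stats

from .data_model import ExpressionDataset, GeneSetBundle, normalize_symbol

__all__ = [
    "RuvConfig",
    "default_negative_controls",
    "load_housekeeping",
    "background_quantile",
    "ruv_clean",
]

#: positivity floor applied by the background step
_FLOOR = 1e-6

#: ridge grid searched when RuvConfig.ridge is None
RIDGE_GRID = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class RuvConfig:
    """Configuration of the regularized RUV cleaning step.

    Parameters
    ----------
    n_factors
        Number of unwanted-variation dimensions removed (default 10). Must
        be smaller than the sample count.
    ridge
        Regularization strength λ >= 0. The removal of each factor is shrunk
        by 1/(1+λ): λ = 0 removes the full projection onto the factors,
        λ → ∞ removes nothing. ``None`` selects λ per dataset from
        ``RIDGE_GRID`` by matching the post-clean control–control correlation
        distribution to the independence null.
    control_genes
        Negative-control gene symbols; must be present in the dataset and
        non-empty whenever ``n_factors > 0``.
    """

    n_factors: int = 10
    ridge: float | None = None
    control_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_factors < 0:
            raise ValueError("n_factors must be non-negative")
        if self.ridge is not None and self.ridge < 0:
            raise ValueError("ridge must be non-negative")
        self.control_genes = frozenset(normalize_symbol(g) for g in self.control_genes)
        if self.n_factors > 0 and not self.control_genes:
            raise ValueError("control_genes must be non-empty when n_factors > 0")


def load_housekeeping() -> frozenset[str]:
    """Packaged default housekeeping gene symbols (replaceable via the CLI)."""
    text = resources.files("coexprior").joinpath("data/housekeeping.txt").read_text()
    return frozenset(
        normalize_symbol(line.split("#", 1)[0])
        for line in text.splitlines()
        if line.split("#", 1)[0].strip()
    )


def default_negative_controls(
    all_genes: Iterable[str], housekeeping: Iterable[str], bundle: GeneSetBundle
) -> frozenset[str]:
    """Default negative controls: housekeeping genes present in the data, minus
    known disease genes, candidates and user exclusions.

    Excluding the disease/candidate genes prevents RUV from treating the
    biology of interest as unwanted variation and removing it.
    """
    hk = frozenset(normalize_symbol(g) for g in housekeeping)
    if not hk:
        raise ValueError("housekeeping set is empty")
    present = frozenset(normalize_symbol(g) for g in all_genes)
    controls = (hk & present) - (bundle.disease | bundle.candidates | bundle.user_excluded)
    if not controls:
        raise ValueError(
            "no usable negative controls remain after filtering; "
            "supply controls explicitly"
        )
    return controls


def _quantile_normalise(X: np.ndarray) -> np.ndarray:
    """Quantile-normalise columns onto the mean of the per-rank order statistics.

    Ties within a column receive the mean of the reference values of the
    tied ranks.
    """
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X, dtype=float)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # average the reference values within each tie group
        s = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = s.to_numpy()
    return out


def background_quantile(dataset: ExpressionDataset) -> ExpressionDataset:
    """Background-style positivity correction followed by quantile normalisation.

    Datasets arrive as summarized log-scale matrices, so the background step
    is reduced to a per-column positivity floor: any column containing
    non-positive values is shifted up so its minimum equals a small constant;
    well-behaved columns are untouched. Quantile normalisation then gives
    every sample the identical empirical distribution (the mean of the
    per-rank order statistics), with ties averaged. The operation is
    idempotent up to tie handling.
    """
    X = dataset.values()
    mins = X.min(axis=0)
    shift = np.where(mins <= 0, _FLOOR - mins, 0.0)
    X = X + shift[None, :]
    X = _quantile_normalise(X)
    return ExpressionDataset(
        name=dataset.name,
        expr=pd.DataFrame(X, index=dataset.expr.index, columns=dataset.expr.columns),
        meta=dataset.meta,
    )


def _pearson_null(n_samples: int) -> scipy.stats.rv_continuous:
    """Null distribution of Pearson r for independent Gaussians (Beta on [-1,1])."""
    a = (n_samples - 2) / 2.0
    return scipy.stats.beta(a, a, loc=-1.0, scale=2.0)


def _control_null_distance(C_clean: np.ndarray, n_samples: int) -> float:
    """KS distance between control–control correlations and the independence null."""
    R = np.corrcoef(C_clean)
    iu = np.triu_indices_from(R, k=1)
    vals = R[iu]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return np.inf
    return float(scipy.stats.kstest(vals, _pearson_null(n_samples).cdf).statistic)


def ruv_clean(
    dataset: ExpressionDataset,
    config: RuvConfig,
    return_info: bool = False,
) -> ExpressionDataset | tuple[ExpressionDataset, dict]:
    """Remove unwanted variation estimated from negative-control genes.

    Rows are centered; the unwanted factors are the top ``n_factors`` right
    singular vectors of the centered control-gene submatrix; each gene's
    expression is adjusted by removing its ridge-regularized projection onto
    those factor scores (shrink factor 1/(1+λ)). With λ = 0 the control rows
    end exactly orthogonal to the estimated factors; with λ → ∞ the output
    converges to the row-centered input; with ``n_factors = 0`` the output is
    the row-centered input.
    """
    Y = dataset.values()
    n_genes, n_samples = Y.shape
    if config.n_factors >= n_samples:
        raise ValueError(
            f"n_factors={config.n_factors} must be below the sample count {n_samples}"
        )
    Yc = Y - Y.mean(axis=1, keepdims=True)

    info: dict = {
        "strategy": "ruv",
        "n_factors": config.n_factors,
        "n_controls": len(config.control_genes),
    }
    if config.n_factors == 0:
        cleaned = Yc
        info["ridge"] = config.ridge
    else:
        idx = {g: i for i, g in enumerate(dataset.expr.index)}
        missing = sorted(g for g in config.control_genes if g not in idx)
        if missing:
            raise ValueError(
                f"dataset {dataset.name!r}: control genes missing: {missing}"
            )
        ctrl_rows = sorted(idx[g] for g in config.control_genes)
        C = Yc[ctrl_rows]
        # factor scores: orthonormal right singular vectors of the controls
        _, _, Vt = np.linalg.svd(C, full_matrices=False)
        k = min(config.n_factors, Vt.shape[0])
        W = Vt[:k].T  # samples × k, orthonormal columns

        def _clean(lam: float) -> np.ndarray:
            return Yc - (Yc @ W) @ W.T / (1.0 + lam)

        if config.ridge is None:
            distances = {
                lam: _control_null_distance(_clean(lam)[ctrl_rows], n_samples)
                for lam in RIDGE_GRID
            }
            lam = min(distances, key=distances.get)
            info["ridge_grid"] = {str(k_): v for k_, v in distances.items()}
        else:
            lam = float(config.ridge)
        cleaned = _clean(lam)
        info["ridge"] = lam

    out = ExpressionDataset(
        name=dataset.name,
        expr=pd.DataFrame(
            cleaned, index=dataset.expr.index, columns=dataset.expr.columns
        ),
        meta=dataset.meta,
    )
    return (out, info) if return_info else out
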