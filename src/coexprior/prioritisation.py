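"""The three-step prioritisation engine with cross-dataset consensus.

Step 1 builds a permutation null: random gene sets of the candidate-set size
are correlated (donor-weighted) with the known disease genes and each random
gene's maximum absolute correlation is retained, pooled over B repeats.
Step 2 converts a user-chosen proportion of random genes allowed through
into an absolute-correlation threshold (the empirical (1 − proportion)
quantile of the pooled null). Step 3 prioritises every candidate whose
maximum absolute correlation with any disease gene strictly exceeds the
threshold. The three steps run per dataset; candidates are then scored by
the number of datasets prioritising them (consensus) and ranked.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ExpressionDataset,
    GeneSetBundle,
    donor_weights,
    normalize_symbol,
    subset_by_periods,
)
from .correlation import weighted_correlation

__all__ = [
    "NullDistribution",
    "DatasetPrioritisation",
    "PrioritisationResult",
    "sample_null",
    "threshold_from_null",
    "prioritise",
    "run_prioritisation",
    "consensus_filter",
    "rank_candidates",
]

def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class NullDistribution:
    """Pooled per-gene maximum absolute weighted correlations from B random sets.

    ``values`` holds B × set_size maxima (minus genes that could not be
    sampled); every value lies in [0, 1].
    """

    values: np.ndarray
    B: int
    set_size: int
    seed: object = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("null values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


def _pool_maxima(
    dataset: ExpressionDataset,
    disease_present: Sequence[str],
    exclude: frozenset[str],
) -> tuple[list[str], np.ndarray]:
    """Max |weighted r| against the disease set, for every eligible pool gene."""
    pool = [g for g in dataset.genes if g not in exclude]
    if not pool:
        return [], np.empty(0)
    w = donor_weights(dataset).to_numpy(dtype=float)
    X = dataset.expr.loc[pool].to_numpy(dtype=float)
    D = dataset.expr.loc[list(disease_present)].to_numpy(dtype=float)
    R, _, _ = weighted_correlation(X, D, w)
    return pool, np.abs(R).max(axis=1)


def sample_null(
    dataset: ExpressionDataset,
    disease: Iterable[str],
    set_size: int,
    B: int = 1000,
    seed=0,
    exclude: Iterable[str] = (),
) -> NullDistribution:
    """Step 1: permutation null of maximum absolute correlations.

    For each of ``B`` repeats a random set of ``set_size`` genes is drawn
    without replacement from the eligible pool (all genes except the disease
    genes and any ``exclude`` genes, typically the candidates); for each
    drawn gene the maximum absolute weighted correlation over the disease
    genes is recorded, and all B × set_size maxima are pooled.

    Because a gene's maximum does not depend on which random set it is drawn
    in, the per-gene maxima are computed once and the repeats only resample
    indices — identical to the literal procedure, but fast.
    """
    disease = {normalize_symbol(g) for g in disease}
    present = sorted(g for g in disease if g in dataset.expr.index)
    absent = sorted(disease - set(present))
    if absent:
        warnings.warn(
            f"dataset {dataset.name!r}: disease genes absent from data: {absent}",
            stacklevel=2,
        )
    if not present:
        raise ValueError(f"dataset {dataset.name!r}: no disease genes present")
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    excl = disease | {normalize_symbol(g) for g in exclude}
    pool, maxima = _pool_maxima(dataset, present, frozenset(excl))
    if len(pool) < set_size:
        raise ValueError(
            f"dataset {dataset.name!r}: eligible pool has {len(pool)} genes, "
            f"fewer than set_size={set_size}"
        )
    rng = _rng(seed)
    n = len(pool)
    picks = np.empty((B, set_size), dtype=np.intp)
    for b in range(B):
        picks[b] = rng.choice(n, size=set_size, replace=False, shuffle=False)
    return NullDistribution(
        values=maxima[picks].ravel(), B=B, set_size=set_size, seed=seed
    )


def threshold_from_null(null: NullDistribution, proportion: float) -> float:
    """Step 2: correlation threshold letting ``proportion`` of random genes through.

    Returns the empirical (1 − proportion) quantile of the pooled null under
    the inverse-ECDF (lower) definition: the smallest pooled value v with
    ECDF(v) >= 1 − proportion. proportion = 1 gives the minimum (every
    random gene would be prioritised or tie), proportion = 0 the maximum
    (no random gene strictly exceeds it). Monotone non-increasing in
    proportion.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError(f"proportion must be in [0, 1], got {proportion}")
    v = np.sort(null.values)
    n = v.size
    if n == 0:
        raise ValueError("null distribution is empty")
    q = 1.0 - proportion
    idx = max(int(math.ceil(q * n - 1e-9)), 1) - 1
    return float(v[idx])


def prioritise(
    dataset: ExpressionDataset,
    disease: Iterable[str],
    candidates: Iterable[str],
    threshold: float,
) -> pd.DataFrame:
    """Step 3: flag candidates whose max |r| with any disease gene exceeds the cutoff.

    Returns a DataFrame indexed by candidate gene with columns

    - ``max_abs_r`` — maximum absolute weighted correlation over the disease genes
    - ``sum_above_threshold`` — sum of |r| over disease genes, restricted to
      |r| > threshold (the within-dataset ranking score)
    - ``prioritised`` — ``max_abs_r > threshold`` (strict)
    - ``testable`` — False for candidates absent from this dataset (their
      numeric columns are NaN; absence is not failure)
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    disease = {normalize_symbol(g) for g in disease}
    cand_order = list(dict.fromkeys(normalize_symbol(g) for g in candidates))
    if not cand_order:
        raise ValueError("candidate set is empty")
    present_d = sorted(g for g in disease if g in dataset.expr.index)
    if not present_d:
        raise ValueError(f"dataset {dataset.name!r}: no disease genes present")
    present_c = [g for g in cand_order if g in dataset.expr.index]

    out = pd.DataFrame(
        index=pd.Index(cand_order, name="gene"),
        data={
            "max_abs_r": np.nan,
            "sum_above_threshold": np.nan,
            "prioritised": False,
            "testable": False,
        },
    )
    if present_c:
        w = donor_weights(dataset).to_numpy(dtype=float)
        X = dataset.expr.loc[present_c].to_numpy(dtype=float)
        D = dataset.expr.loc[present_d].to_numpy(dtype=float)
        R, _, _ = weighted_correlation(X, D, w)
        A = np.abs(R)
        out.loc[present_c, "max_abs_r"] = A.max(axis=1)
        out.loc[present_c, "sum_above_threshold"] = np.where(A > threshold, A, 0.0).sum(
            axis=1
        )
        out.loc[present_c, "prioritised"] = A.max(axis=1) > threshold
        out.loc[present_c, "testable"] = True
    out["prioritised"] = out["prioritised"].astype(bool)
    out["testable"] = out["testable"].astype(bool)
    return out


@dataclass
class DatasetPrioritisation:
    """Per-dataset stage outputs: the candidate records, threshold and null."""

    records: pd.DataFrame
    threshold: float
    null: NullDistribution
    n_samples: int


@dataclass
class PrioritisationResult:
    """Cross-dataset prioritisation outcome.

    ``table`` is indexed by candidate gene and ranked; columns are
    ``consensus_count`` (datasets prioritising the gene),
    ``testable_datasets``, ``total_sum_above_threshold`` (summed over
    prioritising datasets only) and ``rank``. ``per_dataset`` maps dataset
    name to its :class:`DatasetPrioritisation`.
    """

    table: pd.DataFrame
    per_dataset: dict[str, DatasetPrioritisation]
    params: dict = field(default_factory=dict)

    @property
    def thresholds(self) -> dict[str, float]:
        return {name: dp.threshold for name, dp in self.per_dataset.items()}


def rank_candidates(result: "PrioritisationResult | pd.DataFrame") -> pd.DataFrame:
    """Order candidates: consensus desc, total above-threshold sum desc, symbol asc.

    Accepts a :class:`PrioritisationResult` or its consensus table (with a
    ``gene`` column). Adds a 1-based ``rank`` column; ties on both numeric
    keys are visible from the equal key columns.
    """
    table = result.table.reset_index() if isinstance(result, PrioritisationResult) else result
    ordered = table.sort_values(
        by=["consensus_count", "total_sum_above_threshold", "gene"],
        ascending=[False, False, True],
    ).copy()
    ordered["rank"] = np.arange(1, len(ordered) + 1)
    return ordered


def run_prioritisation(
    datasets: Sequence[ExpressionDataset],
    bundle: GeneSetBundle,
    proportion: float = 0.2,
    periods: Iterable[int] | None = None,
    B: int = 1000,
    seed=0,
) -> PrioritisationResult:
    """Run the three prioritisation steps on every dataset and build the consensus.

    Each dataset is (optionally) restricted to the requested developmental
    periods, gets its own permutation null and threshold (with a
    deterministic per-dataset random stream derived from ``seed``), and
    prioritises the candidates. A dataset failing its preconditions is
    skipped with a warning and excluded from consensus denominators.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    if isinstance(seed, np.random.SeedSequence):
        root = seed
    else:
        root = np.random.SeedSequence(seed)
    children = root.spawn(len(datasets))

    per_dataset: dict[str, DatasetPrioritisation] = {}
    for ds, child in zip(datasets, children):
        try:
            d = subset_by_periods(ds, periods) if periods is not None else ds
            present_c = [g for g in sorted(bundle.candidates) if g in d.expr.index]
            if not present_c:
                raise ValueError(f"dataset {ds.name!r}: no candidate genes present")
            null = sample_null(
                d,
                bundle.disease,
                set_size=len(present_c),
                B=B,
                seed=np.random.default_rng(child),
                exclude=bundle.candidates,
            )
            thr = threshold_from_null(null, proportion)
            recs = prioritise(d, bundle.disease, sorted(bundle.candidates), thr)
        except ValueError as exc:
            warnings.warn(f"dataset {ds.name!r} skipped: {exc}", stacklevel=2)
            continue
        per_dataset[ds.name] = DatasetPrioritisation(
            records=recs, threshold=thr, null=null, n_samples=d.n_samples
        )

    cand_order = sorted(bundle.candidates)
    consensus = pd.DataFrame(
        index=pd.Index(cand_order, name="gene"),
        data={
            "consensus_count": 0,
            "testable_datasets": 0,
            "total_sum_above_threshold": 0.0,
        },
    )
    for dp in per_dataset.values():
        r = dp.records
        consensus["testable_datasets"] += r["testable"].astype(int)
        consensus["consensus_count"] += r["prioritised"].astype(int)
        # sum aggregated over prioritising datasets only
        consensus["total_sum_above_threshold"] += np.where(
            r["prioritised"], r["sum_above_threshold"].fillna(0.0), 0.0
        )
    table = rank_candidates(consensus.reset_index()).set_index("gene")

    return PrioritisationResult(
        table=table,
        per_dataset=per_dataset,
        params={
            "proportion": proportion,
            "periods": sorted(periods) if periods is not None else None,
            "B": B,
            "seed": getattr(seed, "entropy", seed)
            if not isinstance(seed, np.random.Generator)
            else None,
            "n_datasets_used": len(per_dataset),
        },
    )


def consensus_filter(result: PrioritisationResult, k: int) -> frozenset[str]:
    """Candidates prioritised in at least ``k`` datasets (nested in k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    t = result.table
    return frozenset(t.index[t["consensus_count"] >= k])
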