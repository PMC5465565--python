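"""Donor-weighted Pearson correlation and derived network quantities.

All correlations in the package weight each sample by the inverse of the
number of samples its donor contributed, so that a donor with many arrays
does not dominate the estimate. With all-singleton donors every formula
reduces exactly to the unweighted Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import ExpressionDataset, donor_weights, normalize_symbol, subset_by_periods

__all__ = [
    "CorrelationMatrix",
    "weighted_pearson",
    "weighted_correlation",
    "correlation_matrix",
    "partial_correlations",
    "period_correlations",
    "differential_correlation",
    "combine_correlation_matrices",
]

#: hard floor on sample count for any correlation estimate
MIN_SAMPLES = 3
#: below this many samples a warning is emitted
WARN_SAMPLES = 10


def _standardize(X: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted row-centering and scaling; returns (centered*sqrt-ready, sd)."""
    wsum = w.sum()
    means = X @ w / wsum
    Xc = X - means[:, None]
    sd = np.sqrt((Xc * Xc) @ w)
    return Xc, sd


def weighted_correlation(
    X: np.ndarray, Y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted Pearson correlation between every row of X and every row of Y.

    r_jk = sum_i w_i (x_ji - x̄_j)(y_ki - ȳ_k) /
           sqrt( sum_i w_i (x_ji - x̄_j)^2 · sum_i w_i (y_ki - ȳ_k)^2 )

    with weighted means x̄, ȳ. Zero-variance rows yield correlation 0 and are
    reported in the returned degeneracy masks.

    Returns
    -------
    (R, x_degenerate, y_degenerate)
        R has shape ``(X.shape[0], Y.shape[0])`` and is clipped to [-1, 1].
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    w = np.asarray(w, dtype=float).ravel()
    if X.shape[1] != w.size or Y.shape[1] != w.size:
        raise ValueError(
            f"length mismatch: X has {X.shape[1]}, Y has {Y.shape[1]}, weights {w.size}"
        )
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    Xc, sx = _standardize(X, w)
    Yc, sy = _standardize(Y, w)
    x_deg = sx <= 0
    y_deg = sy <= 0
    sx_safe = np.where(x_deg, 1.0, sx)
    sy_safe = np.where(y_deg, 1.0, sy)
    R = (Xc * w) @ Yc.T / np.outer(sx_safe, sy_safe)
    R[x_deg, :] = 0.0
    R[:, y_deg] = 0.0
    return np.clip(R, -1.0, 1.0), x_deg, y_deg


def weighted_pearson(
    x: Sequence[float], y: Sequence[float], w: Sequence[float]
) -> float:
    """Donor-weighted Pearson correlation of two vectors.

    Requires at least ``MIN_SAMPLES`` observations. Returns NaN if either
    vector has zero weighted variance (undefined correlation).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if not (x.size == y.size == w.size):
        raise ValueError(f"length mismatch: {x.size}, {y.size}, {w.size}")
    if x.size < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {x.size}")
    R, x_deg, y_deg = weighted_correlation(x[None, :], y[None, :], w)
    if x_deg[0] or y_deg[0]:
        return float("nan")
    return float(R[0, 0])


@dataclass
class CorrelationMatrix:
    """Symmetric gene–gene correlation matrix with provenance.

    ``values`` is a square DataFrame with unit diagonal (except degenerate,
    zero-variance genes, whose rows/columns are 0 and which are listed in
    ``degenerate``). ``provenance`` records dataset name, periods and
    weighting so heatmaps and exports are self-describing.
    """

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    degenerate: frozenset[str] = field(default_factory=frozenset)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")

    def to_edges(self, cutoff: float = 0.0) -> pd.DataFrame:
        """Long-format edge list (gene_a, gene_b, r) with optional |r| cutoff."""
        genes = self.genes
        rows = []
        vals = self.values.to_numpy()
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                r = vals[i, j]
                if abs(r) >= cutoff:
                    rows.append((genes[i], genes[j], r))
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])

    def to_graphml(self, path: str | Path, cutoff: float = 0.0) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.genes)
        for _, row in self.to_edges(cutoff).iterrows():
            g.add_edge(row["gene_a"], row["gene_b"], r=float(row["r"]))
        nx.write_graphml(g, str(path))


def correlation_matrix(
    dataset: ExpressionDataset,
    genes: Iterable[str],
    weights: pd.Series | None = None,
) -> CorrelationMatrix:
    """Pairwise donor-weighted correlations over the requested genes.

    Genes absent from the dataset are dropped with a warning. Fails below
    three samples; warns below ten.
    """
    requested = [normalize_symbol(g) for g in genes]
    present = [g for g in dict.fromkeys(requested) if g in dataset.expr.index]
    absent = [g for g in dict.fromkeys(requested) if g not in dataset.expr.index]
    if absent:
        warnings.warn(
            f"dataset {dataset.name!r}: genes not found and dropped: {absent}",
            stacklevel=2,
        )
    if not present:
        raise ValueError(f"none of the requested genes are in dataset {dataset.name!r}")
    n = dataset.n_samples
    if n < MIN_SAMPLES:
        raise ValueError(
            f"dataset {dataset.name!r}: {n} samples < minimum {MIN_SAMPLES}"
        )
    if n < WARN_SAMPLES:
        warnings.warn(
            f"dataset {dataset.name!r}: only {n} samples; correlations unstable",
            stacklevel=2,
        )
    w = (weights if weights is not None else donor_weights(dataset)).to_numpy(dtype=float)
    X = dataset.expr.loc[present].to_numpy(dtype=float)
    R, deg, _ = weighted_correlation(X, X, w)
    np.fill_diagonal(R, np.where(deg, 0.0, 1.0))
    R = (R + R.T) / 2.0
    return CorrelationMatrix(
        values=pd.DataFrame(R, index=present, columns=present),
        provenance={
            "dataset": dataset.name,
            "n_samples": n,
            "weighted": True,
            "periods": sorted(dataset.meta["period"].unique().tolist()),
        },
        degenerate=frozenset(np.asarray(present)[deg].tolist()),
    )


def partial_correlations(
    cor: CorrelationMatrix, shrinkage: float = 0.1
) -> CorrelationMatrix:
    """Partial correlations controlling for all other genes in the matrix.

    The correlation matrix is shrunk toward the identity,
    ``R_s = (1-s) R + s I``, inverted, and the partials are
    ``p_jk = -q_jk / sqrt(q_jj q_kk)``. Shrinkage keeps the inversion stable
    when the gene count approaches or exceeds the sample count; with two
    genes the partial equals the marginal correlation (nothing to condition
    on, up to the shrinkage of the input).
    """
    if not 0 <= shrinkage < 1:
        raise ValueError(f"shrinkage must be in [0, 1), got {shrinkage}")
    R = cor.values.to_numpy(dtype=float)
    p = R.shape[0]
    Rs = (1.0 - shrinkage) * R + shrinkage * np.eye(p)
    try:
        Q = np.linalg.inv(Rs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "correlation matrix is singular; increase shrinkage above 0"
        ) from exc
    cond = np.linalg.cond(Rs)
    if shrinkage == 0 and cond > 1e12:
        raise ValueError("correlation matrix is near-singular; use shrinkage > 0")
    d = np.sqrt(np.diag(Q))
    P = -Q / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    P = np.clip((P + P.T) / 2.0, -1.0, 1.0)
    prov = dict(cor.provenance)
    prov.update(kind="partial", shrinkage=shrinkage)
    return CorrelationMatrix(
        values=pd.DataFrame(P, index=cor.genes, columns=cor.genes),
        provenance=prov,
        degenerate=cor.degenerate,
    )


def period_correlations(
    dataset: ExpressionDataset,
    genes: Iterable[str],
    period_sets: Sequence[Iterable[int]],
    min_samples: int = MIN_SAMPLES,
) -> list[CorrelationMatrix]:
    """One correlation matrix per developmental-period set.

    Each matrix is computed on the period subset with donor weights
    recomputed on that subset, so networks can be compared across stages of
    brain development. Period sets with fewer than ``min_samples`` samples
    are omitted with a warning.
    """
    genes = list(genes)
    out: list[CorrelationMatrix] = []
    for pset in period_sets:
        pset = set(pset)
        try:
            sub = subset_by_periods(dataset, pset)
        except ValueError as exc:
            warnings.warn(f"period set {sorted(pset)} omitted: {exc}", stacklevel=2)
            continue
        if sub.n_samples < min_samples:
            warnings.warn(
                f"period set {sorted(pset)} omitted: only {sub.n_samples} samples",
                stacklevel=2,
            )
            continue
        cm = correlation_matrix(sub, genes)
        cm.provenance["periods"] = sorted(pset)
        out.append(cm)
    return out


def differential_correlation(
    a: CorrelationMatrix, b: CorrelationMatrix
) -> pd.DataFrame:
    """Elementwise difference a − b of two correlation matrices on identical genes.

    Highlights rewiring of the gene network between two sets of
    developmental periods; entries lie in [−2, 2].
    """
    if a.genes != b.genes:
        raise ValueError("correlation matrices have different gene labels")
    return a.values - b.values


def combine_correlation_matrices(
    matrices: Sequence[CorrelationMatrix], weights: Sequence[float] | None = None
) -> CorrelationMatrix:
    """Combine per-dataset correlation matrices over their shared genes.

    The combination is a weighted average (default weights: the number of
    distinct donors recorded in each matrix's provenance, else 1). Values
    from different platforms are never merged at the sample level; only the
    correlation estimates are averaged.
    """
    if not matrices:
        raise ValueError("no correlation matrices to combine")
    shared = [g for g in matrices[0].genes if all(g in m.values.index for m in matrices)]
    if not shared:
        raise ValueError("no shared genes across matrices")
    if weights is None:
        weights = [float(m.provenance.get("n_donors", 1.0)) for m in matrices]
    w = np.asarray(weights, dtype=float)
    if w.size != len(matrices) or np.any(w <= 0):
        raise ValueError("need one positive weight per matrix")
    acc = np.zeros((len(shared), len(shared)))
    for m, wi in zip(matrices, w):
        acc += wi * m.values.loc[shared, shared].to_numpy()
    acc /= w.sum()
    np.fill_diagonal(acc, 1.0)
    return CorrelationMatrix(
        values=pd.DataFrame(acc, index=shared, columns=shared),
        provenance={
            "kind": "combined",
            "sources": [m.provenance.get("dataset") for m in matrices],
            "weights": w.tolist(),
        },
    )
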