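"""Domain types and I/O: expression datasets, developmental periods, donor weights.

Expression data are genes × samples matrices of log-scale intensities with
per-sample donor and age metadata. Donors often contribute several samples
(multiple brain regions or arrays), so samples are not independent; the
per-sample weights used throughout the package are the inverse of the number
of samples the donor contributed. Samples are binned into 15 developmental
periods (embryonic through late adulthood) from their age at death.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "ExpressionDataset",
    "GeneSetBundle",
    "AGE_UNITS",
    "assign_period",
    "donor_weights",
    "load_expression",
    "load_gene_list",
    "normalize_symbol",
    "subset_by_periods",
]

#: canonical age-unit codes: post-conception weeks, months, years
AGE_UNITS = ("PCW", "M", "Y")

_UNIT_ALIASES = {
    "pcw": "PCW",
    "w": "PCW",
    "weeks": "PCW",
    "m": "M",
    "month": "M",
    "months": "M",
    "y": "Y",
    "yr": "Y",
    "yrs": "Y",
    "year": "Y",
    "years": "Y",
}

# Prenatal periods 1..7 on the PCW scale, half-open [lower, upper):
# [4,8) [8,10) [10,13) [13,16) [16,19) [19,24) [24, inf)
_PCW_EDGES = (8.0, 10.0, 13.0, 16.0, 19.0, 24.0)

# Postnatal periods 8..15 on the year scale, half-open:
# [0,0.5) [0.5,1) [1,6) [6,12) [12,20) [20,40) [40,60) [60, inf)
_POSTNATAL_EDGES_Y = (0.5, 1.0, 6.0, 12.0, 20.0, 40.0, 60.0)


def normalize_symbol(symbol: str) -> str:
    """Strip whitespace and upper-case a gene symbol (case-insensitive matching)."""
    return str(symbol).strip().upper()


def _norm_unit(unit: str) -> str:
    u = str(unit).strip()
    if u in AGE_UNITS:
        return u
    key = u.lower()
    if key in _UNIT_ALIASES:
        return _UNIT_ALIASES[key]
    raise ValueError(f"unparseable age unit {unit!r}; expected one of {AGE_UNITS}")


def assign_period(age_value: float, age_unit: str) -> int:
    """Map an age to one of the 15 developmental periods of the human brain.

    Prenatal ages are given in post-conception weeks (PCW) and map to
    periods 1–7 (embryonic through late fetal); postnatal ages in months or
    years map to periods 8–15 (neonatal through late adulthood). Intervals
    are half-open ``[lower, upper)``; the PCW and postnatal scales are never
    converted into each other — the unit selects the block.

    Parameters
    ----------
    age_value
        Non-negative age. PCW values must be >= 4 (earlier is pre-embryonic
        and outside the period table).
    age_unit
        ``"PCW"``, ``"M"`` (months) or ``"Y"`` (years); common aliases accepted.

    Returns
    -------
    int
        Period number in 1..15.
    """
    unit = _norm_unit(age_unit)
    age = float(age_value)
    if not np.isfinite(age) or age < 0:
        raise ValueError(f"age must be a non-negative number, got {age_value!r}")
    if unit == "PCW":
        if age < 4:
            raise ValueError(
                f"PCW age {age} is pre-embryonic (< 4 PCW) and outside the period table"
            )
        return 1 + bisect_right(_PCW_EDGES, age)
    years = age / 12.0 if unit == "M" else age
    return 8 + bisect_right(_POSTNATAL_EDGES_Y, years)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample: donor, age and assigned developmental period."""

    sample_id: str
    donor_id: str
    age_value: float
    age_unit: str
    period: int

    def __post_init__(self) -> None:
        if not 1 <= self.period <= 15:
            raise ValueError(f"period must be in 1..15, got {self.period}")


@dataclass
class ExpressionDataset:
    """One expression data source: genes × samples matrix plus sample metadata.

    Attributes
    ----------
    name
        Short identifier of the data source.
    expr
        DataFrame of log-scale expression, index = gene symbols (unique,
        normalized), columns = sample ids.
    meta
        DataFrame indexed by sample id with columns ``donor_id``,
        ``age_value``, ``age_unit`` and ``period``; rows ordered like the
        expression columns.
    """

    name: str
    expr: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.expr.columns) != list(self.meta.index):
            raise ValueError(
                f"dataset {self.name!r}: expression columns and metadata rows disagree"
            )
        if self.expr.index.has_duplicates:
            dups = self.expr.index[self.expr.index.duplicated()].unique().tolist()
            raise ValueError(f"dataset {self.name!r}: duplicate gene symbols {dups}")
        if self.expr.isna().to_numpy().any():
            raise ValueError(f"dataset {self.name!r}: missing values in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.expr.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expr.columns)

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    def samples(self) -> list[SampleMeta]:
        """Materialise per-sample metadata records."""
        return [
            SampleMeta(
                sample_id=str(sid),
                donor_id=str(row["donor_id"]),
                age_value=float(row["age_value"]),
                age_unit=str(row["age_unit"]),
                period=int(row["period"]),
            )
            for sid, row in self.meta.iterrows()
        ]

    def values(self) -> np.ndarray:
        """Expression matrix as a float array (genes × samples)."""
        return self.expr.to_numpy(dtype=float)


@dataclass
class GeneSetBundle:
    """Named gene sets driving a prioritisation run.

    ``disease`` are the known genes, ``candidates`` the genes to prioritise,
    ``negative_controls`` the genes assumed free of the biology of interest
    (used by RUV cleaning), and ``user_excluded`` additional genes the user
    bars from serving as controls.
    """

    disease: frozenset[str]
    candidates: frozenset[str]
    negative_controls: frozenset[str] = field(default_factory=frozenset)
    user_excluded: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.disease = frozenset(normalize_symbol(g) for g in self.disease)
        self.candidates = frozenset(normalize_symbol(g) for g in self.candidates)
        self.negative_controls = frozenset(normalize_symbol(g) for g in self.negative_controls)
        self.user_excluded = frozenset(normalize_symbol(g) for g in self.user_excluded)
        overlap = self.disease & self.candidates
        if overlap:
            raise ValueError(
                "genes cannot be both known disease genes and candidates: "
                + ", ".join(sorted(overlap))
            )
        # controls must carry no signal of interest
        self.negative_controls = self.negative_controls - (
            self.disease | self.candidates | self.user_excluded
        )


def donor_weights(dataset: ExpressionDataset) -> pd.Series:
    """Per-sample weights: inverse of the number of samples the donor contributed.

    A donor with four samples gives each of them weight 1/4, so every donor
    contributes total weight 1 and the weights sum to the number of distinct
    donors. These weights feed the weighted Pearson correlation and correct
    for the dependence of repeated samples from one brain.
    """
    counts = dataset.meta["donor_id"].map(dataset.meta["donor_id"].value_counts())
    w = 1.0 / counts.astype(float)
    w.name = "weight"
    return w


def load_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list: one symbol per line, ``#`` comments allowed.

    Symbols are whitespace-stripped, upper-cased and de-duplicated while
    preserving first-occurrence order.
    """
    seen: dict[str, None] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        seen.setdefault(normalize_symbol(line), None)
    return list(seen)


def load_expression(
    matrix_path: str | Path, meta_path: str | Path, name: str
) -> ExpressionDataset:
    """Load a genes × samples TSV matrix and its sample-metadata TSV.

    The matrix has a header row of sample ids and gene symbols in the first
    column; the metadata file has columns ``sample_id``, ``donor_id``,
    ``age_value`` and ``age_unit``. Samples must match one-to-one between the
    two files. Gene symbols are normalized; duplicate symbols are collapsed
    to the highest-variance row; rows with missing values are dropped with a
    warning. Developmental periods are assigned from age.
    """
    expr = pd.read_csv(matrix_path, sep="\t", index_col=0)
    expr.index = [normalize_symbol(g) for g in expr.index]
    expr.columns = [str(c).strip() for c in expr.columns]

    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    required = {"sample_id", "donor_id", "age_value", "age_unit"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata {meta_path} lacks columns: {sorted(missing_cols)}")
    meta["sample_id"] = meta["sample_id"].str.strip()
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    meta = meta.set_index("sample_id")

    matrix_samples = set(expr.columns)
    meta_samples = set(meta.index)
    if matrix_samples != meta_samples:
        only_matrix = sorted(matrix_samples - meta_samples)
        only_meta = sorted(meta_samples - matrix_samples)
        parts = []
        if only_matrix:
            parts.append(f"samples only in matrix: {only_matrix}")
        if only_meta:
            parts.append(f"samples only in metadata: {only_meta}")
        raise ValueError(f"dataset {name!r}: sample mismatch; " + "; ".join(parts))
    meta = meta.loc[expr.columns]

    try:
        meta["age_value"] = meta["age_value"].astype(float)
    except ValueError as exc:
        raise ValueError(f"dataset {name!r}: unparseable age_value: {exc}") from exc
    meta["age_unit"] = [_norm_unit(u) for u in meta["age_unit"]]
    meta["period"] = [
        assign_period(v, u) for v, u in zip(meta["age_value"], meta["age_unit"])
    ]

    # incomplete rows break the correlation machinery; drop them up front
    na_rows = expr.isna().any(axis=1)
    if na_rows.any():
        warnings.warn(
            f"dataset {name!r}: dropping {int(na_rows.sum())} gene rows with missing values",
            stacklevel=2,
        )
        expr = expr.loc[~na_rows]

    if expr.index.has_duplicates:
        variances = expr.var(axis=1, ddof=0)
        # keep the most informative (highest-variance) row per symbol
        order = np.argsort(-variances.to_numpy(), kind="stable")
        expr = expr.iloc[order]
        expr = expr[~expr.index.duplicated(keep="first")]
        expr = expr.sort_index()

    return ExpressionDataset(name=name, expr=expr.astype(float), meta=meta)


def subset_by_periods(
    dataset: ExpressionDataset, periods: Iterable[int]
) -> ExpressionDataset:
    """Restrict a dataset to samples whose developmental period is in ``periods``.

    The gene list is unchanged. Donor weights are not carried over; recompute
    them on the subset.
    """
    pset = {int(p) for p in periods}
    if not pset <= set(range(1, 16)):
        raise ValueError(f"periods must be within 1..15, got {sorted(pset)}")
    keep = dataset.meta["period"].isin(pset)
    if not keep.any():
        raise ValueError(
            f"dataset {dataset.name!r}: no samples in periods {sorted(pset)}; "
            "widen the period selection"
        )
    kept = dataset.meta.index[keep]
    return ExpressionDataset(
        name=dataset.name, expr=dataset.expr[kept], meta=dataset.meta.loc[kept]
    )


def parse_periods(text: str) -> set[int]:
    """Parse a period selection like ``"4-10"`` or ``"1,3,5-7"``."""
    out: set[int] = set()
    for chunk in str(text).split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "-" in chunk:
            lo, hi = chunk.split("-", 1)
            out.update(range(int(lo), int(hi) + 1))
        else:
            out.add(int(chunk))
    if not out or not out <= set(range(1, 16)):
        raise ValueError(f"invalid period selection {text!r}")
    return out
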