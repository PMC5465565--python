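"""Leave-one-out cross-validation benchmarking of the prioritisation pipeline.

Each known gene in turn plays the "defector": it is removed from the known
set, hidden among 99 random decoy candidates, and the pipeline must
re-discover it. Counting defectors and decoys prioritised in at least k
datasets yields confusion matrices and the four accuracy metrics
(sensitivity, specificity, precision, negative predictive value) as
functions of the consensus requirement k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ExpressionDataset, GeneSetBundle, normalize_symbol
from .prioritisation import run_prioritisation

__all__ = [
    "BenchmarkRecord",
    "ConfusionAtK",
    "loocv",
    "confusion_at_k",
    "metrics",
    "benchmark_suite",
]

N_DECOYS = 99


@dataclass(frozen=True)
class BenchmarkRecord:
    """Outcome of one defector trial.

    ``defector_support`` is the number of datasets prioritising the hidden
    known gene; ``decoy_supports`` maps each decoy to its own count.
    """

    gene_set_name: str
    defector: str
    defector_support: int
    decoy_supports: dict[str, int]
    seed: int


@dataclass(frozen=True)
class ConfusionAtK:
    """Confusion matrix at consensus requirement k, pooled over trials."""

    k: int
    TP: int
    FP: int
    TN: int
    FN: int


def loocv(
    datasets: Sequence[ExpressionDataset],
    known_set: Iterable[str],
    proportion: float = 0.2,
    B: int = 1000,
    seed: int = 0,
    n_decoys: int = N_DECOYS,
    gene_set_name: str = "set",
    clean=None,
) -> list[BenchmarkRecord]:
    """Run one defector trial per known gene.

    For each gene g in the known set, the disease set becomes
    ``known_set − {g}`` and the candidates are g plus ``n_decoys`` genes
    drawn (once per trial) from genes present in at least one dataset and
    not in the known set. ``clean`` may be a callable applied to each
    dataset before the run (e.g. a cleaning strategy); known genes absent
    from all datasets are skipped with a warning.
    """
    known = sorted({normalize_symbol(g) for g in known_set})
    if len(known) < 2:
        raise ValueError("known set must contain at least 2 genes")
    if clean is not None:
        datasets = [clean(ds) for ds in datasets]
    all_genes: set[str] = set()
    for ds in datasets:
        all_genes.update(ds.genes)
    pool = sorted(all_genes - set(known))
    testable = [g for g in known if g in all_genes]
    skipped = sorted(set(known) - set(testable))
    if skipped:
        warnings.warn(
            f"known genes absent from every dataset, trials skipped: {skipped}",
            stacklevel=2,
        )

    root = np.random.SeedSequence(seed)
    children = root.spawn(len(testable))
    records: list[BenchmarkRecord] = []
    for g, child in zip(testable, children):
        decoy_ss, run_ss = child.spawn(2)
        rng = np.random.default_rng(decoy_ss)
        nd = min(n_decoys, len(pool))
        if nd < n_decoys:
            warnings.warn(
                f"decoy pool exhausted: {nd} < {n_decoys} decoys for {g}", stacklevel=2
            )
        decoys = [pool[i] for i in rng.choice(len(pool), size=nd, replace=False)]
        bundle = GeneSetBundle(
            disease=frozenset(set(known) - {g}), candidates=frozenset([g, *decoys])
        )
        res = run_prioritisation(
            datasets, bundle, proportion=proportion, B=B, seed=run_ss
        )
        counts = res.table["consensus_count"]
        records.append(
            BenchmarkRecord(
                gene_set_name=gene_set_name,
                defector=g,
                defector_support=int(counts.loc[g]),
                decoy_supports={d: int(counts.loc[d]) for d in decoys},
                seed=seed,
            )
        )
    return records


def confusion_at_k(records: Sequence[BenchmarkRecord], k: int) -> ConfusionAtK:
    """Pool defector/decoy outcomes into a confusion matrix at requirement k.

    A prioritisation is successful when the gene is prioritised in at least
    k datasets: defectors give TP/FN, decoy gene-trials give FP/TN.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tp = sum(r.defector_support >= k for r in records)
    fn = len(records) - tp
    fp = sum(c >= k for r in records for c in r.decoy_supports.values())
    total_decoys = sum(len(r.decoy_supports) for r in records)
    return ConfusionAtK(k=k, TP=tp, FP=fp, TN=total_decoys - fp, FN=fn)


def metrics(c: ConfusionAtK) -> dict[str, float]:
    """Sensitivity, specificity, precision and NPV; NaN where undefined."""

    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "sensitivity": _ratio(c.TP, c.TP + c.FN),
        "specificity": _ratio(c.TN, c.TN + c.FP),
        "precision": _ratio(c.TP, c.TP + c.FP),
        "npv": _ratio(c.TN, c.TN + c.FN),
    }


def benchmark_suite(
    datasets: Sequence[ExpressionDataset],
    gene_sets: Mapping[str, Iterable[str]],
    proportion: float = 0.2,
    B: int = 1000,
    seed: int = 0,
    n_decoys: int = N_DECOYS,
    clean=None,
) -> pd.DataFrame:
    """LOOCV metrics per gene set and per k = 1..n_datasets, plus per-k means.

    Returns a tidy DataFrame with columns gene_set, k, TP, FP, TN, FN and
    the four metrics; the across-set unweighted mean appears as gene_set
    ``"mean"``.
    """
    if not gene_sets:
        raise ValueError("need at least one gene set")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(gene_sets))
    ks = range(1, len(datasets) + 1)
    rows = []
    for (name, genes), child in zip(gene_sets.items(), children):
        records = loocv(
            datasets,
            genes,
            proportion=proportion,
            B=B,
            seed=int(child.generate_state(1)[0] % (2**31)),
            n_decoys=n_decoys,
            gene_set_name=name,
            clean=clean,
        )
        for k in ks:
            c = confusion_at_k(records, k)
            rows.append(
                {
                    "gene_set": name,
                    "k": k,
                    "TP": c.TP,
                    "FP": c.FP,
                    "TN": c.TN,
                    "FN": c.FN,
                    **metrics(c),
                }
            )
    table = pd.DataFrame(rows)
    means = (
        table.groupby("k")[["sensitivity", "specificity", "precision", "npv"]]
        .mean()
        .reset_index()
    )
    means.insert(0, "gene_set", "mean")
    return pd.concat([table, means], ignore_index=True)
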