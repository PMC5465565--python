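"""Shared fixtures: tiny hand-built datasets and simulated module datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coexprior import (
    ExpressionDataset,
    ModuleSpec,
    SimulationConfig,
    loading_for_correlation,
    simulate_datasets,
)


def make_dataset(
    values: np.ndarray,
    genes: list[str],
    donors: list[str],
    ages: list[tuple[float, str]] | None = None,
    name: str = "toy",
) -> ExpressionDataset:
    """Build a dataset from a raw matrix, gene names and per-sample donors."""
    n = values.shape[1]
    if ages is None:
        ages = [(25.0, "Y")] * n
    sample_ids = [f"s{i + 1}" for i in range(n)]
    from coexprior import assign_period

    meta = pd.DataFrame(
        {
            "donor_id": donors,
            "age_value": [a for a, _ in ages],
            "age_unit": [u for _, u in ages],
            "period": [assign_period(a, u) for a, u in ages],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    from coexprior.data_model import normalize_symbol

    expr = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[normalize_symbol(g) for g in genes],
        columns=sample_ids,
    )
    return ExpressionDataset(name=name, expr=expr, meta=meta)


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    """6 samples, donors (A,A,B,C,C,D): 2 disease genes + 2 candidates."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],  # D1
            [2.0, 1.0, 4.0, 3.0, 6.0, 5.0],  # D2
            [1.1, 2.2, 2.9, 4.3, 5.1, 5.8],  # C1, tracks D1
            [3.0, -1.0, 2.0, 0.5, 1.5, -0.5],  # C2, unrelated
        ]
    )
    return make_dataset(values, ["D1", "D2", "C1", "C2"], ["A", "A", "B", "C", "C", "D"])


@pytest.fixture(scope="session")
def module_sim():
    """3 simulated datasets with a 10-gene module at theoretical r = 0.8."""
    lam = loading_for_correlation(0.8)
    config = SimulationConfig(
        n_datasets=3,
        n_genes=400,
        n_samples=100,
        modules=(ModuleSpec(genes=tuple(range(10)), loading=lam),),
        seed=2024,
    )
    return simulate_datasets(config)
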