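"""The three-step prioritisation engine, consensus and ranking."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coexprior import (
    GeneSetBundle,
    NullDistribution,
    consensus_filter,
    prioritise,
    rank_candidates,
    run_prioritisation,
    sample_null,
    threshold_from_null,
)

from conftest import make_dataset


class TestSampleNull:
    def _null_ds(self, seed=0, n_genes=60, n_samples=40):
        rng = np.random.default_rng(seed)
        return make_dataset(
            rng.normal(size=(n_genes, n_samples)),
            [f"g{i}" for i in range(n_genes)],
            [f"d{i}" for i in range(n_samples)],
        )

    def test_determinism(self):
        ds = self._null_ds()
        a = sample_null(ds, ["g0"], set_size=5, B=20, seed=42)
        b = sample_null(ds, ["g0"], set_size=5, B=20, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_size_and_range(self):
        ds = self._null_ds()
        null = sample_null(ds, ["g0", "g1"], set_size=5, B=30, seed=1)
        assert null.values.size == 30 * 5
        assert null.values.min() >= 0 and null.values.max() <= 1

    def test_pool_excludes_disease_and_candidates(self):
        # duplicate g0 as gX: if gX were in the pool its maximum would be 1
        ds = self._null_ds()
        dup = ds.expr.loc[["G0"]].rename(index={"G0": "GX"})
        expr = pd.concat([ds.expr, dup])
        ds2 = make_dataset(
            expr.to_numpy(), list(expr.index), list(ds.meta["donor_id"]),
        )
        null = sample_null(
            ds2, ["g0"], set_size=59, B=50, seed=2, exclude=["gX"]
        )
        assert null.values.max() < 1.0

    def test_duplicated_pool_gene_reaches_one(self):
        ds = self._null_ds()
        dup = ds.expr.loc[["G0"]].rename(index={"G0": "GX"})
        expr = pd.concat([ds.expr, dup])
        ds2 = make_dataset(expr.to_numpy(), list(expr.index), list(ds.meta["donor_id"]))
        null = sample_null(ds2, ["g0"], set_size=60, B=5, seed=3)
        # every repeat draws the whole pool, so gX is always included
        assert null.values.max() == pytest.approx(1.0)

    def test_pool_too_small_fatal(self):
        ds = self._null_ds(n_genes=10)
        with pytest.raises(ValueError, match="pool"):
            sample_null(ds, ["g0"], set_size=10, B=5, seed=0)

    def test_absent_disease_gene_warns(self):
        ds = self._null_ds()
        with pytest.warns(UserWarning, match="absent"):
            sample_null(ds, ["g0", "nope"], set_size=5, B=5, seed=0)

    def test_null_matches_independent_pair_distribution(self):
        # one disease gene, independent pool: null = |r| of independent pairs;
        # compare median to the analytic |r| median for n samples
        import scipy.stats

        n = 40
        ds = self._null_ds(seed=5, n_genes=400, n_samples=n)
        null = sample_null(ds, ["g0"], set_size=100, B=200, seed=6)
        a = (n - 2) / 2
        r_dist = scipy.stats.beta(a, a, loc=-1, scale=2)
        med_expected = r_dist.ppf(0.75)  # median of |r| by symmetry
        assert np.median(null.values) == pytest.approx(med_expected, abs=0.03)


class TestThreshold:
    def test_hand_quantile_on_ten_values(self):
        null = NullDistribution(values=np.arange(1, 11) / 10.0, B=1, set_size=10)
        assert threshold_from_null(null, 0.2) == pytest.approx(0.8)

    def test_proportion_one_gives_minimum(self):
        null = NullDistribution(values=np.array([0.3, 0.1, 0.7]), B=1, set_size=3)
        assert threshold_from_null(null, 1.0) == pytest.approx(0.1)

    def test_proportion_zero_gives_maximum(self):
        null = NullDistribution(values=np.array([0.3, 0.1, 0.7]), B=1, set_size=3)
        assert threshold_from_null(null, 0.0) == pytest.approx(0.7)

    def test_monotone_non_increasing_in_proportion(self):
        rng = np.random.default_rng(0)
        null = NullDistribution(values=rng.random(500), B=5, set_size=100)
        thresholds = [threshold_from_null(null, p) for p in np.linspace(0, 1, 21)]
        assert all(a >= b for a, b in zip(thresholds, thresholds[1:]))

    def test_invalid_proportion_rejected(self):
        null = NullDistribution(values=np.array([0.5]), B=1, set_size=1)
        with pytest.raises(ValueError):
            threshold_from_null(null, 1.5)


class TestPrioritise:
    def test_worked_fixture_matches_loop_oracle(self, toy_dataset):
        """Frozen from a loop-based evaluation of the weighted formula:
        donors (A,A,B,C,C,D) -> w=(.5,.5,1,.5,.5,1);
        C1 vs (D1,D2): r = (0.995550589720, 0.794279213914)
        C2 vs (D1,D2): r = (-0.521485452053, 0.014678923793)
        """
        recs = prioritise(toy_dataset, ["D1", "D2"], ["C1", "C2"], threshold=0.5)
        assert recs.loc["C1", "max_abs_r"] == pytest.approx(0.995550589720, abs=1e-9)
        assert recs.loc["C1", "sum_above_threshold"] == pytest.approx(
            1.789829803634, abs=1e-9
        )
        assert recs.loc["C2", "max_abs_r"] == pytest.approx(0.521485452053, abs=1e-9)
        assert recs.loc["C2", "sum_above_threshold"] == pytest.approx(
            0.521485452053, abs=1e-9
        )
        assert bool(recs.loc["C1", "prioritised"]) and bool(recs.loc["C2", "prioritised"])

    def test_candidate_identical_to_disease_gene(self, toy_dataset):
        dup = toy_dataset.expr.loc[["D1"]].rename(index={"D1": "CD"})
        expr = pd.concat([toy_dataset.expr, dup])
        ds = make_dataset(expr.to_numpy(), list(expr.index), list(toy_dataset.meta["donor_id"]))
        recs = prioritise(ds, ["D1"], ["CD"], threshold=0.99)
        assert recs.loc["CD", "max_abs_r"] == pytest.approx(1.0)
        assert bool(recs.loc["CD", "prioritised"])

    def test_threshold_comparison_is_strict(self, toy_dataset):
        recs = prioritise(toy_dataset, ["D1"], ["C1"], threshold=0.5)
        exact = recs.loc["C1", "max_abs_r"]
        recs2 = prioritise(toy_dataset, ["D1"], ["C1"], threshold=float(exact))
        assert not bool(recs2.loc["C1", "prioritised"])

    def test_absent_candidate_marked_untestable(self, toy_dataset):
        recs = prioritise(toy_dataset, ["D1"], ["C1", "GHOST"], threshold=0.5)
        assert not bool(recs.loc["GHOST", "testable"])
        assert np.isnan(recs.loc["GHOST", "max_abs_r"])
        assert bool(recs.loc["C1", "testable"])


class TestRunPrioritisation:
    def test_composition_matches_manual_steps(self, module_sim):
        datasets, truth = module_sim
        mod = truth.module_genes[0]
        noise = [g for g in truth.genes if g not in mod][:45]
        bundle = GeneSetBundle(
            disease=frozenset(mod[:5]), candidates=frozenset(mod[5:] + noise)
        )
        res = run_prioritisation([datasets[0]], bundle, proportion=0.2, B=200, seed=9)
        dp = res.per_dataset[datasets[0].name]

        # manual: same child stream as run_prioritisation derives
        child = np.random.SeedSequence(9).spawn(1)[0]
        null = sample_null(
            datasets[0],
            bundle.disease,
            set_size=50,
            B=200,
            seed=np.random.default_rng(child),
            exclude=bundle.candidates,
        )
        thr = threshold_from_null(null, 0.2)
        recs = prioritise(datasets[0], bundle.disease, sorted(bundle.candidates), thr)
        assert dp.threshold == pytest.approx(thr)
        pd.testing.assert_frame_equal(dp.records, recs)

    def test_determinism(self, module_sim):
        datasets, truth = module_sim
        mod = truth.module_genes[0]
        bundle = GeneSetBundle(
            disease=frozenset(mod[:5]),
            candidates=frozenset(mod[5:] + [g for g in truth.genes if g not in mod][:20]),
        )
        r1 = run_prioritisation(datasets, bundle, B=100, seed=5)
        r2 = run_prioritisation(datasets, bundle, B=100, seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert r1.thresholds == r2.thresholds

    def test_module_candidates_reach_full_consensus(self, module_sim):
        datasets, truth = module_sim
        mod = truth.module_genes[0]
        bundle = GeneSetBundle(
            disease=frozenset(mod[:5]),
            candidates=frozenset(mod[5:] + [g for g in truth.genes if g not in mod][:20]),
        )
        res = run_prioritisation(datasets, bundle, proportion=0.2, B=500, seed=6)
        assert all(res.table.loc[g, "consensus_count"] == 3 for g in mod[5:])

    def test_failing_dataset_skipped_with_warning(self, module_sim):
        datasets, truth = module_sim
        mod = truth.module_genes[0]
        tiny = make_dataset(
            np.random.default_rng(0).normal(size=(3, 5)),
            ["x1", "x2", "x3"], list("ABCDE"), name="tiny",
        )
        bundle = GeneSetBundle(disease=frozenset(mod[:5]), candidates=frozenset(mod[5:]))
        with pytest.warns(UserWarning, match="skipped"):
            res = run_prioritisation([datasets[0], tiny], bundle, B=50, seed=1)
        assert "tiny" not in res.per_dataset
        assert res.params["n_datasets_used"] == 1

    def test_single_dataset_pipeline_matches_unweighted_reimplementation(self):
        """With singleton donors the weighted pipeline must equal a plain
        numpy.corrcoef reimplementation of steps 1-3 (same drawn indices)."""
        rng = np.random.default_rng(11)
        n_genes, n = 20, 30
        genes = [f"g{i}" for i in range(n_genes)]
        ds = make_dataset(rng.normal(size=(n_genes, n)), genes, [f"d{i}" for i in range(n)])
        disease = ["g0", "g1"]
        cands = ["g2", "g3", "g4"]
        null = sample_null(ds, disease, set_size=3, B=50, seed=13, exclude=cands)
        thr = threshold_from_null(null, 0.2)
        recs = prioritise(ds, disease, cands, thr)

        # independent unweighted reimplementation of max |r|
        C = np.corrcoef(ds.expr.to_numpy())
        idx = {g: i for i, g in enumerate(ds.genes)}
        for c in cands:
            expected = max(abs(C[idx[c.upper()], idx[d.upper()]]) for d in disease)
            assert recs.loc[c.upper(), "max_abs_r"] == pytest.approx(expected, abs=1e-12)
        # threshold is a value from the pooled null at the inverse-ECDF position
        v = np.sort(null.values)
        assert thr == v[int(np.ceil(0.8 * v.size)) - 1]


class TestConsensusAndRanking:
    def _result_table(self):
        t = pd.DataFrame(
            {
                "gene": ["A", "B", "C", "D"],
                "consensus_count": [3, 1, 1, 0],
                "testable_datasets": [3, 3, 2, 3],
                "total_sum_above_threshold": [5.0, 2.4, 1.1, 0.0],
            }
        )
        return t

    def test_rank_orders_by_count_then_sum_then_name(self):
        ranked = rank_candidates(self._result_table())
        assert list(ranked["gene"]) == ["A", "B", "C", "D"]
        tie = pd.DataFrame(
            {
                "gene": ["Z", "A"],
                "consensus_count": [2, 2],
                "testable_datasets": [3, 3],
                "total_sum_above_threshold": [1.0, 1.0],
            }
        )
        assert list(rank_candidates(tie)["gene"]) == ["A", "Z"]

    def test_consensus_filter_and_nesting(self, module_sim):
        datasets, truth = module_sim
        mod = truth.module_genes[0]
        bundle = GeneSetBundle(
            disease=frozenset(mod[:5]),
            candidates=frozenset(mod[5:] + [g for g in truth.genes if g not in mod][:30]),
        )
        res = run_prioritisation(datasets, bundle, B=200, seed=8)
        sets = [consensus_filter(res, k) for k in (1, 2, 3)]
        assert sets[2] <= sets[1] <= sets[0]
        assert consensus_filter(res, 2) == frozenset(
            res.table.index[res.table["consensus_count"] >= 2]
        )

    def test_consensus_counts_bounded_by_testable(self, module_sim):
        datasets, truth = module_sim
        mod = truth.module_genes[0]
        bundle = GeneSetBundle(
            disease=frozenset(mod[:5]),
            candidates=frozenset(mod[5:] + ["NOT_A_GENE"]),
        )
        res = run_prioritisation(datasets, bundle, B=100, seed=3)
        t = res.table
        assert (t["consensus_count"] <= t["testable_datasets"]).all()
        assert t.loc["NOT_A_GENE", "testable_datasets"] == 0
        assert t.loc["NOT_A_GENE", "consensus_count"] == 0


class TestCalibration:
    def test_mean_prioritised_fraction_tracks_proportion(self):
        """Step 2 contract: on independent data ~proportion of random
        candidates clear the threshold on average (quick 12-replicate check;
        the full-scale version lives in the acceptance suite)."""
        from coexprior import simulate_null

        fracs = []
        for rep in range(12):
            ds = simulate_null(n_genes=300, n_samples=60, seed=500 + rep)
            rng = np.random.default_rng(rep)
            picks = rng.choice(ds.n_genes, size=60, replace=False)
            genes = np.array(ds.genes)
            bundle = GeneSetBundle(
                disease=frozenset(genes[picks[:10]]),
                candidates=frozenset(genes[picks[10:]]),
            )
            res = run_prioritisation([ds], bundle, proportion=0.2, B=400, seed=rep)
            dp = next(iter(res.per_dataset.values()))
            fracs.append(dp.records["prioritised"].mean())
        assert np.mean(fracs) == pytest.approx(0.2, abs=0.05)
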