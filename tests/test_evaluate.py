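import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexcopula.evaluate import (
    AssociationMatrix,
    EvalRecord,
    assoc_matrix,
    compare_families,
    distance_correlation,
    fasano_franceschini_test,
    frobenius_error,
    pca_embed,
    project,
    run_benchmark,
    two_stage_means,
)
from coexcopula.simulate import generate_truth


def _assoc(values, measure="pearson"):
    return AssociationMatrix(measure=measure, values=np.asarray(values, dtype=float))


class TestAssocMatrix:
    def test_perfect_linear_pair(self):
        x = np.arange(1, 101, dtype=float)
        data = np.vstack([x, 2 * x])
        for measure in ("pearson", "spearman", "distance_correlation"):
            vals = assoc_matrix(data, measure).values
            assert vals[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(size=(2, 2000))
        for measure in ("pearson", "spearman", "kendall", "bicor",
                        "distance_correlation"):
            assert abs(assoc_matrix(data, measure).values[0, 1]) < 0.1
        mi = assoc_matrix(data, "mutual_information").values[0, 1]
        assert mi < 0.05

    def test_kendall_elliptical_closed_form(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((10_000, 2))
        z[:, 1] = 0.5 * z[:, 0] + np.sqrt(1 - 0.25) * z[:, 1]
        tau = assoc_matrix(z.T, "kendall").values[0, 1]
        assert tau == pytest.approx(2 / np.pi * np.arcsin(0.5), abs=0.03)

    def test_constant_gene_zeroed_not_nan(self):
        data = np.vstack([np.full(50, 3.0), np.arange(50, dtype=float)])
        for measure in ("pearson", "spearman", "kendall", "bicor",
                        "distance_correlation"):
            vals = assoc_matrix(data, measure).values
            assert np.all(np.isfinite(vals))
            assert vals[0, 1] == 0.0

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            assoc_matrix(np.ones((2, 5)), "pearson")

    def test_symmetry_and_diagonal(self):
        truth = generate_truth(m=5, n=300, rng_seed=3)
        for measure in ("pearson", "bicor", "mutual_information"):
            vals = assoc_matrix(truth.counts, measure).values
            assert np.allclose(vals, vals.T)
            if measure != "mutual_information":
                assert np.allclose(np.diag(vals), 1.0)


class TestDistanceCorrelation:
    def test_independent_is_small(self):
        # the sample dcor has a positive O(n^-1/2) bias under the null,
        # so the threshold is checked at a moderately large n
        rng = np.random.default_rng(5)
        assert distance_correlation(rng.uniform(size=2000), rng.uniform(size=2000)) < 0.1

    def test_nonlinear_dependence_detected(self):
        x = np.linspace(-1, 1, 500)
        y = x**2  # pearson ~ 0 but dcor is large
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.05
        assert distance_correlation(x, y) > 0.3


class TestFrobeniusError:
    def test_identity_is_zero(self):
        M = _assoc(np.eye(3))
        assert frobenius_error(M, M) == 0.0

    def test_symmetric_pair_arithmetic(self):
        a = np.eye(3)
        b = a.copy()
        b[0, 1] = b[1, 0] = 0.3
        assert frobenius_error(_assoc(a), _assoc(b)) == pytest.approx(
            np.sqrt(0.09 + 0.09)
        )

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(7)
        A = rng.uniform(-1, 1, size=(5, 5))
        A = (A + A.T) / 2
        B = rng.uniform(-1, 1, size=(5, 5))
        B = (B + B.T) / 2
        brute = 0.0
        for i in range(5):
            for j in range(5):
                brute += (A[i, j] - B[i, j]) ** 2
        assert frobenius_error(_assoc(A), _assoc(B)) == pytest.approx(
            np.sqrt(brute), abs=1e-12
        )

    def test_metric_properties(self):
        rng = np.random.default_rng(8)
        mats = []
        for _ in range(3):
            M = rng.uniform(-1, 1, size=(4, 4))
            mats.append(_assoc((M + M.T) / 2))
        a, b, c = mats
        assert frobenius_error(a, b) >= 0
        assert frobenius_error(a, b) == frobenius_error(b, a)
        assert frobenius_error(a, c) <= frobenius_error(a, b) + frobenius_error(b, c)

    def test_mismatch_rejected(self):
        with pytest.raises(ValueError):
            frobenius_error(_assoc(np.eye(2)), _assoc(np.eye(3)))
        with pytest.raises(ValueError):
            frobenius_error(_assoc(np.eye(2)), _assoc(np.eye(2), "spearman"))


class TestPcaEmbed:
    def test_self_projection_reproduces_scores(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((40, 6))
        loadings, scores = pca_embed(X, 2)
        assert np.allclose(project(loadings, X), scores)

    def test_variance_ordering(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((100, 5)) * np.array([3, 1, 1, 1, 1])
        _, scores = pca_embed(X, 3)
        v = scores.var(axis=0)
        assert v[0] >= v[1] >= v[2]

    def test_spiked_block_concentrates_loadings(self):
        rng = np.random.default_rng(11)
        base = rng.standard_normal((300, 1))
        block = base @ np.ones((1, 3)) + 0.2 * rng.standard_normal((300, 3))
        noise = rng.standard_normal((300, 3))
        X = np.hstack([block, noise])
        loadings, _ = pca_embed(X, 1)
        w = np.abs(loadings.components[:, 0])
        assert w[:3].sum() / w[3:].sum() > 2

    def test_rank_check(self):
        X = np.outer(np.arange(10.0), np.ones(4))
        with pytest.raises(ValueError):
            pca_embed(X, 3)


class TestFasanoFranceschini:
    def test_identical_samples(self):
        rng = np.random.default_rng(12)
        A = rng.standard_normal((30, 2))
        res = fasano_franceschini_test(A, A.copy(), 50, rng_seed=0)
        assert res.d_stat == 0.0
        assert res.p_value == 1.0

    def test_p_value_floor(self):
        rng = np.random.default_rng(13)
        A = rng.standard_normal((50, 2))
        B = rng.standard_normal((50, 2)) + 5
        res = fasano_franceschini_test(A, B, 99, rng_seed=1)
        assert res.p_value >= 1 / (99 + 1)

    def test_shift_alternative_detected(self):
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            A = rng.standard_normal((100, 2))
            B = rng.standard_normal((100, 2)) + 3
            assert fasano_franceschini_test(A, B, 99, rng_seed=s).p_value < 0.02

    def test_three_dimensional_support(self):
        rng = np.random.default_rng(14)
        A = rng.standard_normal((60, 3))
        B = rng.standard_normal((60, 3)) + 2.5
        assert fasano_franceschini_test(A, B, 99, rng_seed=2).p_value < 0.05
        with pytest.raises(NotImplementedError):
            fasano_franceschini_test(rng.standard_normal((20, 4)),
                                     rng.standard_normal((20, 4)), 10, 0)

    def test_null_super_uniformity_small_battery(self):
        rej = 0
        for s in range(50):
            rng = np.random.default_rng(1000 + s)
            A = rng.standard_normal((100, 2))
            B = rng.standard_normal((100, 2))
            rej += fasano_franceschini_test(A, B, 60, rng_seed=s).p_value <= 0.05
        assert rej / 50 <= 0.12


class TestBenchmark:
    def _records(self, values):
        recs = []
        for fam, split, rep, val in values:
            recs.append(EvalRecord("ds", fam, split, rep, "frobenius_pearson", val))
        return recs

    def test_two_stage_average_order(self):
        recs = self._records([
            ("f", 0, 1, 1.0), ("f", 0, 2, 3.0), ("f", 1, 1, 5.0), ("f", 1, 2, 7.0),
        ])
        out = two_stage_means(recs)
        assert out.value.iloc[0] == pytest.approx(4.0)

    def test_degenerate_single_pass(self, hvg_margin_spec):
        truth = generate_truth(m=4, n=200, margin_spec=hvg_margin_spec, rng_seed=15)
        recs = run_benchmark(
            truth.counts, ["gaussian"],
            {"n_splits": 1, "n_replicates": 1, "measures": ["pearson"],
             "n_permutations": 20, "seed": 3},
        )
        assert len(recs) == 2  # one frobenius + one ff record
        assert {r.metric_name for r in recs} == {"frobenius_pearson", "ff_pvalue"}

    def test_reproducible_stream(self, hvg_margin_spec):
        truth = generate_truth(m=4, n=200, margin_spec=hvg_margin_spec, rng_seed=16)
        cfg = {"n_splits": 2, "n_replicates": 2, "measures": ["pearson"],
               "n_permutations": 20, "seed": 4}
        a = run_benchmark(truth.counts, ["independence", "gaussian"], cfg)
        b = run_benchmark(truth.counts, ["independence", "gaussian"], cfg)
        assert [r.__dict__ for r in a] == [r.__dict__ for r in b]

    def test_independence_has_larger_error_on_correlated_truth(self, hvg_margin_spec):
        for s in range(3):
            truth = generate_truth(
                m=5, n=600, margin_spec=hvg_margin_spec,
                dependence_spec={"kind": "exchangeable", "rho": 0.6},
                copula_family="gaussian", rng_seed=600 + s,
            )
            recs = run_benchmark(
                truth.counts, ["independence", "gaussian"],
                {"n_splits": 1, "n_replicates": 3, "measures": ["pearson"],
                 "n_permutations": 10, "seed": s},
            )
            tm = two_stage_means(recs).set_index("family_tag")
            tm = tm[tm.metric_name == "frobenius_pearson"]
            assert tm.loc["independence", "value"] > tm.loc["gaussian", "value"]

    def test_module_hook_records(self, hvg_margin_spec):
        truth = generate_truth(m=3, n=120, margin_spec=hvg_margin_spec, rng_seed=17)
        recs = run_benchmark(
            truth.counts, ["independence"],
            {"n_splits": 1, "n_replicates": 1, "measures": [],
             "n_permutations": 10, "seed": 5},
            module_hook=lambda train, test, syn: {"n_syn_cells": syn.n_cells},
        )
        hook = [r for r in recs if r.metric_name == "n_syn_cells"]
        assert len(hook) == 1 and hook[0].value == 60


class TestCompareFamilies:
    def _records_from_table(self, table):
        recs = []
        for ds, row in table.items():
            for fam, val in row.items():
                recs.append(EvalRecord(ds, fam, 0, 1, "m", val))
        return recs

    def test_identical_families_give_p_one(self):
        table = {f"d{i}": {"a": float(i), "b": float(i)} for i in range(8)}
        out = compare_families(self._records_from_table(table), "m")
        row = out.iloc[0]
        assert row.p_raw == 1.0 and row.effect_size == 0.0

    def test_complete_dominance_effect_one(self):
        table = {f"d{i}": {"lo": float(i), "hi": float(i) + 1} for i in range(10)}
        out = compare_families(self._records_from_table(table), "m")
        assert abs(out.iloc[0].effect_size) == pytest.approx(1.0)

    def test_signed_rank_matches_exact_enumeration(self):
        diffs = np.array([1.0, 2.0, 3.0, 4.0, 5.0, -1.0])
        # exact two-sided p: enumerate all 2^6 sign assignments of |d|
        ranks = stats.rankdata(np.abs(diffs))
        w_obs = ranks[diffs > 0].sum()
        total = ranks.sum()
        stat_obs = min(w_obs, total - w_obs)
        count = 0
        for signs in itertools.product([0, 1], repeat=6):
            w = sum(r for r, s in zip(ranks, signs) if s)
            if min(w, total - w) <= stat_obs:
                count += 1
        p_exact = count / 64
        table = {f"d{i}": {"a": float(d), "b": 0.0} for i, d in enumerate(diffs)}
        out = compare_families(self._records_from_table(table), "m")
        assert out.iloc[0].p_raw == pytest.approx(p_exact, abs=1e-12)

    def test_bh_adjustment_matches_step_up_definition(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.04, 0.03, 0.005])
        adjusted = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adjusted, [0.02, 0.04, 0.04, 0.02])
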