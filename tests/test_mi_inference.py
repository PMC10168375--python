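import numpy as np
import pytest
from scipy import stats

from tissue import (
    de_scan,
    mi_combine_pvalues,
    mi_pvalue_hook,
    mi_ttest,
    sample_imputations,
)
from tissue.uncertainty import VariabilityMatrix

from conftest import make_pred
from test_intervals import trivial_model


class FakeEnsemble:
    """Ensemble with explicitly specified imputation matrices."""

    def __init__(self, matrices, gene_ids=None):
        self.matrices = [np.asarray(m, dtype=float) for m in matrices]
        self.D = len(matrices)
        self.pred = make_pred(self.matrices[0], gene_ids)

    def imputation(self, d):
        return self.matrices[d]


class TestSampleImputations:
    def test_zero_scores_reproduce_prediction(self, rng):
        model = trivial_model([0.0] * 150, [0.0] * 150)
        pred = make_pred(rng.uniform(0, 5, (8, 3)))
        U = VariabilityMatrix(1.0 + rng.uniform(0, 1, (8, 3)))
        ens = sample_imputations(pred, U, model, D=5, seed=0)
        for d in range(5):
            np.testing.assert_array_equal(ens.imputation(d), pred.values)

    def test_unit_scores_shift_by_twice_variability(self, rng):
        model = trivial_model([1.0] * 150, [1.0] * 150)
        pred = make_pred(np.full((6, 2), 10.0))
        U = VariabilityMatrix(np.full((6, 2), 2.0))
        ens = sample_imputations(pred, U, model, D=4, seed=1)
        for d in range(1, 4):
            vals = np.unique(ens.imputation(d))
            assert set(vals) <= {8.0, 12.0}

    def test_lower_draws_never_exceed_prediction(self, rng):
        model = trivial_model([0.5] * 200, [0.0] * 200)
        pred = make_pred(rng.uniform(0, 5, (10, 2)))
        U = VariabilityMatrix(np.full((10, 2), 1.5))
        ens = sample_imputations(pred, U, model, D=6, seed=2)
        for d in range(1, 6):
            assert np.all(ens.imputation(d) <= pred.values + 1e-12)

    def test_requires_at_least_two_imputations(self, rng):
        model = trivial_model([0.0] * 150, [0.0] * 150)
        pred = make_pred(rng.uniform(size=(4, 2)))
        with pytest.raises(ValueError):
            sample_imputations(pred, VariabilityMatrix(np.ones((4, 2))),
                               model, D=1)

    def test_symmetric_sets_center_on_prediction(self, rng):
        # symmetric scores with symmetric signs: mean over imputations -> Xhat
        scores = list(rng.uniform(0.2, 1.0, 150))
        model = trivial_model(scores, scores)
        pred = make_pred(rng.uniform(0, 5, (5, 4)))
        U = VariabilityMatrix(1.0 + rng.uniform(0, 1, (5, 4)))
        ens = sample_imputations(pred, U, model, D=400, seed=3)
        mean = np.mean([ens.imputation(d) for d in range(1, ens.D)], axis=0)
        halfwidth = np.mean(scores) * U.values
        np.testing.assert_allclose(mean, pred.values,
                                   atol=3 * halfwidth.max() / np.sqrt(399))

    def test_truncation_excludes_extreme_scores(self):
        # one huge outlier in 200 scores lies above the 80% quantile
        scores = [0.1] * 199 + [50.0]
        model = trivial_model(scores, scores)
        pred = make_pred(np.zeros((4, 4)))
        U = VariabilityMatrix(np.ones((4, 4)))
        ens = sample_imputations(pred, U, model, D=100, seed=4)
        for d in range(1, 50):
            assert np.all(np.abs(ens.imputation(d)) <= 0.1 + 1e-12)


class TestMITtest:
    def test_two_imputation_toy_against_step_by_step_oracle(self):
        m1 = np.array([[5.0], [6.0], [1.0], [2.0]])
        m2 = np.array([[7.0], [8.0], [1.0], [2.0]])
        res = mi_ttest(FakeEnsemble([m1, m2]), 0, [0, 1], [2, 3])

        # independent evaluation of the pooled-imputation formulas
        def classic(m):
            a, b = m[:2, 0], m[2:, 0]
            mu = a.mean() - b.mean()
            pooled = (a.var(ddof=1) + b.var(ddof=1)) / 2
            return mu, (0.5 + 0.5) * pooled

        mus, s2s = zip(*(classic(m) for m in (m1, m2)))
        D = 2
        mu_MI = np.mean(mus)
        s_W2 = np.mean(s2s)
        s_B2 = np.var(mus, ddof=1)
        s_MI2 = s_W2 + (1 + 1 / D) * s_B2
        t = mu_MI / np.sqrt(s_MI2)
        df = (D - 1) * (1 + D * s_W2 / ((D + 1) * s_B2)) ** 2
        p = 2 * stats.t.sf(abs(t), df)

        assert mu_MI == 5.0 and s_B2 == 2.0  # hand arithmetic
        assert res.mu_MI == pytest.approx(mu_MI)
        assert res.s_W2 == pytest.approx(s_W2)
        assert res.s_B2 == pytest.approx(s_B2)
        assert res.s_MI2 == pytest.approx(s_MI2)
        assert res.t_MI == pytest.approx(t)
        assert res.df == pytest.approx(df)
        assert res.p == pytest.approx(p)

    def test_identical_imputations_fall_back_to_classical_ttest(self, rng):
        m = rng.normal(0, 1, (20, 1))
        res = mi_ttest(FakeEnsemble([m, m, m]), 0, np.arange(10),
                       np.arange(10, 20))
        t_ref, p_ref = stats.ttest_ind(m[:10, 0], m[10:, 0])
        assert res.s_B2 == 0.0
        assert res.t_MI == pytest.approx(t_ref)
        assert res.p == pytest.approx(p_ref)
        assert res.df == 18

    def test_constant_data_gives_p_one(self):
        m = np.ones((8, 1))
        res = mi_ttest(FakeEnsemble([m, m]), 0, [0, 1, 2, 3], [4, 5, 6, 7])
        assert res.p == 1.0

    def test_variance_inflation_never_negative(self, rng):
        mats = [rng.normal(0, 1, (16, 1)) for _ in range(5)]
        res = mi_ttest(FakeEnsemble(mats), 0, np.arange(8), np.arange(8, 16))
        assert res.s_MI2 >= res.s_W2 >= 0
        assert 0 <= res.p <= 1

    def test_overlapping_groups_rejected(self, rng):
        m = rng.normal(size=(10, 1))
        with pytest.raises(ValueError):
            mi_ttest(FakeEnsemble([m, m]), 0, [0, 1, 2], [2, 3, 4])

    def test_null_false_positive_rate_not_inflated(self, rng):
        """Under an exchangeable null with genuine MI perturbation the test
        must not reject more often than its nominal level."""
        model = trivial_model(list(rng.uniform(0.1, 0.5, 200)),
                              list(rng.uniform(0.1, 0.5, 200)))
        reps, hits = 200, 0
        for r in range(reps):
            pred = make_pred(rng.normal(5, 1, (16, 1)))
            U = VariabilityMatrix(np.ones((16, 1)))
            ens = sample_imputations(pred, U, model, D=8, seed=r)
            res = mi_ttest(ens, 0, np.arange(8), np.arange(8, 16))
            hits += res.p <= 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert hits / reps <= 0.05 + 3 * se

    def test_fallback_pvalues_uniform_under_null(self, rng):
        """With degenerate (identical) imputations the p-value reduces to the
        classical t-test's and is uniform under the null."""
        ps = []
        for _ in range(200):
            m = rng.normal(0, 1, (20, 1))
            ps.append(
                mi_ttest(FakeEnsemble([m, m]), 0, np.arange(10),
                         np.arange(10, 20)).p
            )
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCombinePValues:
    def test_all_half_gives_half(self):
        assert mi_combine_pvalues([0.5, 0.5, 0.5]).p_MI == pytest.approx(0.5)

    def test_constant_list_is_fixed_point(self):
        for p0 in (0.01, 0.2, 0.9):
            assert mi_combine_pvalues([p0] * 4).p_MI == pytest.approx(p0)

    def test_known_example(self):
        # independent normal-quantile oracle evaluation
        p = np.array([0.01, 0.04, 0.1])
        z = stats.norm.ppf(p)
        expect = stats.norm.cdf(z.mean() / np.sqrt(1 + z.var(ddof=1)))
        got = mi_combine_pvalues(p)
        assert got.p_MI == pytest.approx(expect)
        assert got.p_MI == pytest.approx(0.057, abs=5e-4)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(0.001, 0.999, 7)
        a = mi_combine_pvalues(p).p_MI
        b = mi_combine_pvalues(p[::-1]).p_MI
        assert a == pytest.approx(b)

    def test_boundary_pvalues_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = mi_combine_pvalues([0.0, 0.5])
        assert 0 <= out.p_MI <= 1


def test_pvalue_hook_combines_per_imputation_tests(rng):
    mats = [rng.normal(0, 1, (10, 2)) for _ in range(4)]
    ens = FakeEnsemble(mats)
    out = mi_pvalue_hook(ens, lambda M: stats.ttest_1samp(M[:, 0], 0).pvalue)
    expect = mi_combine_pvalues(
        [stats.ttest_1samp(m[:, 0], 0).pvalue for m in mats]
    )
    assert out.p_MI == pytest.approx(expect.p_MI)


class TestDeScan:
    def _null_ensemble(self, rng, n=30, p=40, D=6):
        model = trivial_model(list(rng.uniform(0.05, 0.3, 200)),
                              list(rng.uniform(0.05, 0.3, 200)))
        pred = make_pred(rng.normal(5, 1, (n, p)))
        U = VariabilityMatrix(np.ones((n, p)))
        return sample_imputations(pred, U, model, D=D, seed=11)

    def test_planted_marker_detected(self, rng):
        model = trivial_model(list(rng.uniform(0.05, 0.3, 200)),
                              list(rng.uniform(0.05, 0.3, 200)))
        values = rng.normal(5, 1, (40, 20))
        labels = np.array(["A"] * 20 + ["B"] * 20)
        values[:20, 0] += 8.0  # strong label-exclusive marker
        pred = make_pred(values)
        U = VariabilityMatrix(np.ones((40, 20)))
        ens = sample_imputations(pred, U, model, D=10, seed=5)
        tab = de_scan(ens, labels, mode="ttest", fdr=0.05)
        row = tab[(tab.gene == "g0") & (tab.label == "A")].iloc[0]
        assert row.significant
        assert row.statistic > 0

    def test_null_false_calls_bounded(self, rng):
        ens = self._null_ensemble(rng)
        labels = np.array(["A"] * 15 + ["B"] * 15)
        tab = de_scan(ens, labels, mode="ttest", fdr=0.05)
        n_tests = len(tab)
        se = np.sqrt(n_tests * 0.05 * 0.95)
        assert tab.significant.sum() <= 0.05 * n_tests + 3 * se

    def test_rank_mode_detects_shift(self, rng):
        model = trivial_model(list(rng.uniform(0.05, 0.2, 200)),
                              list(rng.uniform(0.05, 0.2, 200)))
        values = rng.normal(5, 1, (30, 10))
        values[:15, 2] += 6.0
        labels = np.array(["A"] * 15 + ["B"] * 15)
        ens = sample_imputations(
            make_pred(values), VariabilityMatrix(np.ones((30, 10))),
            model, D=6, seed=6,
        )
        tab = de_scan(ens, labels, mode="rank", fdr=0.05,
                      alternative="greater")
        row = tab[(tab.gene == "g2") & (tab.label == "A")].iloc[0]
        assert row.q <= 0.05

    def test_small_label_skipped_with_warning(self, rng):
        ens = self._null_ensemble(rng, n=21)
        labels = np.array(["A"] * 10 + ["B"] * 10 + ["C"])
        with pytest.warns(UserWarning, match="'C'"):
            tab = de_scan(ens, labels)
        assert set(tab.label) == {"A", "B"}

    def test_default_fdr_threshold(self):
        import inspect

        assert inspect.signature(de_scan).parameters["fdr"].default == 0.05
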