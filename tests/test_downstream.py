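import numpy as np
import pytest
from sklearn.decomposition import PCA

from tissue import (
    eval_harness,
    filter_cells,
    otsu_threshold,
    stability_score,
    uncertainty_scores,
    weighted_pca,
    wpca_weights,
)
from tissue.intervals import IntervalSet

from conftest import make_pred


def interval_from_widths(widths, alpha=0.33):
    widths = np.asarray(widths, dtype=float)
    return IntervalSet(alpha=alpha, lower=np.zeros_like(widths),
                       upper=widths, q_lower={}, q_upper={})


class TestUncertaintyScores:
    def test_equal_widths_score_zero(self):
        iv = interval_from_widths(np.full((5, 3), 2.0))
        np.testing.assert_allclose(uncertainty_scores(iv), 0.0)

    def test_doubled_width_cell_has_largest_score(self, rng):
        w = rng.uniform(1.0, 2.0, (10, 6))
        w[3] *= 2.0
        scores = uncertainty_scores(interval_from_widths(w))
        assert np.argmax(scores) == 3
        assert scores[3] > np.max(np.delete(scores, 3))

    def test_gene_relabel_invariance(self, rng):
        w = rng.uniform(1.0, 2.0, (8, 5))
        a = uncertainty_scores(interval_from_widths(w))
        b = uncertainty_scores(interval_from_widths(w[:, ::-1]))
        np.testing.assert_allclose(a, b)

    def test_expression_standardization_variant(self, rng):
        w = rng.uniform(1.0, 2.0, (8, 4))
        pred = make_pred(rng.uniform(3.0, 6.0, (8, 4)))
        iv = interval_from_widths(w)
        out = uncertainty_scores(iv, pred=pred, standardize="expression")
        mu = pred.values.mean(axis=0)
        sd = pred.values.std(axis=0)
        np.testing.assert_allclose(out, ((w - mu) / sd).mean(axis=1))


def brute_otsu(values, n_bins=256):
    """Exhaustive scan over interior bin edges (independent oracle)."""
    v = np.asarray(values, dtype=float)
    if v.min() == v.max():
        return np.inf
    edges = np.linspace(v.min(), v.max(), n_bins + 1)[1:-1]
    results = []
    for e in edges:
        lo, hi = v[v <= e], v[v > e]
        if lo.size == 0 or hi.size == 0:
            continue
        var = (lo.size / v.size) * (hi.size / v.size) * (
            lo.mean() - hi.mean()
        ) ** 2
        results.append((e, var))
    if not results:
        return np.inf
    best_var = max(var for _, var in results)
    tied = [e for e, var in results if var >= best_var - 1e-12 * best_var]
    return tied[len(tied) // 2]


class TestOtsu:
    def test_bimodal_split(self):
        thr = otsu_threshold([0, 0, 0, 10, 10])
        assert 0 < thr < 10
        assert np.sum(np.array([0, 0, 0, 10, 10]) > thr) == 2

    def test_constant_input_gives_no_split(self):
        assert otsu_threshold([3.0, 3.0, 3.0]) == np.inf

    def test_two_pair_instance(self):
        assert 2 < otsu_threshold([1, 2, 8, 9]) < 8

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(30):
            v = [rng.uniform(0, 1, 25), rng.normal(0, 1, 40),
                 np.r_[rng.normal(0, 0.2, 30), rng.normal(5, 0.2, 10)]][
                int(rng.integers(3))
            ]
            assert otsu_threshold(v) == pytest.approx(brute_otsu(v))


class TestFilterCells:
    def test_bimodal_scores_remove_high_mode(self, rng):
        scores = np.r_[rng.normal(0, 0.05, 90), rng.normal(5, 0.05, 10)]
        res = filter_cells(scores)
        assert len(res.removed) == 10
        assert set(res.removed) == {str(i) for i in range(90, 100)}

    def test_uniform_class_untouched_by_other_class(self, rng):
        scores = np.r_[np.full(20, 1.0), rng.normal(0, 1, 20)]
        labels = np.array(["u"] * 20 + ["v"] * 20)
        res = filter_cells(scores, labels=labels)
        assert all(int(c) >= 20 for c in res.removed)

    def test_constant_scores_remove_nothing(self):
        res = filter_cells(np.full(30, 2.0))
        assert res.removed == []

    def test_singleton_class_never_removed(self, rng):
        scores = np.r_[rng.normal(0, 1, 10), 100.0]
        labels = np.array(["a"] * 10 + ["b"])
        with pytest.warns(UserWarning, match="single cell"):
            res = filter_cells(scores, labels=labels)
        assert "10" not in res.removed

    def test_removal_shrinks_with_high_mode(self, rng):
        base = rng.normal(0, 0.05, 90)
        big = filter_cells(np.r_[base, rng.normal(5, 0.05, 10)])
        small = filter_cells(np.r_[base, rng.normal(5, 0.05, 4),
                                   rng.normal(0, 0.05, 6)])
        assert len(small.removed) <= len(big.removed)


class TestWPCAWeights:
    def test_equal_widths_all_high(self):
        iv = interval_from_widths(np.full((6, 3), 1.5))
        w = wpca_weights(iv, scheme="binary").weights
        np.testing.assert_array_equal(w, 1.0)

    def test_binary_codomain(self, rng):
        iv = interval_from_widths(rng.uniform(0.5, 3.0, (12, 4)))
        w = wpca_weights(iv, scheme="binary").weights
        assert set(np.unique(w)) <= {0.1, 1.0}

    def test_bottom_fifth_downweighted(self):
        widths = np.array([[1, 1, 1, 1, 1, 1, 1, 1, 50, 60]], dtype=float).T
        w = wpca_weights(interval_from_widths(widths), "binary").weights
        np.testing.assert_array_equal(w[:8, 0], 1.0)
        np.testing.assert_array_equal(w[8:, 0], 0.1)

    def test_log_scheme_positive(self, rng):
        iv = interval_from_widths(rng.uniform(0.5, 3.0, (10, 3)))
        w = wpca_weights(iv, scheme="log").weights
        assert np.all(w > 0)


class TestWeightedPCA:
    def test_uniform_weights_reduce_to_pca(self, rng):
        X = rng.normal(0, 1, (30, 6)) @ rng.normal(0, 1, (6, 6))
        P, emb = weighted_pca(X, np.ones_like(X), n_components=3)
        ref = PCA(n_components=3).fit(X)
        for r in range(3):
            cos = abs(P[r] @ ref.components_[r]) / (
                np.linalg.norm(P[r]) * np.linalg.norm(ref.components_[r])
            )
            assert cos >= 1 - 1e-8
        ref_emb = ref.transform(X)
        for r in range(3):
            sign = np.sign(emb[:, r] @ ref_emb[:, r])
            np.testing.assert_allclose(emb[:, r], sign * ref_emb[:, r],
                                       atol=1e-8)

    def test_rank_one_data_first_component_dominates(self, rng):
        u = rng.normal(size=(20, 1))
        v = rng.normal(size=(1, 5))
        X = u @ v
        # per-cell weights keep the weighted-centered data rank one
        W = np.broadcast_to(rng.uniform(0.5, 1.5, (20, 1)), X.shape).copy()
        P, emb = weighted_pca(X, W, n_components=2)
        mu = (W * X).sum(0) / W.sum(0)
        recon = emb[:, :1] @ P[:1] + mu
        assert np.linalg.norm(recon - X) / np.linalg.norm(X) < 1e-8
        cos = abs(P[0] @ v[0]) / (np.linalg.norm(P[0]) * np.linalg.norm(v))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_downweighted_outlier_recovers_clean_axis(self, rng):
        clean = np.c_[np.linspace(-2, 2, 5)] @ np.array([[1.0, 1.0, 0.0]])
        X = clean.copy()
        X[0, 2] += 25.0  # single corrupted entry
        W = np.ones_like(X)
        axis_clean = PCA(n_components=1).fit(clean).components_[0]

        def cos_to_clean(P):
            return abs(P[0] @ axis_clean) / np.linalg.norm(P[0])

        P_unw, _ = weighted_pca(X, W, 1)
        W[0, 2] = 1e-3
        P_w, _ = weighted_pca(X, W, 1)
        assert cos_to_clean(P_w) > cos_to_clean(P_unw)

    def test_zero_weight_row_warns_and_projects(self, rng):
        X = rng.normal(size=(10, 4))
        W = np.ones_like(X)
        W[3] = 0.0
        with pytest.warns(UserWarning, match="all-zero"):
            _, emb = weighted_pca(X, W, 2)
        assert np.all(np.isfinite(emb))


class TestEvalHarness:
    def _separable(self, rng, n=60):
        X = np.r_[rng.normal(0, 0.3, (n // 2, 5)),
                  rng.normal(6, 0.3, (n // 2, 5))]
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        return X, y

    def test_separable_classes_near_perfect(self, rng):
        X, y = self._separable(rng)
        tab = eval_harness(X, y, task="classify", seed=0)
        assert dict(zip(tab.metric, tab.value))["accuracy"] >= 0.99
        tab = eval_harness(X, y, task="cluster", seed=0)
        assert tab.value[0] >= 0.99
        tab = eval_harness(X, y, task="separability", seed=0)
        assert tab.value[0] >= 0.99

    def test_shuffled_labels_give_null_ari(self, rng):
        X, y = self._separable(rng, n=100)
        aris = []
        for s in range(5):
            ys = np.random.default_rng(s).permutation(y)
            aris.append(
                eval_harness(X, ys, task="cluster", seed=s).value[0]
            )
        assert np.all(np.abs(aris) < 0.05)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            eval_harness(rng.normal(size=(10, 3)), ["a"] * 10)


class TestStabilityScore:
    def test_identical_layouts_score_zero(self, rng):
        E = rng.normal(size=(25, 2))
        s = stability_score([E, E.copy(), E.copy()])
        np.testing.assert_allclose(s.to_numpy(), 0.0, atol=1e-12)

    def test_rigid_motion_invariance(self, rng):
        E = rng.normal(size=(25, 2))
        R = np.array([[0.0, -1.0], [1.0, 0.0]])  # 90 degree rotation
        s = stability_score([E, E @ R.T + np.array([3.0, -1.0])])
        np.testing.assert_allclose(s.to_numpy(), 0.0, atol=1e-8)

    def test_jitter_increases_scores_monotonically(self, rng):
        base = rng.normal(size=(60, 2)) * 3
        medians = []
        for sigma in (0.01, 0.1, 1.0):
            layouts = [base + rng.normal(0, sigma, base.shape)
                       for _ in range(8)]
            medians.append(float(np.median(stability_score(layouts))))
        assert medians[0] < medians[1] < medians[2]

    def test_too_few_shared_cells_rejected(self, rng):
        a = rng.normal(size=(5, 2))
        b = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="shared"):
            stability_score([a, b], ids=[list("abcde"), list("vwxyz")])

    def test_partial_overlap_scores_all_cells(self, rng):
        base = rng.normal(size=(30, 2))
        ids = [str(i) for i in range(30)]
        layouts = [base, base[:20] + 0.01, base[10:] - 0.01]
        s = stability_score(
            [layouts[0], layouts[1], layouts[2]],
            ids=[ids, ids[:20], ids[10:]],
        )
        assert len(s) == 30
        assert np.isfinite(s).all()
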