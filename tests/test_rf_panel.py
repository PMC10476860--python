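"""Random-Forest panel discovery: OOB bookkeeping, permutation importance,
panel selection, proximities, PCoA, evaluation metrics, and panel transfer."""

import numpy as np
import pandas as pd
import pytest

from breathpanel.evaluation import evaluate, ppv
from breathpanel.rf_panel import (
    MarkerPanel,
    fit_rf,
    iterative_importance,
    oob_predictions,
    oob_proximity,
    oob_scores,
    pcoa,
    select_panel,
    transfer_panel,
)


def _separable(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += np.where(y == 1, 3.0, -3.0)
    return X, y


class TestFitRF:
    def test_separable_toy_has_low_oob_error(self):
        X, y = _separable()
        m = fit_rf(X, y, n_trees=200, seed=1)
        err = np.mean(oob_predictions(m) != y)
        assert err < 0.05

    def test_permuted_labels_hit_majority_baseline(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 5))
        y = np.array([0] * 56 + [1] * 24)  # 70% majority class
        m = fit_rf(X, rng.permutation(y), n_trees=200, seed=3)
        acc = np.mean(oob_predictions(m) == rng.permutation(y))
        assert abs(acc - max(np.bincount(y) / y.size)) < 0.2

    def test_fixed_seed_identical_oob_votes(self):
        X, y = _separable(seed=4)
        s1 = oob_scores(fit_rf(X, y, n_trees=100, seed=5))
        s2 = oob_scores(fit_rf(X, y, n_trees=100, seed=5))
        assert np.array_equal(s1, s2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_rf(np.zeros((10, 2)), np.zeros(10, dtype=int), n_trees=10)

    def test_every_sample_oob_somewhere(self):
        X, y = _separable(n=40, seed=6)
        m = fit_rf(X, y, n_trees=50, seed=7)
        assert m.oob_mask.any(axis=0).all()


class TestIterativeImportance:
    def _planted(self, seed, n=100, p=50):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = np.repeat([0, 1], n // 2)
        X[y == 1, 0] += 2.0  # one informative feature at 2 SD
        return X, y

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_informative_feature_ranked_first(self, seed):
        X, y = self._planted(seed)
        r = iterative_importance(X, y, n_iter=30, trees_per_iter=100, seed=seed)
        assert r.ranked_features()[0] == 0
        assert r.signs[0] == 1  # higher in the positive class

    def test_label_permutation_centers_importance_at_zero(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 20))
        y = rng.permutation(np.repeat([0, 1], 30))
        r = iterative_importance(X, y, n_iter=20, trees_per_iter=50, seed=4)
        assert abs(r.mean_importance.mean()) < 0.01

    def test_more_trees_shrink_dispersion(self):
        X, y = self._planted(5, n=80, p=10)
        r_small = iterative_importance(X, y, n_iter=15, trees_per_iter=25, seed=6)
        r_big = iterative_importance(X, y, n_iter=15, trees_per_iter=100, seed=6)
        assert r_big.draws.std(axis=0).mean() < r_small.draws.std(axis=0).mean()

    def test_dispersion_needs_two_iterations(self):
        X, y = self._planted(7)
        with pytest.raises(ValueError):
            iterative_importance(X, y, n_iter=1, trees_per_iter=10, seed=0)


class TestSelectPanel:
    def test_full_grid_returns_all_features_ranked(self):
        X, y = _separable(n=50, seed=8)
        r = iterative_importance(X, y, n_iter=5, trees_per_iter=50, seed=9)
        panel = select_panel(r, X, y, k_grid=(2,), n_trees=50, seed=0)
        assert set(panel.features) == {0, 1}
        assert panel.features == r.ranked_features()

    def test_truncation_keeps_top_by_magnitude(self):
        signed = pd.Series([0.5, -0.4, 0.3, -0.2, 0.1], index=list("abcde"))
        panel = MarkerPanel(list("abcde"), signed)
        assert panel.truncate(3).features == ["a", "b", "c"]

    def test_forced_panel_size(self):
        X, y = self._toy()
        r = iterative_importance(X, y, n_iter=3, trees_per_iter=30, seed=1)
        panel = select_panel(r, X, y, force_k=4, seed=0)
        assert len(panel) == 4

    def test_unordered_panel_rejected(self):
        signed = pd.Series([0.1, 0.9], index=["a", "b"])
        with pytest.raises(ValueError):
            MarkerPanel(["a", "b"], signed)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            MarkerPanel([], pd.Series(dtype=float))

    @staticmethod
    def _toy():
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 6))
        y = np.repeat([0, 1], 20)
        X[y == 1, 0] += 3
        return X, y


class TestProximity:
    def test_duplicated_rows_have_unit_proximity(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=(20, 3))
        X = np.vstack([base, base[:1]])  # row 20 duplicates row 0
        y = np.array([0, 1] * 10 + [0])
        m = fit_rf(X, y, n_trees=300, seed=12)
        prox, _ = oob_proximity(m)
        assert prox[0, 20] == pytest.approx(1.0)

    def test_matches_brute_force_count(self):
        """Small forest: proximity equals a direct count over stored leaf
        assignments and OOB masks (enumeration oracle)."""
        rng = np.random.default_rng(13)
        X = rng.normal(size=(12, 3))
        y = np.repeat([0, 1], 6)
        m = fit_rf(X, y, n_trees=10, seed=14)
        prox, _ = oob_proximity(m)
        leaves = m.forest.apply(m.X)
        for i in range(12):
            for j in range(i + 1, 12):
                both, same = 0, 0
                for t in range(m.n_trees):
                    if m.oob_mask[t, i] and m.oob_mask[t, j]:
                        both += 1
                        same += leaves[i, t] == leaves[j, t]
                expected = same / both if both else 0.0
                assert prox[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_bounds_diagonal(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(25, 4))
        y = rng.integers(0, 2, 25)
        y[:2] = [0, 1]
        m = fit_rf(X, y, n_trees=100, seed=16)
        prox, _ = oob_proximity(m)
        assert np.allclose(prox, prox.T)
        assert prox.min() >= 0.0 and prox.max() <= 1.0
        assert np.allclose(np.diag(prox), 1.0)


class TestPCoA:
    def test_identity_proximity_gives_equidistant_points(self):
        n = 5
        res = pcoa(np.eye(n))
        coords = res.coordinates
        dists = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        off = dists[~np.eye(n, dtype=bool)]
        assert np.allclose(off, off[0], atol=1e-8)

    def test_matches_skbio_classical_mds(self):
        """Hand-built Euclidean-embeddable proximity: coordinates match
        scikit-bio's PCoA within 1e-8 up to per-axis sign."""
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        from skbio import DistanceMatrix

        pts = np.array([[0.0, 0.0], [0.3, 0.0], [0.0, 0.4], [0.3, 0.4]])
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        prox = 1.0 - D**2  # then d = sqrt(1 - prox) reproduces D
        ours = pcoa(prox)
        ref = skbio_pcoa(DistanceMatrix(D), method="eigh")
        k = ours.coordinates.shape[1]
        ref_coords = ref.samples.to_numpy()[:, :k]
        for axis in range(k):
            a, b = ours.coordinates[:, axis], ref_coords[:, axis]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)
        assert np.allclose(
            ours.proportion_explained,
            ref.proportion_explained.to_numpy()[:k],
            atol=1e-8,
        )

    def test_fractions_non_increasing_and_sum_le_one(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(15, 8))
        y = np.repeat([0, 1], [7, 8])
        m = fit_rf(X, y, n_trees=150, seed=18)
        prox, _ = oob_proximity(m)
        res = pcoa(prox)
        assert np.all(np.diff(res.proportion_explained) <= 1e-12)
        assert res.proportion_explained.sum() <= 1.0 + 1e-12


class TestEvaluate:
    def test_perfect_and_reversed_separation(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        s = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        assert evaluate(s, y).auc_roc == pytest.approx(1.0)
        assert evaluate(s, 1 - y).auc_roc == pytest.approx(0.0)
        assert evaluate(s, y).auc_pr == pytest.approx(1.0)

    def test_auc_equals_normalized_mann_whitney_u(self):
        """Trapezoidal ROC AUC on a 20-sample toy equals U / (n1 n0)."""
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(19)
        y = np.repeat([0, 1], 10)
        s = rng.normal(size=20) + y * 0.8
        rep = evaluate(s, y)
        u = mannwhitneyu(s[y == 1], s[y == 0]).statistic
        assert rep.auc_roc == pytest.approx(u / 100.0)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(20)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.normal(size=30)
        a1 = evaluate(s, y).auc_roc
        a2 = evaluate(np.exp(2.0 * s) + 5.0, y).auc_roc
        assert a1 == pytest.approx(a2)

    def test_operating_point_anchors_specificity_from_above(self):
        y = np.array([0] * 10 + [1] * 10)
        rng = np.random.default_rng(21)
        s = np.concatenate([rng.normal(0, 1, 10), rng.normal(1.5, 1, 10)])
        rep = evaluate(s, y, spec_target=0.70)
        assert rep.specificity >= 0.70
        assert rep.confusion.sum() == 20

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.arange(5.0), np.ones(5, dtype=int))


class TestPPV:
    def test_screening_arithmetic(self):
        # 70% sensitivity / 90% specificity on a 10+10 test set -> 7/(7+1)
        assert ppv(0.70, 0.90, 10, 10) == pytest.approx(0.875)

    def test_perfect_rates(self):
        assert ppv(1.0, 1.0, 25, 25) == 1.0

    def test_symmetric_case_direct_count(self):
        assert ppv(0.5, 0.5, 100, 100) == pytest.approx(0.5)  # 50/(50+50)

    def test_undefined_when_no_positive_calls(self):
        with pytest.raises(ValueError, match="undefined"):
            ppv(0.0, 1.0, 10, 10)

    def test_rate_bounds_checked(self):
        with pytest.raises(ValueError):
            ppv(1.2, 0.5, 10, 10)


class TestTransfer:
    def test_same_contrast_matches_direct_evaluation(self):
        rng = np.random.default_rng(22)
        X = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        y = np.repeat([0, 1], 30)
        X.loc[y == 1, "a"] += 2.5
        signed = pd.Series([0.4, 0.1], index=["a", "b"])
        panel = MarkerPanel(["a", "b"], signed)
        rep = transfer_panel(panel, X, y, n_trees=200, seed=23)
        m = fit_rf(X[["a", "b"]].to_numpy(), y, n_trees=200, seed=23)
        direct = evaluate(oob_scores(m), y)
        assert rep.as_dict() == direct.as_dict()

    def test_missing_feature_listed_in_error(self):
        X = pd.DataFrame(np.zeros((10, 2)), columns=["a", "b"])
        panel = MarkerPanel(["a", "zz"], pd.Series([0.5, 0.4], index=["a", "zz"]))
        with pytest.raises(ValueError, match="zz"):
            transfer_panel(panel, X, np.repeat([0, 1], 5))


def test_selection_inside_training_only_no_leakage():
    """With pure-noise data the full select-then-test protocol is honest:
    held-out AUC centers on 0.5 even though training OOB looks optimistic."""
    rng = np.random.default_rng(24)
    test_aucs = []
    for seed in range(6):
        X = rng.normal(size=(80, 30))
        y = np.repeat([0, 1], 40)
        tr = np.r_[0:30, 40:70]
        te = np.r_[30:40, 70:80]
        r = iterative_importance(X[tr], y[tr], n_iter=10, trees_per_iter=50, seed=seed)
        panel = select_panel(r, X[tr], y[tr], k_grid=(3, 5), n_trees=100, seed=seed)
        cols = [int(f) for f in panel.features]
        m = fit_rf(X[tr][:, cols], y[tr], n_trees=200, seed=seed)
        from breathpanel.rf_panel import predict_scores

        rep = evaluate(predict_scores(m, X[te][:, cols]), y[te])
        test_aucs.append(rep.auc_roc)
    assert abs(np.mean(test_aucs) - 0.5) < 0.15
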