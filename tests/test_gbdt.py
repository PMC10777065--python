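import itertools
import math

import numpy as np
import pytest

from spbcmi import gbdt
from spbcmi.gbdt import (
    BoostedEnsemble, fit, fit_tree, init_constant, line_search, loss_value,
    predict_proba, pseudo_residuals,
)


class TestInitConstant:
    def test_squared_is_mean(self):
        assert init_constant(np.array([0, 1, 1, 0]), "squared") == 0.5

    def test_logistic_is_log_odds(self):
        got = init_constant(np.array([1, 1, 1, 0]), "logistic")
        assert got == pytest.approx(math.log(3.0), abs=1e-12)

    def test_constant_labels_squared(self):
        assert init_constant(np.full(5, 2.5), "squared") == 2.5

    def test_degenerate_logistic_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            v = init_constant(np.ones(4), "logistic")
        assert np.isfinite(v) and v > 0


class TestPseudoResiduals:
    def test_squared_zero_at_fit(self, rng):
        y = rng.normal(size=6)
        np.testing.assert_array_equal(pseudo_residuals(y, y, "squared"), np.zeros(6))

    def test_logistic_at_zero_scores(self):
        r = pseudo_residuals(np.array([1.0]), np.array([0.0]), "logistic")
        assert r[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("loss", ["squared", "logistic"])
    def test_matches_negative_numeric_gradient(self, loss, rng):
        y = (rng.random(5) < 0.5).astype(float)
        F = rng.normal(size=5)
        r = pseudo_residuals(y, F, loss)
        eps = 1e-7
        for i in range(5):
            Fp, Fm = F.copy(), F.copy()
            Fp[i] += eps
            Fm[i] -= eps
            num_grad = (loss_value(y, Fp, loss) - loss_value(y, Fm, loss)) / (2 * eps)
            assert -num_grad == pytest.approx(r[i], abs=1e-6)

    def test_nan_scores_rejected(self):
        with pytest.raises(FloatingPointError):
            pseudo_residuals(np.ones(2), np.array([0.0, np.nan]), "squared")


def exhaustive_tree_oracle(X, r, max_depth, min_leaf):
    """Brute-force reference: try every (feature, midpoint threshold) split,
    scoring by directly computed within-child squared error."""

    def sse(vals):
        return float(np.sum((vals - vals.mean()) ** 2)) if len(vals) else 0.0

    def build(idx, depth):
        node = {"value": float(r[idx].mean())}
        if depth >= max_depth or len(idx) < 2 * min_leaf:
            return node
        best = None  # (neg_gain, feature, threshold) for lexicographic min
        parent = sse(r[idx])
        for f in range(X.shape[1]):
            vals = np.unique(X[idx, f])
            for lo, hi in zip(vals[:-1], vals[1:]):
                thr = (lo + hi) / 2
                left = idx[X[idx, f] <= thr]
                right = idx[X[idx, f] > thr]
                if len(left) < min_leaf or len(right) < min_leaf:
                    continue
                gain = parent - sse(r[left]) - sse(r[right])
                if gain <= 1e-12:
                    continue
                # same tie tolerance as the implementation contract: equal
                # gains resolve to lowest feature, then lowest threshold
                tol = 1e-9 * max(1.0, abs(gain if best is None else best[0]))
                if best is None or gain > best[0] + tol:
                    best = (gain, f, thr)
        if best is None:
            return node
        _, f, thr = best
        left = idx[X[idx, f] <= thr]
        right = idx[X[idx, f] > thr]
        return {
            "feature": f,
            "threshold": thr,
            "left": build(left, depth + 1),
            "right": build(right, depth + 1),
        }

    return build(np.arange(len(r)), 0)


def strip(d):
    """Compare tree structures: feature/threshold of splits, value of leaves."""
    if "feature" in d:
        return ("split", d["feature"], round(d["threshold"], 10),
                strip(d["left"]), strip(d["right"]))
    return ("leaf", round(d["value"], 10))


class TestFitTree:
    def test_depth_zero_is_mean_leaf(self, rng):
        r = rng.normal(size=8)
        t = fit_tree(rng.normal(size=(8, 2)), r, max_depth=0)
        np.testing.assert_allclose(t.predict(np.zeros((3, 2))), r.mean())

    def test_perfect_one_dimensional_split(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        r = np.array([5.0, 5.0, -5.0, -5.0])
        t = fit_tree(X, r, max_depth=1)
        np.testing.assert_allclose(t.predict(X), r)

    def test_constant_features_give_single_leaf(self, rng):
        r = rng.normal(size=6)
        t = fit_tree(np.ones((6, 3)), r, max_depth=3)
        assert t.root.feature == -1
        np.testing.assert_allclose(t.predict(np.ones((2, 3))), r.mean())

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 17))
        f = int(rng.integers(1, 4))
        depth = int(rng.integers(1, 4))
        X = rng.normal(size=(n, f))
        r = rng.normal(size=n)
        ours = fit_tree(X, r, max_depth=depth, min_samples_leaf=1).root.to_dict()
        oracle = exhaustive_tree_oracle(X, r, depth, 1)
        assert strip(ours) == strip(oracle)

    def test_min_leaf_respected(self, rng):
        X = rng.normal(size=(10, 1))
        r = rng.normal(size=10)
        t = fit_tree(X, r, max_depth=4, min_samples_leaf=4)

        def leaf_counts(node, idx):
            if node.feature < 0:
                return [len(idx)]
            left = idx[X[idx, node.feature] <= node.threshold]
            right = idx[X[idx, node.feature] > node.threshold]
            return leaf_counts(node.left, left) + leaf_counts(node.right, right)

        assert min(leaf_counts(t.root, np.arange(10))) >= 4


class TestLineSearch:
    def test_squared_perfect_fit_gives_one(self, rng):
        y = rng.normal(size=6)
        F = rng.normal(size=6)
        r = y - F
        assert line_search(y, F, r, "squared") == pytest.approx(1.0)

    def test_squared_double_residual_gives_half(self, rng):
        y = rng.normal(size=6)
        F = rng.normal(size=6)
        assert line_search(y, F, 2 * (y - F), "squared") == pytest.approx(0.5)

    def test_logistic_matches_grid_oracle(self, rng):
        y = np.array([1.0, 0.0, 1.0, 1.0])
        F = rng.normal(size=4)
        h = rng.normal(size=4)
        got = line_search(y, F, h, "logistic")
        grid = np.linspace(-10, 10, 20001)
        losses = [loss_value(y, F + g * h, "logistic") for g in grid]
        g0 = grid[int(np.argmin(losses))]
        fine = np.linspace(g0 - 1e-3, g0 + 1e-3, 20001)
        losses = [loss_value(y, F + g * h, "logistic") for g in fine]
        assert got == pytest.approx(fine[int(np.argmin(losses))], abs=1e-6)

    def test_zero_learner_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="zero"):
            assert line_search(np.ones(3), np.zeros(3), np.zeros(3), "squared") == 0.0


class TestBoosting:
    def test_separable_toy_reaches_perfect_training_accuracy(self, rng):
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] + X[:, 1] > 0).astype(float)
        model = fit(X, y, n_stages=50, max_depth=2, min_samples_leaf=1)
        acc = np.mean((predict_proba(model, X) >= 0.5) == y)
        assert acc == 1.0

    def test_zero_stages_predicts_constant(self):
        y = np.array([1.0, 1.0, 1.0, 0.0])
        model = fit(np.zeros((4, 1)), y, n_stages=0)
        p = predict_proba(model, np.zeros((2, 1)))
        np.testing.assert_allclose(p, 0.75, atol=1e-12)

    def test_training_loss_monotone_non_increasing(self, rng):
        X = rng.normal(size=(200, 5))
        y = (X[:, 0] > 0.2).astype(float)
        model = fit(X, y, n_stages=100, max_depth=2)
        losses = np.array(model.train_loss_)
        assert len(losses) == 101
        assert np.all(np.diff(losses) <= 1e-9)

    def test_nu_to_zero_with_fixed_budget_converges(self, rng):
        # predictions under (nu, M) and (nu/2, 2M) approach each other
        X = rng.normal(size=(80, 2))
        y = (X[:, 0] * X[:, 1] > 0).astype(float)
        Xt = rng.normal(size=(40, 2))
        p = {}
        for nu, M in ((0.4, 25), (0.2, 50), (0.1, 100), (0.05, 200)):
            m = fit(X, y, n_stages=M, learning_rate=nu, max_depth=2)
            p[nu] = m.decision_function(Xt)
        d_coarse = np.abs(p[0.4] - p[0.1]).mean()
        d_fine = np.abs(p[0.1] - p[0.05]).mean()
        assert d_fine < d_coarse

    def test_binary_label_check(self, rng):
        with pytest.raises(ValueError):
            fit(rng.normal(size=(4, 1)), np.array([0.0, 1.0, 2.0, 1.0]))

    def test_agrees_with_reference_implementation(self, rng):
        from sklearn.ensemble import GradientBoostingClassifier
        from sklearn.metrics import roc_auc_score

        X = rng.normal(size=(500, 6))
        y = ((X[:, 0] + 0.5 * X[:, 1] - X[:, 2] + 0.3 * rng.normal(size=500)) > 0).astype(float)
        Xt = rng.normal(size=(300, 6))
        yt = ((Xt[:, 0] + 0.5 * Xt[:, 1] - Xt[:, 2]) > 0).astype(float)
        ours = fit(X, y, n_stages=100, learning_rate=0.1, max_depth=3, min_samples_leaf=5)
        auc_ours = roc_auc_score(yt, predict_proba(ours, Xt))
        ref = GradientBoostingClassifier(
            n_estimators=100, learning_rate=0.1, max_depth=3, min_samples_leaf=5
        ).fit(X, y)
        auc_ref = roc_auc_score(yt, ref.predict_proba(Xt)[:, 1])
        print(f"AUC ours={auc_ours:.4f} sklearn={auc_ref:.4f}")
        assert abs(auc_ours - auc_ref) < 0.05

    def test_save_load_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(30, 3))
        y = (X[:, 0] > 0).astype(float)
        model = fit(X, y, n_stages=10, max_depth=2)
        path = tmp_path / "model.json"
        model.save(path)
        back = BoostedEnsemble.load(path)
        np.testing.assert_array_equal(
            predict_proba(model, X), predict_proba(back, X)
        )
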