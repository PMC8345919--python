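import numpy as np
import pandas as pd
import pytest

from xnorm_bench import (
    DataError,
    fit_nsc,
    fit_penalized_logistic,
    misclassification_error,
    predict_nsc,
    predict_penalized_logistic,
)
from xnorm_bench.classify import NSCModel, _nsc_statistics


# ---------------------------------------------------------------------------
# brute-force nearest-shrunken-centroid oracle: plain loops, no vectorization
# ---------------------------------------------------------------------------


def nsc_oracle(X, y, delta, classes):
    """Apply the shrunken-centroid formulas literally, marker by marker."""
    n_markers, n = X.shape
    k = len(classes)
    n_k = [sum(1 for v in y if v == cls) for cls in classes]
    overall = np.array([sum(X[i]) / n for i in range(n_markers)])
    cent = np.zeros((n_markers, k))
    for j, cls in enumerate(classes):
        for i in range(n_markers):
            cent[i, j] = sum(X[i, t] for t in range(n) if y[t] == cls) / n_k[j]
    s = np.zeros(n_markers)
    for i in range(n_markers):
        ss = 0.0
        for j, cls in enumerate(classes):
            ss += sum((X[i, t] - cent[i, j]) ** 2 for t in range(n) if y[t] == cls)
        s[i] = np.sqrt(ss / (n - k))
    s0 = float(np.median(s))
    m_k = [np.sqrt(1.0 / n_k[j] - 1.0 / n) for j in range(k)]
    d = np.zeros((n_markers, k))
    d_shr = np.zeros((n_markers, k))
    shrunk = np.zeros((n_markers, k))
    for i in range(n_markers):
        for j in range(k):
            d[i, j] = (cent[i, j] - overall[i]) / (m_k[j] * (s[i] + s0))
            d_shr[i, j] = np.sign(d[i, j]) * max(abs(d[i, j]) - delta, 0.0)
            shrunk[i, j] = overall[i] + m_k[j] * (s[i] + s0) * d_shr[i, j]
    priors = [n_k[j] / n for j in range(k)]
    return {
        "overall": overall,
        "centroids": cent,
        "s": s,
        "s0": s0,
        "m_k": np.array(m_k),
        "d": d,
        "d_shrunk": d_shr,
        "shrunken_centroids": shrunk,
        "priors": np.array(priors),
    }


def nsc_oracle_predict(oracle, X_test, classes):
    preds = []
    w = (oracle["s"] + oracle["s0"]) ** 2
    for t in range(X_test.shape[1]):
        scores = []
        for j in range(len(classes)):
            score = sum(
                (X_test[i, t] - oracle["shrunken_centroids"][i, j]) ** 2 / w[i]
                for i in range(X_test.shape[0])
            ) - 2.0 * np.log(oracle["priors"][j])
            scores.append(score)
        preds.append(classes[int(np.argmin(scores))])
    return np.array(preds, dtype=object)


def random_instance(rng):
    n_markers = int(rng.integers(2, 21))
    n = int(rng.integers(6, 13))
    n_a = int(rng.integers(2, n - 1))
    y = np.array(["A"] * n_a + ["B"] * (n - n_a), dtype=object)
    rng.shuffle(y)
    X = rng.normal(0, 1, (n_markers, n))
    shift = rng.normal(0, 1.5, n_markers)
    X[:, y == "B"] += shift[:, None]
    return X, y


class TestNSCOracleEquivalence:
    def test_model_components_match_brute_force_on_random_instances(self):
        """d_ik, soft-thresholding, shrunken centroids and predictions agree
        with a literal loop-based application of the formulas on 120 random
        small instances at random shrinkage levels."""
        rng = np.random.default_rng(314)
        for _ in range(120):
            X, y = random_instance(rng)
            classes = ["A", "B"]
            delta = float(rng.uniform(0.0, 2.0))
            stats = _nsc_statistics(X, y, classes)
            model = NSCModel(
                classes=classes,
                overall_centroid=stats["overall"],
                centroids=stats["centroids"],
                s=stats["s"],
                s0=stats["s0"],
                priors=stats["priors"],
                m_k=stats["m_k"],
                delta=delta,
            )
            oracle = nsc_oracle(X, y, delta, classes)
            np.testing.assert_allclose(model.overall_centroid, oracle["overall"], rtol=1e-12)
            np.testing.assert_allclose(model.centroids, oracle["centroids"], rtol=1e-12)
            np.testing.assert_allclose(model.s, oracle["s"], rtol=1e-12)
            assert model.s0 == pytest.approx(oracle["s0"], rel=1e-12)
            np.testing.assert_allclose(model.d_ik, oracle["d"], rtol=1e-9, atol=1e-12)
            np.testing.assert_allclose(model.d_shrunk, oracle["d_shrunk"], rtol=1e-9, atol=1e-12)
            np.testing.assert_allclose(
                model.shrunken_centroids, oracle["shrunken_centroids"], rtol=1e-9, atol=1e-12
            )
            X_test = rng.normal(0, 1.5, (X.shape[0], 5))
            np.testing.assert_array_equal(
                predict_nsc(model, X_test), nsc_oracle_predict(oracle, X_test, classes)
            )

    def test_fitted_model_at_fixed_delta_matches_oracle(self):
        rng = np.random.default_rng(9)
        X, y = random_instance(rng)
        model = fit_nsc(X, y, delta_grid=np.array([0.7]), cv_folds=2, seed=0)
        oracle = nsc_oracle(X, y, 0.7, ["A", "B"])
        np.testing.assert_allclose(
            model.shrunken_centroids, oracle["shrunken_centroids"], rtol=1e-9
        )


class TestNSCBehaviour:
    def _separable(self):
        X = np.array(
            [[0.0, 0.2, -0.1, 5.0, 5.2, 4.9], [1.0, 1.1, 0.9, -3.0, -3.1, -2.9]]
        )
        y = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
        return X, y

    def test_zero_shrinkage_separable_training_error_is_zero(self):
        X, y = self._separable()
        model = fit_nsc(X, y, delta_grid=np.array([0.0]), cv_folds=2, seed=0)
        assert misclassification_error(predict_nsc(model, X), y) == 0.0

    def test_full_shrinkage_predicts_majority_class(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (5, 8))
        y = np.array(["A"] * 6 + ["B"] * 2, dtype=object)  # priors 0.75 / 0.25
        model = fit_nsc(X, y, delta_grid=np.array([1e6]), cv_folds=2, seed=0)
        assert model.n_active == 0
        assert (predict_nsc(model, rng.normal(0, 1, (5, 10))) == "A").all()

    def test_cv_curve_reproducible_from_seed(self):
        rng = np.random.default_rng(11)
        X, y = random_instance(rng)
        m1 = fit_nsc(X, y, cv_folds=3, seed=5)
        m2 = fit_nsc(X, y, cv_folds=3, seed=5)
        np.testing.assert_array_equal(m1.cv_errors, m2.cv_errors)
        assert m1.delta == m2.delta

    def test_tie_break_prefers_sparser_model(self):
        X, y = self._separable()
        # perfectly separable: many deltas reach CV error 0; the largest wins
        model = fit_nsc(X, y, delta_grid=np.array([0.0, 0.1, 0.2]), cv_folds=3, seed=0)
        zero_err = model.cv_errors == model.cv_errors.min()
        assert model.delta == model.delta_grid[zero_err][-1]

    def test_marker_mismatch_rejected(self):
        X, y = self._separable()
        Xdf = pd.DataFrame(X, index=["g1", "g2"], columns=[f"s{i}" for i in range(6)])
        model = fit_nsc(Xdf, y, delta_grid=np.array([0.0]), cv_folds=2, seed=0)
        bad = Xdf.copy()
        bad.index = ["g2", "g1"]
        with pytest.raises(DataError, match="marker"):
            predict_nsc(model, bad)


class TestPenalizedLogistic:
    def _toy(self, rng, n_markers=5, n=40):
        X = rng.normal(0, 1, (n_markers, n))
        y = np.array(["A"] * (n // 2) + ["B"] * (n // 2), dtype=object)
        X[0, y == "B"] += 2.5
        X[1, y == "B"] -= 1.5
        return X, y

    def test_huge_penalty_gives_intercept_only_majority_model(self, rng):
        X = rng.normal(0, 1, (4, 30))
        y = np.array(["A"] * 20 + ["B"] * 10, dtype=object)
        model = fit_penalized_logistic(X, y, lambda_grid=np.array([1e4]), seed=0)
        assert model.n_active == 0
        assert (predict_penalized_logistic(model, rng.normal(0, 1, (4, 7))) == "A").all()

    def test_unpenalized_separable_training_error_zero(self):
        X = np.array([[0.0, 0.1, -0.1, 4.0, 4.1, 3.9], [0.5, 0.4, 0.6, -2.0, -2.1, -1.9]])
        y = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
        model = fit_penalized_logistic(X, y, lambda_grid=np.array([1e-6]), cv_folds=3, seed=0)
        pred = predict_penalized_logistic(model, X)
        assert misclassification_error(pred, y) == 0.0

    def test_active_set_size_nonincreasing_in_lambda(self, rng):
        X, y = self._toy(rng)
        grid = np.geomspace(1.0, 1e-4, 12)
        sizes = []
        for lam in grid:
            m = fit_penalized_logistic(X, y, lambda_grid=np.array([lam]), seed=0)
            sizes.append(m.n_active)
        # grid descends in lambda, so sparsity must not increase
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_cv_selection_reproducible(self, rng):
        X, y = self._toy(rng)
        m1 = fit_penalized_logistic(X, y, seed=3)
        m2 = fit_penalized_logistic(X, y, seed=3)
        assert m1.lam == m2.lam
        np.testing.assert_array_equal(m1.coef, m2.coef)

    def test_model_json_round_trip(self, rng, tmp_path):
        X, y = self._toy(rng)
        model = fit_penalized_logistic(X, y, lambda_grid=np.array([0.05]), seed=0)
        import json

        payload = json.loads(model.to_json(tmp_path / "m.json"))
        assert payload["lambda"] == model.lam
        assert len(payload["coef"]) == 5


class TestMisclassificationError:
    @pytest.mark.parametrize(
        "pred, truth, expected",
        [
            (["a", "b", "a"], ["a", "b", "a"], 0.0),
            (["a", "a"], ["b", "b"], 1.0),
            (["a"] * 61 + ["b"] * 3, ["a"] * 64, 3 / 64),
        ],
    )
    def test_counting(self, pred, truth, expected):
        assert misclassification_error(pred, truth) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            misclassification_error([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            misclassification_error(["a"], ["a", "b"])
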