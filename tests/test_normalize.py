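import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xnorm_bench import (
    freeze_reference,
    log2_transform,
    median_normalize,
    normalize_test,
    normalize_train,
    quantile_normalize,
    summarize_replicates,
)
from xnorm_bench.normalize import NormalizationError, NormalizationModel


def _df(arr, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"p{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


def _random_df(rng, n=40, k=6, prefix="s"):
    return _df(rng.normal(8, 2, (n, k)), prefix)


class TestLog2Transform:
    def test_values(self, tiny_matrix):
        out = log2_transform(tiny_matrix)
        assert out.scale == "log2"
        assert out.values.loc["p1", "s1"] == 3.0  # log2(8)
        assert out.values.loc["p4", "s1"] == 0.0  # log2(1)

    def test_double_transform_guard(self, tiny_matrix):
        once = log2_transform(tiny_matrix)
        with pytest.raises(NormalizationError, match="already log2"):
            log2_transform(once)

    def test_nonpositive_cell_reported_with_coordinates(self, tiny_matrix):
        bad = tiny_matrix.values.copy()
        bad.loc["p3", "s2"] = -1.0
        em = tiny_matrix.with_values(bad)
        with pytest.raises(NormalizationError, match="p3.*s2"):
            log2_transform(em)


class TestSummarizeReplicates:
    def test_odd_and_even_medians(self):
        values = _df([[2.0], [4.0], [9.0], [2.0], [4.0]])
        mm = pd.Series(["m1", "m1", "m1", "m2", "m2"], index=values.index)
        out = summarize_replicates(values, mm)
        assert out.loc["m1", "s0"] == 4.0
        assert out.loc["m2", "s0"] == 3.0

    def test_one_row_per_marker(self, rng):
        counts = rng.integers(1, 7, size=25)
        probes, markers = [], []
        for i, c in enumerate(counts):
            for j in range(c):
                probes.append(f"m{i:02d}_p{j}")
                markers.append(f"m{i:02d}")
        values = pd.DataFrame(
            rng.normal(size=(len(probes), 4)),
            index=probes,
            columns=list("abcd"),
        )
        mm = pd.Series(markers, index=probes)
        out = summarize_replicates(values, mm)
        assert out.shape == (25, 4)
        # spot-check one marker against a plain pandas median
        expected = values.groupby(mm).median()
        pd.testing.assert_frame_equal(out, expected.loc[out.index])


class TestMedianNormalize:
    def test_center_to_explicit_target(self):
        out, shifts = median_normalize(_df([[1.0], [2.0], [3.0]]), target=0)
        np.testing.assert_array_equal(out.to_numpy().ravel(), [-1.0, 0.0, 1.0])

    def test_fixed_point_when_target_matches(self):
        df = _df([[1.0, 3.0], [2.0, 4.0], [3.0, 5.0]])
        df.iloc[:, 1] -= 2.0  # both columns now share median 2
        out, shifts = median_normalize(df, target=2.0)
        pd.testing.assert_frame_equal(out, df)
        assert (shifts == 0).all()

    def test_default_target_is_median_of_medians(self):
        df = _df(np.array([[1.0, 3.0, 5.0], [2.0, 4.0, 6.0], [3.0, 5.0, 7.0]]))
        # column medians: 2, 4, 6 -> target 4, shifts +2, 0, -2
        out, shifts = median_normalize(df)
        np.testing.assert_array_equal(shifts.to_numpy(), [2.0, 0.0, -2.0])
        assert (out.median(axis=0) == 4.0).all()

    def test_only_locations_change(self, rng):
        df = _random_df(rng)
        out, _ = median_normalize(df)
        np.testing.assert_allclose(
            out.to_numpy() - out.to_numpy().mean(axis=0),
            df.to_numpy() - df.to_numpy().mean(axis=0),
            atol=1e-12,
        )


class TestQuantileNormalize:
    def test_two_column_brute_force(self):
        out, ref = quantile_normalize(_df([[2.0, 1.0], [4.0, 3.0], [6.0, 5.0]]))
        np.testing.assert_array_equal(ref, [1.5, 3.5, 5.5])
        np.testing.assert_array_equal(out.to_numpy(), [[1.5, 1.5], [3.5, 3.5], [5.5, 5.5]])

    def test_identical_columns_are_a_fixed_point(self):
        col = np.array([5.0, 1.0, 3.0])
        df = _df(np.column_stack([col, col, col]))
        out, ref = quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)
        np.testing.assert_array_equal(ref, np.sort(col))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_equal_distribution_postcondition(self, seed):
        """After QN every column has the identical sorted value vector."""
        rng = np.random.default_rng(seed)
        df = _df(rng.normal(0, 1, (rng.integers(3, 30), rng.integers(2, 6))))
        out, ref = quantile_normalize(df)
        arr = out.to_numpy()
        for j in range(arr.shape[1]):
            np.testing.assert_allclose(np.sort(arr[:, j]), ref, atol=1e-12)

    def test_ties_receive_mean_of_tied_reference_positions(self):
        # column 0 has a tie at ranks 1-2; reference values there are 2.5, 3.5
        out, ref = quantile_normalize(_df([[1.0, 2.0], [5.0, 3.0], [5.0, 4.0], [9.0, 10.0]]))
        np.testing.assert_array_equal(ref, [1.5, 4.0, 4.5, 9.5])
        assert out.iloc[1, 0] == out.iloc[2, 0] == pytest.approx((4.0 + 4.5) / 2)

    def test_single_column_rejected(self):
        with pytest.raises(NormalizationError, match="at least 2"):
            quantile_normalize(_df([[1.0], [2.0]]))


class TestFreezeReference:
    def test_fqn_reference_equals_any_qn_column_sorted(self, rng):
        train = normalize_train(_random_df(rng), "QN")
        model = freeze_reference(train, "fQN")
        np.testing.assert_allclose(
            model.reference_quantiles, np.sort(train.iloc[:, 0].to_numpy()), atol=1e-12
        )

    def test_fmn_reference_is_grand_median(self, rng):
        train = normalize_train(_random_df(rng), "MN")
        model = freeze_reference(train, "fMN")
        assert model.reference_median == float(np.median(train.to_numpy()))

    def test_freezing_is_deterministic(self, rng):
        train = normalize_train(_random_df(rng), "QN")
        a = freeze_reference(train, "fQN")
        b = freeze_reference(train, "fQN")
        np.testing.assert_array_equal(a.reference_quantiles, b.reference_quantiles)
        assert a.fitted_on == b.fitted_on

    def test_nothing_to_freeze_for_other_methods(self, rng):
        train = normalize_train(_random_df(rng), "QN")
        with pytest.raises(NormalizationError, match="freeze"):
            freeze_reference(train, "NN")

    def test_json_round_trip(self, rng, tmp_path):
        train = normalize_train(_random_df(rng), "QN")
        model = freeze_reference(train, "fQN")
        path = tmp_path / "model.json"
        model.to_json(path)
        back = NormalizationModel.from_json(path)
        assert back.method == "fQN"
        np.testing.assert_array_equal(back.reference_quantiles, model.reference_quantiles)


class TestNormalizeTest:
    @pytest.fixture
    def frozen(self, rng):
        train = normalize_train(_random_df(rng, n=30, k=8), "QN")
        return {
            "train": train,
            "fQN": freeze_reference(train, "fQN"),
            "fMN": freeze_reference(train, "fMN"),
        }

    def test_nn_is_identity(self, rng):
        df = _random_df(rng)
        pd.testing.assert_frame_equal(normalize_test(df, "NN"), df)

    def test_fqn_self_consistency_on_training_column(self, frozen):
        """fQN of a training column against its own model reproduces its QN values."""
        col = frozen["train"].iloc[:, [2]]
        out = normalize_test(col, "fQN", model=frozen["fQN"])
        np.testing.assert_allclose(out.to_numpy(), col.to_numpy(), atol=1e-12)

    def test_fmn_shifts_to_reference_median(self, frozen, rng):
        test = _random_df(rng, n=30, k=3, prefix="t") + 6.0
        out = normalize_test(test, "fMN", model=frozen["fMN"])
        med = frozen["fMN"].reference_median
        np.testing.assert_allclose(out.median(axis=0).to_numpy(), med, atol=1e-12)
        # a column with median 6 against reference 4 is shifted by -2
        two_col = test.iloc[:, [0]] - test.iloc[:, 0].median() + 6.0
        model = NormalizationModel("fMN", reference_median=4.0)
        shifted = normalize_test(two_col, "fMN", model=model)
        np.testing.assert_allclose(
            shifted.to_numpy(), two_col.to_numpy() - 2.0, atol=1e-12
        )

    def test_fqn_depends_only_on_ranks(self, frozen, rng):
        """Any strictly increasing transform of a test column leaves fQN output unchanged."""
        test = _random_df(rng, n=30, k=2, prefix="t")
        out1 = normalize_test(test, "fQN", model=frozen["fQN"])
        transformed = np.exp(0.3 * test) + test**3 / 50.0
        out2 = normalize_test(transformed, "fQN", model=frozen["fQN"])
        np.testing.assert_array_equal(out1.to_numpy(), out2.to_numpy())

    @pytest.mark.parametrize("method", ["fMN", "fQN"])
    def test_frozen_methods_ignore_constant_shifts(self, frozen, rng, method):
        test = _random_df(rng, n=30, k=3, prefix="t")
        out1 = normalize_test(test, method, model=frozen[method])
        out2 = normalize_test(test + 13.7, method, model=frozen[method])
        np.testing.assert_allclose(out1.to_numpy(), out2.to_numpy(), atol=1e-9)

    def test_frozen_methods_work_on_single_sample(self, frozen, rng):
        one = _random_df(rng, n=30, k=1, prefix="t")
        for method in ("fMN", "fQN", "MN"):
            out = normalize_test(one, method, model=frozen.get(method))
            assert out.shape == one.shape

    def test_pqn_on_duplicated_training_matrix(self, rng):
        """pQN with test == training columns equals the QN of training."""
        train = _random_df(rng, n=25, k=5)
        test = train.copy()
        test.columns = [f"t{j}" for j in range(5)]
        out = normalize_test(test, "pQN", train_values=train)
        qn_train, _ = quantile_normalize(train)
        np.testing.assert_allclose(out.to_numpy(), qn_train.to_numpy(), atol=1e-12)

    def test_fqn_interpolates_length_mismatch(self, rng):
        train = normalize_train(_random_df(rng, n=50, k=4), "QN")
        model = freeze_reference(train, "fQN")
        short = _random_df(rng, n=20, k=2, prefix="t")
        out = normalize_test(short, "fQN", model=model)
        assert out.shape == short.shape
        lo, hi = model.reference_quantiles.min(), model.reference_quantiles.max()
        assert out.to_numpy().min() >= lo - 1e-9
        assert out.to_numpy().max() <= hi + 1e-9

    def test_missing_model_rejected(self, rng):
        with pytest.raises(NormalizationError, match="frozen"):
            normalize_test(_random_df(rng), "fQN")

    def test_pqn_requires_training_matrix(self, rng):
        with pytest.raises(NormalizationError, match="training"):
            normalize_test(_random_df(rng), "pQN")
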