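"""Feature engineering: robust scaling, binarisation, MA features, one-hot,
probabilities — examples, brute-force oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bonemetab import encoding
from bonemetab.encoding import (
    BLOCK_WIDTHS, ExperimentCenteredEncoder, binarize_output, build_block,
    build_ma_mixed, build_ma_single, build_one_hot, build_probabilities,
    moving_average, robust_scale,
)
from bonemetab.study_io import EC_AXES, PROTEINS

from conftest import make_table


def brute_force_robust_scale(values):
    """Independent oracle: direct sort-and-interpolate median/quartiles."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)

    def quantile(q):
        pos = q * (n - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        return x[lo] + (pos - lo) * (x[hi] - x[lo])

    med, q1, q3 = quantile(0.5), quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    if iqr == 0:
        return np.zeros(n)
    return (np.asarray(values, dtype=float) - med) / iqr


class TestRobustScale:
    def test_three_point_example(self):
        np.testing.assert_allclose(robust_scale([1, 2, 3]), [-1, 0, 1])

    def test_constant_vector_maps_to_zeros(self):
        np.testing.assert_allclose(robust_scale([7, 7, 7]), [0, 0, 0])

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            robust_scale([])

    def test_matches_brute_force_oracle_on_random_vector(self):
        rng = np.random.default_rng(7)
        x = rng.normal(10, 3, size=50)
        np.testing.assert_allclose(robust_scale(x), brute_force_robust_scale(x),
                                   atol=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=2,
                    max_size=40))
    def test_median_zero_whenever_iqr_positive(self, values):
        scaled = robust_scale(values)
        if not np.allclose(scaled, 0):
            assert np.median(scaled) == pytest.approx(0, abs=1e-9)


class TestBinarize:
    def _one_animal(self, values):
        df = make_table(n_per_cell=1, seed=0).iloc[:len(values)].copy()
        df["animal"] = "fetus"
        df["serum_id"] = [f"x{i}" for i in range(len(values))]
        df["Fw"] = values
        return df

    def test_even_split(self):
        got = binarize_output(self._one_animal([1, 2, 3, 4]), "Fw")
        assert list(got) == [0, 0, 1, 1]

    def test_tie_at_median_falls_to_class_zero(self):
        got = binarize_output(self._one_animal([1, 2, 3]), "Fw")
        assert list(got) == [0, 0, 1]

    def test_scaling_is_per_animal_type(self):
        # fetal and maternal values on very different scales must not
        # separate by animal type: each type splits internally
        df = make_table(n_per_cell=1, seed=0).iloc[:4].copy()
        df["serum_id"] = list("abcd")
        df["animal"] = ["fetus", "fetus", "mother", "mother"]
        df["Fw"] = [1.0, 2.0, 100.0, 200.0]
        assert list(binarize_output(df, "Fw")) == [0, 1, 0, 1]

    def test_constant_within_animal_type_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            binarize_output(self._one_animal([5.0, 5.0, 5.0]), "Fw")


class TestMovingAverage:
    def test_constant_protein_gives_zeros(self, small_table):
        df = small_table.copy()
        df["PTH"] = 4.2
        assert (moving_average(df, "PTH") == 0).all()

    def test_two_record_group(self):
        df = make_table(n_per_cell=1, seed=0).iloc[:2].copy()
        df["serum_id"] = ["a", "b"]
        df[["animal", "treat", "period"]] = ["fetus", "control", "middle"]
        df["PTH"] = [2.0, 4.0]
        got = moving_average(df, "PTH")
        np.testing.assert_allclose(got, [1.0, -1.0])

    @pytest.mark.parametrize("axes", [("animal",), ("treat",), ("period",),
                                      ("animal", "treat", "period")])
    def test_matches_naive_double_loop_oracle(self, factorial_table, axes):
        df = factorial_table
        got = moving_average(df, "BALP", axes)
        for i in range(len(df)):
            members = [j for j in range(len(df))
                       if all(df[a].iloc[j] == df[a].iloc[i] for a in axes)]
            expected = np.mean([df["BALP"].iloc[j] for j in members]) \
                - df["BALP"].iloc[i]
            assert got.iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_unknown_protein_rejected(self, factorial_table):
        with pytest.raises(KeyError):
            moving_average(factorial_table, "XYZ")

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(1, 4), st.integers(0, 2 ** 31 - 1))
    def test_zero_sum_within_every_group(self, n_per_cell, seed):
        df = make_table(n_per_cell=n_per_cell, seed=seed)
        for axes in [("animal",), ("treat", "period"),
                     ("animal", "treat", "period")]:
            ma = moving_average(df, "CTX-I", axes)
            sums = ma.groupby([df[a] for a in axes], observed=True).sum()
            assert (sums.abs() < 1e-9).all()


class TestBlocks:
    def test_block_widths_and_names(self, small_table):
        for name, width in BLOCK_WIDTHS.items():
            block = build_block(small_table, name)
            assert block.shape == (len(small_table), width)
        assert list(build_ma_mixed(small_table).columns)[0] == "MA-PTH-experim"
        assert list(build_ma_single(small_table).columns)[:2] == [
            "MA-PTH-Animal", "MA-BALP-Animal"]
        assert list(build_ma_single(small_table).columns)[-1] == "MA-CTX-I-Period"

    def test_single_record_input_gives_all_zero_ma(self):
        df = make_table(n_per_cell=1, seed=3).iloc[:1]
        assert (build_ma_mixed(df).to_numpy() == 0).all()
        assert (build_ma_single(df).to_numpy() == 0).all()

    def test_ma_single_columns_equal_direct_calls(self, small_table):
        mai = build_ma_single(small_table)
        direct = moving_average(small_table, "TRAP", ("treat",))
        np.testing.assert_allclose(mai["MA-TRAP-Treat"], direct)

    def test_one_hot_examples_and_row_sums(self, small_table):
        oh = build_one_hot(small_table)
        row = oh[(small_table["animal"] == "fetus")
                 & (small_table["treat"] == "control")
                 & (small_table["period"] == "middle")].iloc[0]
        assert list(row) == [1, 0, 1, 0, 0, 1]
        row = oh[(small_table["animal"] == "mother")
                 & (small_table["treat"] == "restricted")
                 & (small_table["period"] == "late")].iloc[0]
        assert list(row) == [0, 1, 0, 1, 1, 0]
        for pair in (["Animal_Fetus", "Animal_Mon"], ["Treat_Con", "Treat_Res"],
                     ["Period_Late", "Period_Mid"]):
            assert (oh[pair].sum(axis=1) == 1).all()

    def test_probabilities_balanced_design(self, small_table):
        prob_ecs, prob_mix = build_probabilities(small_table)
        assert np.allclose(prob_ecs, 0.5)
        assert np.allclose(prob_mix, 1 / 8)

    def test_prob_mix_one_record_per_cell(self, factorial_table):
        _, prob_mix = build_probabilities(factorial_table)
        assert np.allclose(prob_mix, 1 / 8)

    def test_prob_axis_categories_sum_to_one(self):
        df = make_table(n_per_cell=2, seed=5).iloc[:11]  # unbalanced
        prob_ecs, prob_mix = build_probabilities(df)
        for axis, col in zip(EC_AXES, prob_ecs.columns):
            distinct = prob_ecs.groupby(df[axis], observed=True)[col].first()
            assert distinct.sum() == pytest.approx(1.0)
        # a joint cell is never larger than any of its marginals
        assert (prob_mix["Prob_Mix"].to_numpy()
                <= prob_ecs.to_numpy().min(axis=1) + 1e-12).all()

    def test_permutation_equivariance(self, small_table):
        perm = np.random.default_rng(0).permutation(len(small_table))
        shuffled = small_table.iloc[perm].reset_index(drop=True)
        for name in BLOCK_WIDTHS:
            orig = build_block(small_table, name).to_numpy()
            shuf = build_block(shuffled, name).to_numpy()
            np.testing.assert_allclose(shuf, orig[perm])

    def test_unknown_block_rejected(self, small_table):
        with pytest.raises(KeyError):
            build_block(small_table, "Bogus")


class TestExperimentCenteredEncoder:
    def test_default_mode_matches_build_ma_mixed(self, small_table):
        enc = ExperimentCenteredEncoder()
        got = enc.fit_transform(small_table)
        pd.testing.assert_frame_equal(got, build_ma_mixed(small_table))

    def test_strict_mode_uses_training_group_means(self, small_table):
        train = small_table.iloc[:16]
        test = small_table.iloc[16:]
        enc = ExperimentCenteredEncoder(strict=True).fit(train)
        got = enc.transform(test)
        cell = test.iloc[0][["animal", "treat", "period"]]
        members = train[(train["animal"] == cell["animal"])
                        & (train["treat"] == cell["treat"])
                        & (train["period"] == cell["period"])]
        expected = members["PTH"].mean() - test.iloc[0]["PTH"]
        assert got["MA-PTH-experim"].iloc[0] == pytest.approx(expected)

    def test_sklearn_params_round_trip(self):
        enc = ExperimentCenteredEncoder(axes=("animal",), strict=True)
        params = enc.get_params()
        clone = ExperimentCenteredEncoder(**params)
        assert clone.get_params() == params
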