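"""Standardization, optimum transform and Kendall-tau trophic profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffm.core import (
    ColumnStandardizer,
    FSPMatrix,
    TrophicProfiler,
    apply_optimum_transform,
    compute_trophic_profile,
    kendall_tau,
    mean_trophic_profiles,
    standardize,
)
from oracles import tau_b_oracle


def small_fsp(rows, traits=None, optimum=()):
    traits = traits or [f"T{i}" for i in range(len(rows[0]))]
    return FSPMatrix(
        effects=pd.DataFrame(
            rows, index=[f"food_{i}" for i in range(len(rows))], columns=traits
        ),
        optimum_traits=frozenset(optimum),
    )


class TestStandardize:
    def test_hand_checked_column(self):
        z = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 1.0, 3.0]}))
        assert list(z["a"]) == pytest.approx([-1.0, 0.0, 1.0])  # sample SD = 1

    def test_mean_zero_sd_one(self, z_traits):
        assert np.abs(z_traits.mean(axis=0)).max() < 1e-9
        assert np.abs(z_traits.std(axis=0, ddof=1) - 1).max() < 1e-9

    def test_zero_variance_error_lists_columns(self):
        X = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "const": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="const"):
            standardize(X)

    def test_zero_variance_drop_policy(self, caplog):
        X = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "const": [1.0, 1.0, 1.0]})
        with caplog.at_level("WARNING"):
            z = standardize(X, zero_variance="drop")
        assert list(z.columns) == ["ok"]

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            standardize(pd.DataFrame({"a": [1.0]}))


class TestKendallTau:
    def test_hand_counted_example(self):
        # 5 concordant, 1 discordant of 6 pairs -> (5-1)/6
        x = [0.5, -1.2, 0.7, 0.0]
        y = [1.1, -0.8, 0.3, -0.6]
        assert kendall_tau(x, y) == pytest.approx(4 / 6)

    def test_perfect_concordance_and_discordance(self):
        x = np.array([0.3, 1.7, -0.2, 2.5])
        assert kendall_tau(x, x) == pytest.approx(1.0)
        assert kendall_tau(x, -x) == pytest.approx(-1.0)

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            kendall_tau([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 23))
            x = rng.integers(-2, 3, size=n).astype(float)
            y = rng.normal(size=n).round(1)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert kendall_tau(x, y) == pytest.approx(tau_b_oracle(x, y), abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        xs=st.lists(st.integers(min_value=-10, max_value=10), min_size=3, max_size=15),
        a=st.floats(min_value=0.1, max_value=3.0),
        b=st.floats(min_value=-2.0, max_value=2.0),
    )
    def test_invariant_under_strictly_increasing_transforms(self, xs, a, b):
        x = np.asarray(xs, dtype=float)
        y = np.arange(len(x), dtype=float)
        if np.ptp(x) == 0:
            return
        g = a * x + b + 0.1 * x**3  # strictly increasing for a > 0
        assert kendall_tau(g, y) == pytest.approx(kendall_tau(x, y), abs=1e-12)


class TestOptimumTransform:
    def test_symmetric_penalty_around_optimum(self):
        fsp = small_fsp([[1, 0, 2], [0, 1, -1]], traits=["A", "B", "C"], optimum={"A"})
        z = pd.Series({"A": 1.5, "B": 0.4, "C": -0.2})
        out_pos = apply_optimum_transform(z, fsp, "food_0")
        out_neg = apply_optimum_transform(z.replace(1.5, -1.5), fsp, "food_0")
        assert out_pos["A"] == out_neg["A"] == -1.5
        assert out_pos["B"] == 0.4 and out_pos["C"] == -0.2  # non-optimum untouched

    def test_no_penalty_at_optimum_and_zero_effect_passthrough(self):
        fsp = small_fsp([[1, 0], [0, 1]], traits=["A", "B"], optimum={"A"})
        z = pd.Series({"A": 0.0, "B": 2.0})
        assert apply_optimum_transform(z, fsp, "food_0")["A"] == 0.0
        # effect of A on food_1 is 0 -> A passes through even far from optimum
        z2 = pd.Series({"A": 3.0, "B": 2.0})
        assert apply_optimum_transform(z2, fsp, "food_1")["A"] == 3.0

    def test_custom_optimum_value(self):
        fsp = small_fsp([[1, 1], [0, -1]], traits=["A", "B"], optimum={"A"})
        z = pd.Series({"A": 1.0, "B": 0.0})
        out = apply_optimum_transform(z, fsp, "food_0", optima={"A": 1.0})
        assert out["A"] == 0.0

    def test_unknown_optimum_trait_errors(self):
        fsp = small_fsp([[1, 1], [0, -1]], traits=["A", "B"], optimum={"A"})
        z = pd.Series({"B": 0.0})
        with pytest.raises(ValueError, match="A"):
            apply_optimum_transform(z, fsp, "food_0")


class TestTrophicProfiles:
    def test_monotone_specimen_scores_one(self, rng):
        fsp = small_fsp([[2, -1, 1, 0, -2, 1], [0, 1, -1, 2, 1, -2]])
        fz = ColumnStandardizer().fit_transform(fsp.effects)
        z = fz.loc["food_0"] + 0.1 * fz.loc["food_0"] ** 3  # strictly increasing map
        tp = compute_trophic_profile(z, fsp)
        assert tp["food_0"] == pytest.approx(1.0)

    def test_opposite_fsp_rows_give_opposite_taus(self):
        fsp = small_fsp([[2, -1, 1, -2, 1], [-2, 1, -1, 2, -1]])
        z = pd.Series(
            [0.3, -1.1, 0.8, -0.4, 1.9], index=fsp.trait_abbreviations
        )  # tie-free
        tp = compute_trophic_profile(z, fsp)
        assert tp["food_0"] == pytest.approx(-tp["food_1"])

    def test_profile_bounds_and_shape(self, z_traits, fsp):
        profiler = TrophicProfiler(fsp).fit(z_traits)
        tp = profiler.transform(z_traits)
        assert tp.shape == (len(z_traits), 10)
        assert (tp.to_numpy() >= -1).all() and (tp.to_numpy() <= 1).all()

    def test_specimen_order_does_not_matter(self, z_traits, fsp):
        profiler = TrophicProfiler(fsp).fit(z_traits)
        tp = profiler.transform(z_traits)
        shuffled = z_traits.sample(frac=1.0, random_state=0)
        tp2 = profiler.transform(shuffled)
        pd.testing.assert_frame_equal(tp2.sort_index(), tp.sort_index())

    def test_trait_set_mismatch_lists_difference(self, z_traits, fsp):
        bad = z_traits.rename(columns={"BD": "XX"})
        with pytest.raises(ValueError, match="XX"):
            TrophicProfiler(fsp).fit(bad)

    def test_fsp_standardization_is_per_trait_across_foods(self, fsp):
        profiler = TrophicProfiler(fsp).fit(
            pd.DataFrame(np.zeros((2, 22)), columns=fsp.trait_abbreviations)
        )
        fz = profiler.fsp_z_
        assert np.abs(fz.mean(axis=0)).max() < 1e-9  # columns = traits
        assert np.abs(fz.std(axis=0, ddof=1) - 1).max() < 1e-9


class TestFSPMatrix:
    def test_rejects_out_of_range_effects(self):
        with pytest.raises(ValueError, match="-2"):
            small_fsp([[3, 0], [0, 1]])

    def test_rejects_single_food(self):
        with pytest.raises(ValueError, match="2 food types"):
            small_fsp([[1, 0]])

    def test_rejects_unknown_optimum_trait(self):
        with pytest.raises(ValueError, match="optimum"):
            small_fsp([[1, 0], [0, 1]], optimum={"nope"})


class TestMeanTrophicProfiles:
    def test_arithmetic_mean_per_species(self):
        tp = pd.DataFrame(
            {"mollusks": [0.2, 0.4, 0.9], "detritus": [0.0, -0.2, 0.5]},
            index=["a", "b", "c"],
        )
        species = pd.Series({"a": "sp1", "b": "sp1", "c": "sp2"})
        m = mean_trophic_profiles(tp, species)
        assert m.at["sp1", "mollusks"] == pytest.approx(0.3)
        assert m.at["sp2", "detritus"] == pytest.approx(0.5)  # single specimen
        assert list(m["n"]) == [2, 1]

    def test_community_yields_nine_species(self, z_traits, fsp, species_of):
        tp = TrophicProfiler(fsp).fit(z_traits).transform(z_traits)
        m = mean_trophic_profiles(tp, species_of)
        assert m.shape[0] == 9
        assert m["n"].sum() == 85

    def test_unmapped_specimen_errors(self):
        tp = pd.DataFrame({"f": [0.1]}, index=["a"])
        with pytest.raises(ValueError, match="a"):
            mean_trophic_profiles(tp, pd.Series(dtype=object))
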