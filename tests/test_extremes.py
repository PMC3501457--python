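"""Extreme detection chain, merging, peak naming and replicate cleaning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import as_curve, brute_force_extremes
from voltfp.errors import ConfigurationError, ParameterError
from voltfp.extremes import (ExtremeSet, clean_dataset, differentiate,
                             find_extremes, flag_outlier_replicates,
                             merge_close_extremes, name_peaks, sign_normalize)
from voltfp.synthetic import (DEFAULT_OUTLIER_FLAGS, generate_voltammogram,
                              make_tissue_profiles)

NOISE_OFF = dict(replicate_noise_sd=0.0, family_noise_frac=0.0,
                 replicate_gain_sd=0.0, shape_noise_sd=0.0)


class TestDifferentiate:
    def test_constant_signal_gives_zeros(self):
        np.testing.assert_array_equal(differentiate(np.full(5, 3.2)), np.zeros(5))

    def test_first_differences_with_leading_pad(self):
        np.testing.assert_array_equal(differentiate([0.0, 1.0, 3.0]),
                                      [0.0, 1.0, 2.0])

    def test_prefix_sum_inverts(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        np.testing.assert_allclose(np.cumsum(differentiate(x)) + x[0], x,
                                   rtol=0, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            differentiate([1.0])


class TestSignNormalize:
    def test_zero_maps_to_positive(self):
        np.testing.assert_array_equal(sign_normalize([-1.0, 0.0, 2.0]),
                                      [-0.5, 0.5, 0.5])

    def test_values_are_half_units(self):
        out = sign_normalize(np.random.default_rng(0).normal(size=100))
        assert set(np.unique(out)) <= {-0.5, 0.5}


class TestFindExtremes:
    def test_single_bump_is_one_maximum(self):
        x = np.linspace(-3, 3, 101)
        e = find_extremes(as_curve(np.exp(-x ** 2)))
        assert len(e) == 1 and e.kinds == ["max"]

    @pytest.mark.parametrize("idx", range(9))
    def test_six_or_four_extremes_on_noise_free_curves(self, profiles, idx):
        p = profiles[idx]
        cur = generate_voltammogram(p, rng=np.random.default_rng(0), **NOISE_OFF)
        e = find_extremes(cur)
        assert len(e) == p.n_extremes_target
        assert e.kinds == ["min", "max"] * (len(e) // 2)

    @given(st.lists(st.integers(min_value=-3, max_value=3),
                    min_size=4, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_chain_equals_neighbour_oracle_with_plateaus(self, vals):
        y = np.array(vals, dtype=float) * 1e-7
        e = find_extremes(as_curve(y))
        pos, kinds = brute_force_extremes(y)
        np.testing.assert_array_equal(e.positions, pos)
        assert e.kinds == kinds

    def test_chain_equals_oracle_on_random_signals(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            y = rng.normal(size=rng.integers(5, 200))
            e = find_extremes(as_curve(y))
            pos, kinds = brute_force_extremes(y)
            np.testing.assert_array_equal(e.positions, pos)
            assert e.kinds == kinds


def make_extremes(positions, values, kinds):
    positions = np.asarray(positions, dtype=int)
    pots = -0.7 - 0.002 * positions
    return ExtremeSet(positions, pots, np.asarray(values, dtype=float),
                      list(kinds))


class TestMerge:
    def test_close_pair_merged(self):
        e = make_extremes([10, 12, 300], [1.0, 0.2, 2.0], ["max", "min", "max"])
        merged = merge_close_extremes(e, 5)
        assert len(merged) == 2
        assert merged.positions[0] in (10, 12)
        assert merged.positions[1] == 300

    def test_min_distance_one_is_identity(self):
        e = make_extremes([5, 6, 7], [1.0, 0.0, 1.0], ["max", "min", "max"])
        merged = merge_close_extremes(e, 1)
        np.testing.assert_array_equal(merged.positions, e.positions)

    def test_postconditions_and_idempotence(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(2, 20)
            pos = np.sort(rng.choice(500, size=n, replace=False))
            vals = rng.normal(size=n)
            kinds = [("min", "max")[i % 2] for i in range(n)]
            e = make_extremes(pos, vals, kinds)
            m1 = merge_close_extremes(e, 5)
            if len(m1) >= 2:
                assert np.diff(m1.positions).min() >= 5
                assert all(a != b for a, b in zip(m1.kinds, m1.kinds[1:]))
            m2 = merge_close_extremes(m1, 5)
            np.testing.assert_array_equal(m1.positions, m2.positions)
            assert m1.kinds == m2.kinds

    def test_invalid_distance(self):
        with pytest.raises(ParameterError):
            merge_close_extremes(make_extremes([1], [0.0], ["max"]), 0)


class TestNamePeaks:
    def curve_peaks(self, profiles, tissue):
        p = next(q for q in profiles if q.tissue_name == tissue)
        cur = generate_voltammogram(p, rng=np.random.default_rng(0), **NOISE_OFF)
        return name_peaks(merge_close_extremes(find_extremes(cur)))

    def test_liver_curve_names_three_minima_and_three_maxima(self, profiles):
        named = self.curve_peaks(profiles, "liver")
        for name in ("rs2co", "cat1", "cat2", "max1", "max2", "max3"):
            assert getattr(named, name) is not None, name
        assert named.cat2.potential < named.cat1.potential < named.rs2co.potential

    def test_muscle_curve_lacks_co1(self, profiles):
        named = self.curve_peaks(profiles, "muscle")
        assert named.co1 is None
        assert named.cat2 is not None and named.max3 is not None

    def test_empty_extreme_set(self):
        named = name_peaks(make_extremes([], [], []))
        assert all(getattr(named, n) is None for n in
                   ("co1", "rs2co", "cat1", "cat2", "max1", "max2", "max3"))

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ConfigurationError):
            name_peaks(make_extremes([], [], []),
                       windows={"rs2co": (-1.35, -1.10), "cat1": (-1.48, -1.30)})


class TestOutlierFlagging:
    def group(self, n=5):
        y = np.sin(np.linspace(0, 3, 518)) - 2.0
        return [as_curve(y, "liver", 1, r + 1) for r in range(n)]

    def test_identical_curves_not_flagged(self):
        assert flag_outlier_replicates(self.group()) == []

    def test_collapsed_replicate_flagged(self):
        group = self.group(4)
        y = group[0].currents
        bad = as_curve(y[0] + 0.05 * (y - y[0]), "liver", 1, 5)
        flagged = flag_outlier_replicates(group + [bad])
        assert [c.key for c in flagged] == [("liver", 1, 5)]

    def test_manual_flags_override(self):
        group = self.group()
        flagged = flag_outlier_replicates(group,
                                          manual_flags=[("liver", 1, 2)])
        assert [c.key for c in flagged] == [("liver", 1, 2)]

    def test_small_group_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert flag_outlier_replicates(self.group(2)) == []


class TestCleaning:
    def test_manual_cleaning_leaves_352(self, default_dataset):
        cleaned, flagged = clean_dataset(
            default_dataset, manual_flags=list(DEFAULT_OUTLIER_FLAGS))
        assert len(flagged) == 8
        assert len(cleaned) == 352

    def test_auto_detection_catches_injected_corruptions(self, default_dataset):
        _, flagged = clean_dataset(default_dataset)
        assert set(DEFAULT_OUTLIER_FLAGS) <= set(flagged)
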