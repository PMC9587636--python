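"""Normalization chain: plate medians, bin axis, histograms, control profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sopra import profiles
from sopra.profiles import (
    BinAxis,
    DegenerateAxisError,
    binwise_normalize,
    compute_bin_axis,
    compute_profiles,
    control_reference,
    histogram_well,
    platewise_normalize,
    relative_freq,
)
from sopra.screen_io import ContentType


def _cells(values_by_well, content_by_well, plate="P1", rep=1, feature="Area"):
    rows = []
    for well, values in values_by_well.items():
        for v in values:
            rows.append((plate, rep, well, content_by_well[well], v))
    return pd.DataFrame(rows, columns=["plate", "replicate", "well", "content", feature])


class TestPlatewiseNormalize:
    def test_divides_by_control_median(self):
        cells = _cells(
            {1: [90.0, 100.0, 110.0], 2: [150.0]},
            {1: "neutral_control", 2: "sample"},
        )
        out, report = platewise_normalize(cells, "Area")
        assert out.loc[out["well"] == 2, "Area__norm"].iloc[0] == pytest.approx(1.5)
        assert report["control_median"].iloc[0] == 100.0

    def test_equal_controls_normalize_to_one(self):
        cells = _cells({1: [7.0, 7.0, 7.0]}, {1: "neutral_control"})
        out, _ = platewise_normalize(cells, "Area")
        assert (out["Area__norm"] == 1.0).all()

    def test_matches_sort_based_median_oracle(self, rng):
        values = rng.lognormal(0, 0.5, 500)
        ctrl_mask = rng.random(500) < 0.3
        cells = pd.DataFrame(
            {
                "plate": "P1", "replicate": 1,
                "well": np.where(ctrl_mask, 1, 2),
                "content": np.where(ctrl_mask, "neutral_control", "sample"),
                "Area": values,
            }
        )
        out, _ = platewise_normalize(cells, "Area")
        ctrl_sorted = np.sort(values[ctrl_mask])
        m = len(ctrl_sorted)
        oracle_median = (
            ctrl_sorted[m // 2] if m % 2 else (ctrl_sorted[m // 2 - 1] + ctrl_sorted[m // 2]) / 2
        )
        np.testing.assert_allclose(
            out["Area__norm"].to_numpy(), out["Area"].to_numpy() / oracle_median, atol=1e-12
        )

    def test_plate_without_controls_excluded_and_reported(self):
        cells = pd.concat(
            [
                _cells({1: [1.0, 2.0], 2: [3.0]}, {1: "neutral_control", 2: "sample"}),
                _cells({1: [5.0]}, {1: "sample"}, plate="P2"),
            ]
        )
        out, report = platewise_normalize(cells, "Area")
        assert set(out["plate"]) == {"P1"}
        assert report.loc[report["plate"] == "P2", "error"].iloc[0] == "no control objects"


class TestBinAxis:
    def test_unit_width_and_split_points(self):
        axis = compute_bin_axis([0.0, 7.0], n=7)
        assert axis.width_L == 1.0
        np.testing.assert_array_equal(axis.split_points, [1, 2, 3, 4, 5, 6])

    def test_degenerate_limits_rejected(self):
        with pytest.raises(DegenerateAxisError):
            compute_bin_axis([3.0, 3.0, 3.0])

    def test_percentile_limits_match_sort_oracle(self, rng):
        values = rng.random(1000)
        axis = compute_bin_axis(values, n=7, lower_pct=5, upper_pct=95)

        def oracle_pct(sorted_vals, q):
            # linear interpolation between closest ranks
            pos = q / 100 * (len(sorted_vals) - 1)
            lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
            hi = min(lo + 1, len(sorted_vals) - 1)
            return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac

        s = np.sort(values)
        assert axis.lower == pytest.approx(oracle_pct(s, 5), abs=1e-12)
        assert axis.upper == pytest.approx(oracle_pct(s, 95), abs=1e-12)


class TestHistogram:
    axis = BinAxis(feature="Area", n=7, lower=0.0, upper=7.0)

    def test_empty_well_gets_pure_pseudocounts(self):
        counts = histogram_well([], self.axis)
        assert counts.tolist() == [1] * 7
        assert counts.sum() == 7

    def test_one_value_per_bin(self):
        counts = histogram_well([0.5, 1.5, 2.5, 3.5, 4.5, 5.5, 6.5], self.axis)
        assert counts.tolist() == [2] * 7

    def test_upper_limit_closed_and_ties_go_up(self):
        assert histogram_well([7.0], self.axis).tolist() == [1, 1, 1, 1, 1, 1, 2]
        assert histogram_well([1.0], self.axis).tolist() == [1, 2, 1, 1, 1, 1, 1]

    def test_out_of_range_values_clamped_to_edge_bins(self):
        counts = histogram_well([-5.0, 12.0], self.axis)
        assert counts.tolist() == [2, 1, 1, 1, 1, 1, 2]

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-10, 20, allow_nan=False), max_size=50), st.floats(0.01, 5))
    def test_conservation_and_shift_monotonicity(self, values, shift):
        counts = histogram_well(values, self.axis)
        assert counts.sum() == len(values) + self.axis.n  # conservation + pseudocounts
        before = profiles._bin_indices(np.asarray(values, float), self.axis) if values else []
        after = (
            profiles._bin_indices(np.asarray(values, float) + shift, self.axis) if values else []
        )
        assert np.all(np.asarray(after) >= np.asarray(before))


class TestRelativeFreqAndReference:
    def test_uniform_counts(self):
        np.testing.assert_allclose(relative_freq(np.ones(7, int)), np.full(7, 1 / 7))

    def test_example_counts(self):
        rf = relative_freq(np.array([3, 1, 1, 1, 1, 1, 6]))
        np.testing.assert_allclose(rf, np.array([3, 1, 1, 1, 1, 1, 6]) / 14)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.integers(1, 1000), min_size=2, max_size=12))
    def test_sums_to_one(self, counts):
        assert relative_freq(np.array(counts)).sum() == pytest.approx(1.0, abs=1e-12)

    def test_reference_is_binwise_median(self):
        c = [np.array([0.1, 0.9]), np.array([0.2, 0.8]), np.array([0.2, 0.8])]
        np.testing.assert_allclose(control_reference(c), [0.2, 0.8])

    def test_single_control_is_its_own_reference(self):
        c = [np.array([0.3, 0.7])]
        np.testing.assert_array_equal(control_reference(c), c[0])

    def test_reference_matches_sort_based_oracle(self, rng):
        c = [relative_freq(rng.integers(1, 100, 7)) for _ in range(20)]
        stacked = np.vstack(c)
        oracle = np.empty(7)
        for k in range(7):
            col = np.sort(stacked[:, k])
            oracle[k] = (col[9] + col[10]) / 2
        np.testing.assert_allclose(control_reference(c), oracle, atol=1e-15)


class TestBinwiseNormalize:
    def test_reference_equal_test_gives_exact_zero_log_profile(self):
        rf = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
        assert (binwise_normalize(rf, rf, "log2") == 0.0).all()

    def test_ratio_scale(self):
        ref = np.array([0.2, 0.2])
        test = np.array([0.4, 0.2])
        np.testing.assert_allclose(binwise_normalize(test, ref, "ratio"), [2.0, 1.0])

    def test_matches_elementwise_division(self, rng):
        test = relative_freq(rng.integers(1, 50, 7))
        ref = relative_freq(rng.integers(1, 50, 7))
        np.testing.assert_allclose(binwise_normalize(test, ref, "ratio"), test / ref)
        np.testing.assert_allclose(binwise_normalize(test, ref, "log2"), np.log2(test / ref))


class TestComputeProfiles:
    def test_shared_axis_and_profile_shape(self, tiny_cells):
        profs, axes = compute_profiles(tiny_cells, ["Area"])
        assert set(profs["feature"]) == {"Area"}
        per_well = profs.groupby(["plate", "replicate", "well"]).size()
        assert (per_well == axes["Area"].n).all()

    def test_conservation_per_well(self, tiny_cells):
        profs, axes = compute_profiles(tiny_cells, ["Area"])
        n = axes["Area"].n
        counts = profs.groupby(["plate", "replicate", "well"])["count"].sum()
        objects = tiny_cells.groupby(["plate", "replicate", "well"]).size()
        aligned = pd.concat([counts, objects], axis=1, keys=["c", "o"]).dropna()
        assert (aligned["c"] == aligned["o"] + n).all()

    def test_control_median_profile_normalizes_to_zero(self):
        # wells drawn identically: the single control's profile is its own
        # reference, hence exactly zero on the log2 scale
        rng = np.random.default_rng(0)
        cells = _cells(
            {1: list(rng.normal(10, 2, 200)), 2: list(rng.normal(10, 2, 200))},
            {1: "neutral_control", 2: "sample"},
        )
        profs, _ = compute_profiles(cells, ["Area"], lower_pct=0, upper_pct=100)
        ctrl = profs[profs["content"] == "neutral_control"]
        assert (ctrl["value"] == 0.0).all()
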