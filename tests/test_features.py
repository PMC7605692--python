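import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from infantwear import (
    RawTriaxialSeries,
    aggregate_minutes,
    build_feature_table,
    compute_inclination,
    compute_vm,
    pivot_sites,
    placement_cvs,
    sliding_cv,
)
from conftest import TABLE1_CELLS, TABLE1_VM, brute_force_sliding_cv


class TestVectorMagnitude:
    @pytest.mark.parametrize(
        "xyz,expected",
        [((600, -800, 0), 1000.0), ((0, 0, 0), 0.0), ((577.35, 577.35, 577.35), 1000.0)],
    )
    def test_examples(self, xyz, expected):
        assert compute_vm(*xyz) == pytest.approx(expected, abs=0.01)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            compute_vm(np.nan, 0, 0)
        with pytest.raises(ValueError):
            compute_vm(0, np.inf, 0)

    def test_vectorized(self):
        out = compute_vm(np.array([600.0, 0.0]), np.array([-800.0, 0.0]), np.array([0.0, 0.0]))
        np.testing.assert_allclose(out, [1000.0, 0.0])


class TestInclination:
    @pytest.mark.parametrize(
        "xyz,axis,expected",
        [
            ((0, -1000, 0), "y", 180.0),
            ((0, -1000, 0), "x", 90.0),
            ((577.35, 577.35, 577.35), "z", 54.7356),
        ],
    )
    def test_examples(self, xyz, axis, expected):
        assert compute_inclination(*xyz, axis=axis) == pytest.approx(expected, abs=1e-3)

    def test_zero_vm_is_missing(self):
        assert np.isnan(compute_inclination(0, 0, 0, axis="x"))

    @given(
        st.tuples(
            st.floats(-2000, 2000), st.floats(-2000, 2000), st.floats(-2000, 2000)
        ).filter(lambda v: (v[0] ** 2 + v[1] ** 2 + v[2] ** 2) > 1e-6)
    )
    @settings(max_examples=200, derandomize=True)
    def test_per_sample_angle_identity(self, xyz):
        # cos^2(theta_x) + cos^2(theta_y) + cos^2(theta_z) == 1 whenever VM > 0
        total = sum(
            np.cos(np.radians(compute_inclination(*xyz, axis=a))) ** 2 for a in "xyz"
        )
        assert total == pytest.approx(1.0, abs=1e-9)
        for a in "xyz":
            assert 0.0 <= compute_inclination(*xyz, axis=a) <= 180.0


class TestAggregateMinutes:
    def _series(self, samples, start="2020-01-06 08:00:00", rate=30.0):
        return RawTriaxialSeries("P01", "hip", pd.Timestamp(start), np.asarray(samples, float), rate)

    def test_constant_signal(self):
        s = self._series(np.tile([0.0, -1000.0, 0.0], (1800, 1)))
        out = aggregate_minutes(s)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["mean_vm"] == pytest.approx(1000.0, abs=1e-9)
        assert row["incl_y"] == pytest.approx(180.0, abs=1e-9)
        assert row["incl_x"] == pytest.approx(90.0, abs=1e-9)
        assert row["incl_z"] == pytest.approx(90.0, abs=1e-9)

    def test_partial_trailing_minute_dropped(self):
        s = self._series(np.tile([0.0, -1000.0, 0.0], (2700, 1)))  # 90 s at 30 Hz
        assert len(aggregate_minutes(s)) == 1

    def test_partial_leading_minute_dropped(self):
        # starts mid-minute: first complete epoch begins at the next boundary
        s = self._series(np.tile([0.0, -1000.0, 0.0], (3600, 1)), start="2020-01-06 08:00:30")
        out = aggregate_minutes(s)
        assert len(out) == 1
        assert out["minute_start"].iloc[0] == pd.Timestamp("2020-01-06 08:01:00")

    def test_per_sample_then_average_ordering(self):
        # alternating +-1 g on x: axis mean cancels but VM and angles do not
        samples = np.zeros((1800, 3))
        samples[::2, 0] = 1000.0
        samples[1::2, 0] = -1000.0
        out = aggregate_minutes(self._series(samples))
        row = out.iloc[0]
        assert row["mean_x"] == pytest.approx(0.0, abs=1e-9)
        assert row["mean_vm"] == pytest.approx(1000.0, abs=1e-9)
        assert row["incl_x"] == pytest.approx(90.0, abs=1e-9)  # mean of 0 and 180

    def test_short_series_warns_and_is_empty(self):
        s = self._series(np.tile([0.0, -1000.0, 0.0], (100, 1)))
        with pytest.warns(UserWarning, match="shorter than one"):
            out = aggregate_minutes(s)
        assert len(out) == 0


class TestSlidingCV:
    def test_worked_example_all_printed_cells(self):
        """Published 11-minute VM example: every CV cell, scale 1e4."""
        pc2 = placement_cvs(TABLE1_VM, 2, scale=1e4)
        pc3 = placement_cvs(TABLE1_VM, 3, scale=1e4)
        min2 = sliding_cv(TABLE1_VM, 2, scale=1e4)
        min3 = sliding_cv(TABLE1_VM, 3, scale=1e4)
        for i, (b2, f2, b3, c3, f3, m2, m3) in TABLE1_CELLS.items():
            assert pc2[i, 0] == pytest.approx(b2, abs=0.05), f"cv2 backward @ row {i}"
            assert pc2[i, 1] == pytest.approx(f2, abs=0.05), f"cv2 forward @ row {i}"
            assert pc3[i, 0] == pytest.approx(b3, abs=0.05), f"cv3 backward @ row {i}"
            assert pc3[i, 1] == pytest.approx(c3, abs=0.05), f"cv3 center @ row {i}"
            assert pc3[i, 2] == pytest.approx(f3, abs=0.05), f"cv3 forward @ row {i}"
            assert min2[i] == pytest.approx(m2, abs=0.05), f"min cv2 @ row {i}"
            assert min3[i] == pytest.approx(m3, abs=0.05), f"min cv3 @ row {i}"

    @pytest.mark.parametrize("w", [2, 3, 4, 5])
    def test_edge_minutes_missing(self, w):
        out = sliding_cv(np.arange(1, 21, dtype=float), w)
        assert np.isnan(out[: w - 1]).all()
        assert np.isnan(out[len(out) - w + 1 :]).all()
        assert np.isfinite(out[w - 1 : len(out) - w + 1]).all()

    def test_min_over_available_fallback(self):
        out = sliding_cv(np.arange(1, 11, dtype=float), 3, require_all_placements=False)
        assert np.isfinite(out).all()

    @pytest.mark.parametrize("w", [2, 3, 4, 5])
    def test_constant_series_is_zero(self, w):
        out = sliding_cv(np.full(12, 7.5), w, scale=1e4)
        valid = out[~np.isnan(out)]
        assert len(valid) == 12 - 2 * (w - 1)
        np.testing.assert_allclose(valid, 0.0, atol=1e-9)

    @given(
        st.lists(st.floats(0.1, 2000), min_size=5, max_size=50),
        st.sampled_from([2, 3, 4, 5]),
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_brute_force_enumeration(self, values, w):
        if len(values) < w:
            values = values + [1.0] * (w - len(values))
        ours = sliding_cv(values, w, scale=100.0)
        oracle = brute_force_sliding_cv(values, w, scale=100.0)
        np.testing.assert_allclose(ours, oracle, rtol=1e-9, atol=1e-12, equal_nan=True)

    @given(
        st.lists(st.floats(0.5, 1500), min_size=9, max_size=40),
        st.sampled_from([2, 3, 4, 5]),
        st.floats(1e-3, 1e3),
    )
    @settings(max_examples=60, derandomize=True)
    def test_scale_invariance_in_values(self, values, w, c):
        # multiplying the series by any c > 0 leaves the CV unchanged
        base = sliding_cv(values, w)
        scaled = sliding_cv([c * v for v in values], w)
        np.testing.assert_allclose(base, scaled, rtol=1e-6, equal_nan=True)

    def test_minimum_rule_bounds_every_placement(self):
        rng = np.random.default_rng(11)
        values = rng.uniform(10, 100, 20)
        for w in (2, 3, 4, 5):
            pc = placement_cvs(values, w)
            mn = sliding_cv(values, w)
            ok = ~np.isnan(mn)
            assert (mn[ok][:, None] <= pc[ok] + 1e-12).all()

    def test_zero_mean_rules(self):
        # all-zero window: no variability, CV 0
        assert sliding_cv([0.0, 0.0, 0.0, 0.0], 2)[1] == 0.0
        # sd > 0 with zero mean: that placement is undefined and dropped
        pc = placement_cvs([-1.0, 1.0, 5.0, 6.0], 2)
        assert np.isnan(pc[1, 0])
        assert np.isfinite(pc[2, 1])

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            sliding_cv([1.0, 2.0], 3)


class TestFeatureTable:
    def _series(self, pid, site, minutes, seed=0, start="2020-01-06 08:00:00"):
        rng = np.random.default_rng(seed)
        n = minutes * 1800
        samples = np.tile([0.0, -1000.0, 0.0], (n, 1)) + rng.normal(0, 3, (n, 3))
        return RawTriaxialSeries(pid, site, pd.Timestamp(start), samples, 30.0)

    def _labels(self, pid, site, minutes, start="2020-01-06 08:00:00"):
        t0 = pd.Timestamp(start)
        return pd.DataFrame(
            {
                "participant_id": pid,
                "site": site,
                "minute_start": t0 + pd.to_timedelta(np.arange(minutes), unit="min"),
                "wear": ["wear"] * minutes,
                "state": ["sleep"] * minutes,
                "location": "rocker",
            }
        )

    def test_ten_minutes_with_edge_cvs_missing(self):
        table = build_feature_table(
            [self._series("P01", "hip", 10)], labels=self._labels("P01", "hip", 10), windows=(3,)
        )
        assert len(table) == 10
        assert table["cv3_vm"].isna().sum() == 4  # first/last w-1 minutes
        assert (table["wear"] == "wear").all()

    def test_two_sites_distinguishable(self):
        table = build_feature_table(
            [self._series("P01", "hip", 5), self._series("P01", "ankle", 5, seed=1)]
        )
        assert set(table["site"]) == {"hip", "ankle"}
        assert len(table) == 10

    def test_duplicate_minute_raises_with_timestamp(self):
        with pytest.raises(ValueError, match="2020-01-06 08:00:00"):
            build_feature_table(
                [self._series("P01", "hip", 3), self._series("P01", "hip", 3, seed=1)]
            )

    def test_misaligned_labels_reported(self):
        labels = self._labels("P01", "hip", 5, start="2020-01-06 08:01:00")
        with pytest.warns(UserWarning, match="did not match"):
            table = build_feature_table([self._series("P01", "hip", 5)], labels=labels)
        # the overlapping minutes still join
        assert table["wear"].notna().sum() == 4

    def test_pivot_sites_prefixes_and_label_agreement(self):
        table = build_feature_table(
            [self._series("P01", "hip", 5), self._series("P01", "ankle", 5, seed=1)],
            labels=pd.concat(
                [self._labels("P01", "hip", 5), self._labels("P01", "ankle", 5)],
                ignore_index=True,
            ),
        )
        wide = pivot_sites(table)
        assert len(wide) == 5
        assert "hip_incl_z" in wide.columns and "ankle_cv4_x" in wide.columns
        assert (wide["wear"] == "wear").all()
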