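"""Pupil preprocessing: binocular merge, filtering, outliers, metrics.

Numerical operations are checked against independent brute-force oracles:
a naive difference-equation evaluation for the filter, per-frame scans for
exclusions and interpolation, and explicit normal equations for the slope.
"""

import numpy as np
import pytest

from dyadload import pupil
from dyadload.core import PupilStream, UtteranceSegment, ValidationError
from dyadload.pupil import FilterSpec, OutlierSpec, Provenance


def series_from(values, t0=0.0):
    values = np.asarray(values, dtype=float)
    t = t0 + np.arange(values.size) / 50.0
    return PupilStream(t=t, left_mm=values, right_mm=values)


class TestMergeBinocular:
    def test_both_eyes_mean(self):
        s = pupil.merge_binocular(PupilStream(t=[0.0], left_mm=[3.0],
                                              right_mm=[3.2]))
        assert s.diameter_mm[0] == pytest.approx(3.1)
        assert s.flags[0] == Provenance.MERGED_BOTH

    def test_single_eye_used_directly(self):
        s = pupil.merge_binocular(PupilStream(t=[0.0, 0.02],
                                              left_mm=[np.nan, 3.4],
                                              right_mm=[3.2, np.nan]))
        assert s.diameter_mm[0] == pytest.approx(3.2)
        assert s.flags[0] == Provenance.RIGHT_ONLY
        assert s.diameter_mm[1] == pytest.approx(3.4)
        assert s.flags[1] == Provenance.LEFT_ONLY

    def test_neither_eye_invalid(self):
        s = pupil.merge_binocular(PupilStream(t=[0.0], left_mm=[np.nan],
                                              right_mm=[np.nan]))
        assert not s.valid[0]
        assert s.flags[0] == Provenance.MISSING


class TestInterpolateGaps:
    def test_linear_midpoint(self):
        s = pupil.merge_binocular(series_from([3.0, np.nan, 3.2]))
        out = pupil.interpolate_gaps(s)
        assert out.diameter_mm[1] == pytest.approx(3.1)
        assert out.flags[1] == Provenance.INTERPOLATED
        assert out.valid[1]

    def test_leading_gap_not_extrapolated(self):
        s = pupil.merge_binocular(series_from([np.nan, np.nan, 3.0, 3.2]))
        out = pupil.interpolate_gaps(s)
        assert not out.valid[0] and not out.valid[1]

    def test_long_gap_stays_invalid(self):
        vals = np.full(40, 3.0)
        vals[5:35] = np.nan        # 30-frame gap > default 25
        out = pupil.interpolate_gaps(pupil.merge_binocular(series_from(vals)))
        assert not out.valid[5:35].any()

    def test_random_gaps_match_piecewise_linear_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(20, 80))
            vals = rng.uniform(2.5, 4.5, n)
            mask = rng.random(n) < 0.3
            mask[0] = mask[-1] = False
            vals_missing = vals.copy()
            vals_missing[mask] = np.nan
            out = pupil.interpolate_gaps(
                pupil.merge_binocular(series_from(vals_missing)),
                max_gap_frames=n)
            idx = np.arange(n)
            oracle = np.interp(idx, idx[~mask], vals[~mask])
            assert np.allclose(out.diameter_mm[out.valid], oracle[out.valid],
                               atol=1e-12)


class TestLowpassFilter:
    def test_dc_gain_unity_on_constant(self):
        s = pupil.merge_binocular(series_from(np.full(500, 3.3)))
        out = pupil.lowpass_filter(s, FilterSpec())
        assert np.allclose(out.diameter_mm, 3.3, atol=1e-9)

    def test_causal_impulse_matches_difference_equation(self):
        # oracle: naive direct-form recursion of the same transfer function
        spec = FilterSpec(zero_phase=False)
        b, a = spec.coefficients()
        n = 200
        x = np.zeros(n)
        x[0] = 1.0
        base = 3.0
        s = pupil.merge_binocular(series_from(base + x))
        out = pupil.lowpass_filter(s, spec)
        y = np.zeros(n)
        xin = base + x
        for i in range(n):
            acc = sum(b[j] * xin[i - j] for j in range(len(b)) if i - j >= 0)
            acc -= sum(a[j] * y[i - j] for j in range(1, len(a)) if i - j >= 0)
            y[i] = acc / a[0]
        assert np.allclose(out.diameter_mm, y, atol=1e-9)

    def test_magnitude_response_at_stop_and_pass_bands(self):
        t = np.arange(2000) / 50.0
        for freq, lo, hi in ((10.0, 0.0, 0.05), (1.0, 0.95, 1.01)):
            x = 3.0 + np.sin(2 * np.pi * freq * t)
            out = pupil.lowpass_filter(
                pupil.merge_binocular(series_from(x)), FilterSpec())
            mid = out.diameter_mm[500:1500] - 3.0
            amp = (mid.max() - mid.min()) / 2.0
            assert lo <= amp <= hi

    def test_too_short_series_is_an_error(self):
        s = pupil.merge_binocular(series_from(np.full(10, 3.0)))
        with pytest.raises(ValidationError, match="at least"):
            pupil.lowpass_filter(s, FilterSpec())


class TestRemoveOutliers:
    def test_feasible_range_rule(self):
        vals = np.full(100, 3.0)
        vals[17] = 10.0
        out = pupil.remove_outliers(pupil.merge_binocular(series_from(vals)))
        assert out.excluded[17]
        assert out.excluded.sum() == 1

    def test_constant_series_nothing_excluded(self):
        out = pupil.remove_outliers(
            pupil.merge_binocular(series_from(np.full(50, 3.0))))
        assert not out.excluded.any()

    def test_planted_deviants_match_bruteforce_scan(self, rng):
        spec = OutlierSpec()
        for _ in range(200):
            n = int(rng.integers(30, 120))
            vals = rng.normal(3.5, 0.2, n)
            k = int(rng.integers(1, 4))
            pos = rng.choice(n, k, replace=False)
            vals[pos] += rng.choice([-1, 1], k) * rng.uniform(1.0, 3.0, k)
            vals = np.clip(vals, 0.2, None)
            out = pupil.remove_outliers(
                pupil.merge_binocular(series_from(vals)), spec)
            in_range = (vals >= spec.feasible_min_mm) & (vals <= spec.feasible_max_mm)
            mean, sd = vals[in_range].mean(), vals[in_range].std()
            oracle = ~in_range | (np.abs(vals - mean) > spec.z_threshold * sd)
            assert np.array_equal(out.excluded, oracle)

    def test_idempotent_with_stored_statistics(self, rng):
        vals = rng.normal(3.5, 0.3, 200)
        once = pupil.remove_outliers(pupil.merge_binocular(series_from(vals)))
        twice = pupil.remove_outliers(once, recompute_stats=False)
        assert np.array_equal(once.excluded, twice.excluded)

    def test_lowering_threshold_never_shrinks_exclusions(self, rng):
        vals = rng.normal(3.5, 0.4, 300)
        base = pupil.merge_binocular(series_from(vals))
        prev = None
        for z in (3.0, 2.0, 1.0, 0.5):
            out = pupil.remove_outliers(base, OutlierSpec(z_threshold=z))
            if prev is not None:
                assert np.all(out.excluded | ~prev)   # prev subset of current
            prev = out.excluded

    def test_global_scope_uses_supplied_statistics(self):
        vals = np.array([3.0, 3.1, 3.2, 5.0])
        spec = OutlierSpec(z_scope="global", global_mean=3.1, global_sd=0.1)
        out = pupil.remove_outliers(pupil.merge_binocular(series_from(vals)),
                                    spec)
        assert out.excluded.tolist() == [False, False, False, True]

    def test_all_excluded_is_an_error(self):
        vals = np.full(20, 12.0)    # everything outside the feasible range
        with pytest.raises(ValidationError, match="unusable"):
            pupil.remove_outliers(pupil.merge_binocular(series_from(vals)))


class TestBaseline:
    def test_constant_window(self):
        s = pupil.merge_binocular(series_from(np.full(250, 3.0)))
        b = pupil.extract_baseline(s, (0.0, 5.0))
        assert b.value_mm == pytest.approx(3.0)

    def test_mean_over_valid_frames_only(self):
        s = pupil.merge_binocular(
            series_from([3.0, 3.0, 4.0, np.nan]))
        b = pupil.extract_baseline(s, (0.0, 0.08))
        assert b.value_mm == pytest.approx(10.0 / 3.0)

    def test_insufficient_coverage_is_an_error(self):
        vals = np.full(100, np.nan)
        vals[:10] = 3.0
        s = pupil.merge_binocular(series_from(vals))
        with pytest.raises(ValidationError, match="50%"):
            pupil.extract_baseline(s, (0.0, 2.0))


class TestSegmentMetrics:
    @staticmethod
    def run(values, baseline_value=3.0, start=0.0, end=None):
        s = pupil.merge_binocular(series_from(values))
        b = pupil.PupilBaseline(role="builder", value_mm=baseline_value,
                                window=(-1.0, 0.0))
        end = end if end is not None else len(values) / 50.0
        seg = UtteranceSegment(instruction_id="i", fragment_ordinal=1,
                               start=start, end=end, referent_id="o")
        return pupil.segment_pupil_metrics(s, b, seg)

    def test_segment_at_baseline_gives_zeroes(self):
        mean, peak, slope = self.run(np.full(100, 3.0))
        assert mean == pytest.approx(0.0) and peak == pytest.approx(0.0)
        assert slope == pytest.approx(0.0)

    def test_linear_ramp_closed_form(self):
        a, b0 = 0.004, 3.0
        frames = np.arange(100)
        mean, peak, slope = self.run(b0 + a * frames)
        assert slope == pytest.approx(a, abs=1e-12)
        assert peak == pytest.approx(b0 + a * 99 - 3.0)

    def test_noisy_slope_matches_normal_equations(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 200))
            vals = rng.uniform(2.0, 5.0, n)
            _, _, slope = self.run(vals)
            frames = np.arange(n, dtype=float)
            oracle = (np.mean(frames * vals) - frames.mean() * vals.mean()) \
                / (np.mean(frames ** 2) - frames.mean() ** 2)
            assert slope == pytest.approx(oracle, abs=1e-10)

    def test_too_few_frames_undefined(self):
        vals = np.full(100, np.nan)
        vals[3] = 3.0
        assert self.run(vals) == (None, None, None)

    def test_peak_never_below_mean(self, rng):
        for _ in range(50):
            vals = rng.uniform(2.0, 5.0, int(rng.integers(2, 150)))
            mean, peak, _ = self.run(vals)
            assert peak >= mean
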