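"""Rate extraction, calibration, LOB/LOD, equivalence and interference."""

import numpy as np
import pytest
from scipy import stats

from altsense import (
    CalibrationCurve,
    KineticTrace,
    ValidationError,
    fit_calibration,
    fixed_interval_slope,
    interference_assessment,
    limit_of_blank,
    limit_of_blank_from_stats,
    limit_of_detection,
    max_window_slope,
    slopes_equivalent,
)


def make_trace(times, values):
    return KineticTrace("t", "electrical", times, values)


def ols_oracle(x, y):
    """Normal-equations OLS with t-based 95% slope CI (independent oracle)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (n - 2)
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(cov[1, 1])
    half = stats.t.ppf(0.975, n - 2) * se
    return beta[1], beta[0], (beta[1] - half, beta[1] + half)


class TestFixedIntervalSlope:
    def test_linear_trace_rate(self):
        t = np.arange(0.0, 601.0, 30.0)
        res = fixed_interval_slope(make_trace(t, 100.0 - 0.1 * t), 250.0, 500.0)
        assert res.rate == pytest.approx(0.1, abs=1e-12)
        assert res.slope == pytest.approx(-0.1, abs=1e-12)

    def test_constant_trace_rate_zero(self):
        t = np.arange(0.0, 601.0, 30.0)
        res = fixed_interval_slope(make_trace(t, np.full(t.size, 5.0)), 250.0, 500.0)
        assert res.rate == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            t = np.sort(rng.uniform(0, 600, 25))
            t += np.arange(25) * 1e-6  # strictly increasing
            y = rng.normal(size=25)
            res = fixed_interval_slope(make_trace(t, y), 100.0, 500.0)
            sel = (t >= 100.0) & (t <= 500.0)
            slope, _, _ = ols_oracle(t[sel], y[sel])
            assert res.slope == pytest.approx(slope, abs=1e-10)

    def test_window_too_sparse_rejected(self):
        t = np.arange(0.0, 601.0, 30.0)
        with pytest.raises(ValidationError):
            fixed_interval_slope(make_trace(t, t), 1000.0, 1100.0)


class TestMaxWindowSlope:
    def test_linear_trace_equals_global_slope_earliest_window(self):
        t = np.arange(0.0, 1200.0, 31.7)
        res = max_window_slope(make_trace(t, 50.0 - 0.02 * t))
        assert res.rate == pytest.approx(0.02, abs=1e-10)
        assert res.n_points == 6
        # earliest admissible window: first point at/after 300 s
        assert res.window_start == pytest.approx(t[t >= 300][0])

    def test_piecewise_trace_selects_fast_segment(self):
        t = np.arange(0.0, 1200.0, 31.7)
        y = np.where(t < 450, 100.0 - 0.05 * t, 100.0 - 0.05 * 450 - 0.2 * (t - 450))
        res = max_window_slope(make_trace(t, y))
        assert res.window_start >= 400.0
        assert res.rate > 0.15

    def test_six_point_windows_at_nominal_cycle_period(self):
        t = np.arange(0.0, 1200.0, 31.7)
        res = max_window_slope(make_trace(t, -t))
        assert res.n_points == 6
        assert res.window_end - res.window_start == pytest.approx(5 * 31.7)

    def test_dominates_fixed_interval(self, electrical_series):
        from altsense import process_sensor_run

        for e in electrical_series.entries[::7]:
            tr = process_sensor_run(e.data).as_trace()
            mx = max_window_slope(tr)
            fx = fixed_interval_slope(tr, 300.0, 460.0)
            assert mx.rate >= fx.rate - 1e-12

    def test_matches_brute_force_oracle_on_random_traces(self, rng):
        # Exhaustive enumeration oracle over all consecutive-point windows.
        for _ in range(200):
            n = rng.integers(25, 45)
            t = np.cumsum(rng.uniform(25, 38, n)) - 20.0
            y = rng.normal(size=n)
            tr = make_trace(t, y)
            try:
                res = max_window_slope(tr)
            except ValidationError:
                continue
            dt = np.median(np.diff(t))
            npts = max(int(round(160.0 / dt)) + 1, 2)
            best_rate, best_start = -np.inf, None
            for i in range(n - npts + 1):
                j = i + npts - 1
                if t[i] < 300.0 - 1e-9 or t[j] > 600.0 + 1e-9:
                    continue
                slope = np.polyfit(t[i : j + 1], y[i : j + 1], 1)[0]
                if -slope > best_rate + 1e-15:
                    best_rate, best_start = -slope, t[i]
            assert res.rate == pytest.approx(best_rate, abs=1e-10)
            assert res.window_start == pytest.approx(best_start)

    def test_no_admissible_window_rejected(self):
        t = np.arange(0.0, 250.0, 30.0)
        with pytest.raises(ValidationError):
            max_window_slope(make_trace(t, t))


class TestFitCalibration:
    def test_exact_line(self):
        pts = [(a, 2.0 * a + 1.0) for a in (50.0, 150.0, 250.0, 350.0, 450.0)]
        cal = fit_calibration(pts)
        assert cal.slope == pytest.approx(2.0, abs=1e-12)
        assert cal.intercept == pytest.approx(1.0, abs=1e-9)
        assert cal.r2 == pytest.approx(1.0, abs=1e-12)
        assert cal.ci95_slope[1] - cal.ci95_slope[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_oracle_with_t_ci(self, rng):
        for _ in range(50):
            x = np.repeat(np.arange(50.0, 451.0, 50.0), 3)
            y = 1e-4 + 3e-7 * x + rng.normal(0, 2e-6, x.size)
            cal = fit_calibration(np.column_stack([x, y]))
            slope, intercept, ci = ols_oracle(x, y)
            assert cal.slope == pytest.approx(slope, abs=1e-10)
            assert cal.intercept == pytest.approx(intercept, abs=1e-10)
            assert cal.ci95_slope[0] == pytest.approx(ci[0], abs=1e-10)
            assert cal.ci95_slope[1] == pytest.approx(ci[1], abs=1e-10)

    def test_blank_excluded_from_linear_range(self):
        pts = [(0.0, 99.0)] + [(a, 2.0 * a) for a in (50.0, 250.0, 450.0)]
        cal = fit_calibration(pts)
        assert cal.n == 3
        assert 0.0 not in cal.activities
        assert cal.slope == pytest.approx(2.0, abs=1e-12)

    def test_too_few_activities_rejected(self):
        with pytest.raises(ValidationError):
            fit_calibration([(50.0, 1.0), (100.0, 2.0)])


class TestLimits:
    def test_printed_blank_statistics_worked_example(self):
        lob = limit_of_blank_from_stats(1.1e-4, 4.4e-6)
        assert lob == pytest.approx(1.232e-4, rel=1e-12)

    def test_identical_blanks(self):
        assert limit_of_blank([2.0, 2.0, 2.0]) == 2.0

    def test_hand_arithmetic(self):
        assert limit_of_blank([0.0, 2.0]) == pytest.approx(1.0 + 3.0 * np.sqrt(2.0))

    def test_lod_worked_example(self):
        assert limit_of_detection(1.3e-5, 9.4e-6) == pytest.approx(4.149, abs=0.001)

    def test_lod_zero_sd(self):
        assert limit_of_detection(0.0, 1e-3) == 0.0

    def test_lod_arithmetic(self):
        assert limit_of_detection(3e-6, 1e-3) == pytest.approx(9e-3)

    def test_lod_requires_positive_slope(self):
        with pytest.raises(ValidationError):
            limit_of_detection(1e-6, 0.0)

    def test_lob_needs_two_values(self):
        with pytest.raises(ValidationError):
            limit_of_blank([1.0])

    def test_limits_invariant_to_time_unit_of_trace(self):
        # Rates expressed per second do not care whether the trace clock was
        # in s or min as long as the window follows the same rescaling.
        t = np.arange(0.0, 601.0, 30.0)
        y = 2.0 - 1.1e-4 * t
        r_s = fixed_interval_slope(make_trace(t, y), 250.0, 500.0).rate
        r_min = (
            fixed_interval_slope(
                KineticTrace("t", "electrical", t / 60.0, y), 250.0 / 60.0, 500.0 / 60.0
            ).rate
            / 60.0
        )
        assert r_s == pytest.approx(r_min, rel=1e-9)


def _cal(ci, slope=None):
    lo, hi = ci
    s = (lo + hi) / 2 if slope is None else slope
    return CalibrationCurve(
        activities=np.array([50.0, 250.0, 450.0]),
        rates=np.array([1.0, 2.0, 3.0]),
        slope=s,
        intercept=0.0,
        ci95_slope=(lo, hi),
        r2=1.0,
        residual_sd=0.0,
    )


class TestEquivalence:
    def test_printed_ci_pair_overlaps(self):
        rep = slopes_equivalent(_cal((3.4e-4, 4.3e-4)), _cal((3.5e-4, 4.5e-4)))
        assert rep.equivalent

    def test_disjoint_intervals(self):
        assert not slopes_equivalent(_cal((1.0, 2.0)), _cal((3.0, 4.0))).equivalent

    def test_shared_boundary_counts_as_overlap(self):
        assert slopes_equivalent(_cal((1.0, 2.0)), _cal((2.0, 3.0))).equivalent

    def test_non_finite_ci_rejected(self):
        with pytest.raises(ValidationError):
            slopes_equivalent(_cal((np.nan, 1.0)), _cal((1.0, 2.0)))


class TestInterference:
    def test_identical_series_is_clean(self, rng):
        x = np.repeat(np.arange(50.0, 451.0, 100.0), 2)
        y = 1.0 + 0.01 * x + rng.normal(0, 0.05, x.size)
        pts = np.column_stack([x, y])
        rep = interference_assessment(pts, pts)
        assert not rep.interference
        assert rep.p_value == pytest.approx(1.0, abs=1e-9)
        assert rep.slope_difference == pytest.approx(0.0, abs=1e-12)

    def test_halved_slope_detected(self, rng):
        x = np.repeat(np.arange(50.0, 451.0, 50.0), 3)
        noise = 0.02
        ctrl = np.column_stack([x, 0.01 * x + rng.normal(0, noise, x.size)])
        intf = np.column_stack([x, 0.005 * x + rng.normal(0, noise, x.size)])
        rep = interference_assessment(ctrl, intf)
        assert rep.interference
        assert rep.slope_difference < 0
        assert rep.ci95_difference[1] < 0

    def test_matches_closed_form_interaction_t_test(self, rng):
        # Independent oracle: explicit design-matrix algebra.
        x = np.repeat(np.arange(50.0, 451.0, 100.0), 2)
        yc = 0.01 * x + rng.normal(0, 0.1, x.size)
        yi = 0.012 * x + rng.normal(0, 0.1, x.size)
        rep = interference_assessment(
            np.column_stack([x, yc]), np.column_stack([x, yi])
        )
        xx = np.concatenate([x, x])
        yy = np.concatenate([yc, yi])
        g = np.concatenate([np.zeros(x.size), np.ones(x.size)])
        X = np.column_stack([np.ones(xx.size), xx, g, xx * g])
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        resid = yy - X @ beta
        s2 = resid @ resid / (xx.size - 4)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[3, 3])
        tstat = beta[3] / se
        p = 2 * stats.t.sf(abs(tstat), xx.size - 4)
        assert rep.slope_difference == pytest.approx(beta[3], abs=1e-10)
        assert rep.p_value == pytest.approx(p, abs=1e-10)

    def test_inadequate_points_rejected(self):
        with pytest.raises(ValidationError):
            interference_assessment([(50.0, 1.0)], [(50.0, 1.0), (100.0, 2.0)])
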