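"""Rate extraction, calibration, detection limits, equivalence, interference.

Sign convention: the assay's physical signals fall as ferricyanide is
consumed, so every reported *rate* is the magnitude of decrease (the
negated OLS slope); the raw signed slope is retained on the result.

Rates are extracted either over a fixed window (optical default 250-500 s,
electrical default 300-460 s) or as the start-time-independent maximum
slope: among all runs of consecutive cycles spanning ~160 s that lie fully
inside 300-600 s, the window with the largest magnitude of decrease (at the
nominal 31.7 s cycle period such a window holds six points).

Calibration is an OLS fit of rate vs activity restricted to the assay's
linear range (50-450 U/L; the 0 U/L blank is excluded from the fit but
feeds the limit of blank).  The detection limits follow the standard
definitions: LOB = mean blank rate + 3 * blank sd, and LOD = 3 s / m with s
the replicate sd at a low activity and m the calibration slope.  Two
calibrations are "equivalent" when their closed 95% slope CIs intersect;
interference is a significant difference between calibration slopes with
and without an interferant, tested via the group-by-activity interaction
term of a pooled regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import ValidationError
from .pipeline import process_sensor_run
from .traces import DilutionSeriesData, KineticTrace

__all__ = [
    "SlopeResult",
    "CalibrationCurve",
    "AssayLimits",
    "EquivalenceReport",
    "InterferenceReport",
    "fixed_interval_slope",
    "max_window_slope",
    "fit_calibration",
    "limit_of_blank",
    "limit_of_blank_from_stats",
    "limit_of_detection",
    "compute_assay_limits",
    "slopes_equivalent",
    "interference_assessment",
    "extract_series_rates",
    "OPTICAL_FIXED_WINDOW",
    "ELECTRICAL_FIXED_WINDOW",
    "MAX_SLOPE_SEARCH",
    "MAX_SLOPE_SPAN_S",
    "LINEAR_RANGE_U_PER_L",
    "ULN_U_PER_L",
]

OPTICAL_FIXED_WINDOW = (250.0, 500.0)
ELECTRICAL_FIXED_WINDOW = (300.0, 460.0)
MAX_SLOPE_SEARCH = (300.0, 600.0)
MAX_SLOPE_SPAN_S = 160.0
LINEAR_RANGE_U_PER_L = (50.0, 450.0)
#: Upper limit of normal for serum ALT adopted by the assay; 3x and 8x ULN
#: are the clinical-trial monitoring and stopping thresholds.
ULN_U_PER_L = 50.0

_TIME_TOL = 1e-9


@dataclass(frozen=True)
class SlopeResult:
    """An extracted signal rate. ``rate`` = magnitude of decrease (-slope)."""

    rate: float
    slope: float
    window_start: float
    window_end: float
    n_points: int
    fit_r2: float


@dataclass
class CalibrationCurve:
    """OLS calibration of rate vs ALT activity with a t-based 95% slope CI."""

    activities: np.ndarray
    rates: np.ndarray
    slope: float
    intercept: float
    ci95_slope: tuple[float, float]
    r2: float
    residual_sd: float
    label: str = ""

    @property
    def n(self) -> int:
        return int(self.activities.size)


@dataclass(frozen=True)
class AssayLimits:
    """Limit of blank (signal-rate units) and limit of detection (U/L)."""

    lob: float
    blank_mean: float
    blank_sd: float
    lod: float
    low_sd: float
    slope: float


@dataclass(frozen=True)
class EquivalenceReport:
    equivalent: bool
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    label_a: str = ""
    label_b: str = ""


@dataclass(frozen=True)
class InterferenceReport:
    interference: bool
    p_value: float
    alpha: float
    slope_control: float
    slope_interferant: float
    slope_difference: float
    ci95_difference: tuple[float, float]


def _ols_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.linregress(t, y)
    return float(res.slope), float(res.rvalue**2)


def fixed_interval_slope(
    trace: KineticTrace, t_start: float, t_end: float
) -> SlopeResult:
    """OLS rate over the points whose times fall in the closed window."""
    if t_end <= t_start:
        raise ValidationError("t_end must exceed t_start")
    sel = (trace.times >= t_start - _TIME_TOL) & (trace.times <= t_end + _TIME_TOL)
    n = int(sel.sum())
    if n < 2:
        raise ValidationError(
            f"window [{t_start}, {t_end}] contains {n} point(s); need >= 2"
        )
    t = trace.times[sel]
    slope, r2 = _ols_slope(t, trace.values[sel])
    return SlopeResult(
        rate=-slope,
        slope=slope,
        window_start=float(t[0]),
        window_end=float(t[-1]),
        n_points=n,
        fit_r2=r2,
    )


def window_point_count(trace: KineticTrace, window_span: float) -> int:
    """Points per sliding window: span / median cycle period, rounded, min 2.

    At the nominal 31.7 s cycle period a 160 s window rounds to 5 intervals,
    i.e. six consecutive points.
    """
    if len(trace) < 2:
        raise ValidationError("trace too short for a sliding window")
    dt = float(np.median(np.diff(trace.times)))
    return max(int(round(window_span / dt)) + 1, 2)


def max_window_slope(
    trace: KineticTrace,
    window_span: float = MAX_SLOPE_SPAN_S,
    search_start: float = MAX_SLOPE_SEARCH[0],
    search_end: float = MAX_SLOPE_SEARCH[1],
) -> SlopeResult:
    """Start-time-independent rate: steepest decrease over sliding windows.

    Windows are runs of consecutive cycles spanning ``window_span`` that
    start and end inside ``[search_start, search_end]``; the window
    maximising the magnitude of decrease wins, ties broken by the earliest
    window.
    """
    n_pts = window_point_count(trace, window_span)
    t, y = trace.times, trace.values
    best: SlopeResult | None = None
    for i in range(len(trace) - n_pts + 1):
        j = i + n_pts - 1
        if t[i] < search_start - _TIME_TOL:
            continue
        if t[j] > search_end + _TIME_TOL:
            break
        slope, r2 = _ols_slope(t[i : j + 1], y[i : j + 1])
        # numerically tied windows keep the earliest start
        tie_tol = 1e-12 * max(abs(slope), best.rate if best else 0.0, 1e-300)
        if best is None or -slope > best.rate + tie_tol:
            best = SlopeResult(
                rate=-slope,
                slope=slope,
                window_start=float(t[i]),
                window_end=float(t[j]),
                n_points=n_pts,
                fit_r2=r2,
            )
    if best is None:
        raise ValidationError(
            f"no {n_pts}-point window lies fully inside "
            f"[{search_start}, {search_end}]"
        )
    return best


def fit_calibration(
    points: list[tuple[float, float]] | np.ndarray,
    range_min: float = LINEAR_RANGE_U_PER_L[0],
    range_max: float = LINEAR_RANGE_U_PER_L[1],
    label: str = "",
) -> CalibrationCurve:
    """OLS rate-vs-activity fit restricted to the closed [range_min, range_max].

    The 95% slope CI uses the t distribution with n-2 df.  Activities
    outside the range (notably the 0 U/L blank) are excluded.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("points must be (activity, rate) pairs")
    sel = (arr[:, 0] >= range_min) & (arr[:, 0] <= range_max)
    x, y = arr[sel, 0], arr[sel, 1]
    if np.unique(x).size < 3:
        raise ValidationError(
            f"need >= 3 distinct activities in [{range_min}, {range_max}], "
            f"got {np.unique(x).size}"
        )
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in activity")
    res = stats.linregress(x, y)
    n = x.size
    tcrit = stats.t.ppf(0.975, n - 2)
    half = tcrit * res.stderr
    resid = y - (res.intercept + res.slope * x)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    return CalibrationCurve(
        activities=x,
        rates=y,
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci95_slope=(float(res.slope - half), float(res.slope + half)),
        r2=float(res.rvalue**2),
        residual_sd=residual_sd,
        label=label,
    )


def limit_of_blank(blank_rates: list[float] | np.ndarray) -> float:
    """LOB: mean blank rate + 3 sample standard deviations."""
    r = np.asarray(blank_rates, dtype=float)
    if r.size < 2:
        raise ValidationError("limit_of_blank needs >= 2 blank rates")
    return float(r.mean() + 3.0 * r.std(ddof=1))


def limit_of_blank_from_stats(blank_mean: float, blank_sd: float) -> float:
    """LOB from pre-computed blank statistics (mean + 3 sd)."""
    if blank_sd < 0:
        raise ValidationError("blank_sd must be >= 0")
    return float(blank_mean + 3.0 * blank_sd)


def limit_of_detection(s_low: float, m: float) -> float:
    """LOD in activity units: 3 s / m.

    ``s_low`` is the replicate sd of the rate at a low activity and ``m``
    the calibration slope (rate per U/L).
    """
    if m <= 0:
        raise ValidationError("calibration slope m must be > 0")
    if s_low < 0:
        raise ValidationError("s_low must be >= 0")
    return float(3.0 * s_low / m)


def compute_assay_limits(
    blank_rates: list[float] | np.ndarray,
    low_rates: list[float] | np.ndarray,
    calibration: CalibrationCurve,
) -> AssayLimits:
    """LOB from blanks and LOD from low-level replicates + calibration slope."""
    blanks = np.asarray(blank_rates, dtype=float)
    lows = np.asarray(low_rates, dtype=float)
    if lows.size < 2:
        raise ValidationError("need >= 2 low-activity replicate rates for LOD")
    s_low = float(lows.std(ddof=1))
    return AssayLimits(
        lob=limit_of_blank(blanks),
        blank_mean=float(blanks.mean()),
        blank_sd=float(blanks.std(ddof=1)),
        lod=limit_of_detection(s_low, calibration.slope),
        low_sd=s_low,
        slope=calibration.slope,
    )


def slopes_equivalent(
    cal_a: CalibrationCurve, cal_b: CalibrationCurve
) -> EquivalenceReport:
    """True iff the closed 95% slope CIs intersect (shared-boundary counts)."""
    for cal in (cal_a, cal_b):
        if not all(np.isfinite(cal.ci95_slope)):
            raise ValidationError(
                f"calibration {cal.label!r} has a non-finite slope CI"
            )
    a_lo, a_hi = cal_a.ci95_slope
    b_lo, b_hi = cal_b.ci95_slope
    overlap = (a_lo <= b_hi) and (b_lo <= a_hi)
    return EquivalenceReport(
        equivalent=bool(overlap),
        ci_a=cal_a.ci95_slope,
        ci_b=cal_b.ci95_slope,
        label_a=cal_a.label,
        label_b=cal_b.label,
    )


def interference_assessment(
    control_points: list[tuple[float, float]] | np.ndarray,
    interferant_points: list[tuple[float, float]] | np.ndarray,
    alpha: float = 0.05,
) -> InterferenceReport:
    """Test whether an interferant changes the calibration slope.

    Pooled OLS of rate on activity, group indicator and their interaction;
    the interaction t-test (p < alpha) declares interference.  The report
    carries the slope difference (interferant - control) and its 95% CI.
    """
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    ctrl = np.asarray(control_points, dtype=float)
    intf = np.asarray(interferant_points, dtype=float)
    for name, arr in (("control", ctrl), ("interferant", intf)):
        if arr.ndim != 2 or arr.shape[1] != 2 or np.unique(arr[:, 0]).size < 3:
            raise ValidationError(
                f"{name} series needs >= 3 distinct activities of (activity, rate)"
            )
    x = np.concatenate([ctrl[:, 0], intf[:, 0]])
    y = np.concatenate([ctrl[:, 1], intf[:, 1]])
    g = np.concatenate([np.zeros(len(ctrl)), np.ones(len(intf))])
    design = sm.add_constant(np.column_stack([x, g, x * g]))
    fit = sm.OLS(y, design).fit()
    delta = float(fit.params[3])
    se = float(fit.bse[3])
    slope_ctrl = float(fit.params[1])
    if se == 0 or not np.isfinite(se):
        # Perfectly collinear residual-free fit: identical slopes are a clean
        # no-interference verdict; anything else is degenerate.
        if abs(delta) < 1e-12:
            p_value, ci = 1.0, (0.0, 0.0)
        else:
            raise ValidationError("degenerate interference fit: zero residual variance")
    else:
        p_value = float(fit.pvalues[3])
        lo, hi = fit.conf_int(alpha=0.05)[3]
        ci = (float(lo), float(hi))
    return InterferenceReport(
        interference=bool(p_value < alpha),
        p_value=p_value,
        alpha=alpha,
        slope_control=slope_ctrl,
        slope_interferant=slope_ctrl + delta,
        slope_difference=delta,
        ci95_difference=ci,
    )


def extract_series_rates(
    data: DilutionSeriesData,
    method: str = "fixed",
    baseline_t_ref: float = 144.0,
) -> list[tuple[float, int, SlopeResult]]:
    """Per-entry rates for a dilution series.

    Optical traces are used directly; electrical runs are first conditioned
    through the full pipeline (boxcar -> offset at ``baseline_t_ref`` ->
    percent-full-scale rescale -> ensemble average) and the rate is taken on
    the ensemble mean.  ``method`` is ``"fixed"`` (window 250-500 s optical /
    300-460 s electrical) or ``"max"`` (steepest ~160 s window in 300-600 s).
    """
    if method not in ("fixed", "max"):
        raise ValidationError(f"method must be 'fixed' or 'max', got {method!r}")
    out = []
    for e in data.entries:
        if data.modality == "optical":
            trace = e.data
        else:
            trace = process_sensor_run(e.data, t_ref=baseline_t_ref).as_trace()
        if method == "fixed":
            lo, hi = (
                OPTICAL_FIXED_WINDOW
                if data.modality == "optical"
                else ELECTRICAL_FIXED_WINDOW
            )
            res = fixed_interval_slope(trace, lo, hi)
        else:
            res = max_window_slope(trace)
        out.append((e.alt_activity, e.replicate, res))
    return out
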