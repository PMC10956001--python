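"""Trace conditioning for multiplexed sensor records.

The processing chain mirrors how the multiplexed assay records are prepared
before rate extraction: raw samples are boxcar averaged within each
measurement cycle, each sensor is offset to an equal baseline at a reference
time (default 144 s), min-max rescaled to percent full scale,

    %FS = (y - y_min) / (y_max - y_min) * 100,

and finally ensemble averaged across the array at each cycle.  Averaging n
independent sensors improves the signal-to-noise ratio by sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateTraceError, ValidationError
from .traces import KineticTrace, SensorArrayRun

__all__ = [
    "EnsembleTrace",
    "boxcar_average_cycles",
    "baseline_offset",
    "rescale_percent_fs",
    "ensemble_average",
    "process_sensor_run",
    "write_ensemble_csv",
]

BASELINE_REFERENCE_S = 144.0


@dataclass
class EnsembleTrace:
    """Cross-sensor mean +/- sd of percent-full-scale traces, per cycle."""

    bin_times: np.ndarray
    mean_pct_fs: np.ndarray
    sd_pct_fs: np.ndarray
    n: int
    meta: dict = field(default_factory=dict)

    def as_trace(self, channel_id: str = "ensemble") -> KineticTrace:
        return KineticTrace(
            channel_id=channel_id,
            modality="electrical",
            times=self.bin_times,
            values=self.mean_pct_fs,
            meta=dict(self.meta),
        )


def boxcar_average_cycles(trace: KineticTrace) -> KineticTrace:
    """Collapse raw samples to one (mean time, mean value) point per cycle.

    Cycle order of first appearance is preserved; every cycle must contain at
    least one sample (cycles are taken from the trace's cycle tags, so an
    untagged trace is rejected).
    """
    if trace.cycles is None:
        raise ValidationError(
            f"trace {trace.channel_id!r}: boxcar averaging needs cycle tags"
        )
    if len(trace) == 0:
        raise ValidationError("cannot boxcar average an empty trace")
    cycles, first_idx = np.unique(trace.cycles, return_index=True)
    order = np.argsort(first_idx)  # preserve order of appearance
    cycles = cycles[order]
    t_mean = np.empty(cycles.size)
    v_mean = np.empty(cycles.size)
    for j, c in enumerate(cycles):
        sel = trace.cycles == c
        t_mean[j] = trace.times[sel].mean()
        v_mean[j] = trace.values[sel].mean()
    return KineticTrace(
        channel_id=trace.channel_id,
        modality=trace.modality,
        times=t_mean,
        values=v_mean,
        cycles=cycles,
        meta=dict(trace.meta),
    )


def baseline_offset(trace: KineticTrace, t_ref: float = BASELINE_REFERENCE_S) -> KineticTrace:
    """Shift a trace so its value at the sample nearest ``t_ref`` is zero.

    No interpolation: the nearest sample is used, ties broken toward the
    earlier one.  Pairwise differences are preserved exactly.
    """
    if len(trace) == 0:
        raise ValidationError("cannot offset an empty trace")
    if not (trace.times[0] <= t_ref <= trace.times[-1]):
        raise ValidationError(
            f"t_ref={t_ref} outside trace span "
            f"[{trace.times[0]}, {trace.times[-1]}]"
        )
    idx = int(np.argmin(np.abs(trace.times - t_ref)))  # argmin -> earlier on ties
    return trace.replace_values(trace.values - trace.values[idx])


def rescale_percent_fs(trace: KineticTrace, epsilon: float = 1e-9) -> KineticTrace:
    """Min-max rescale a trace to percent full scale (0 at min, 100 at max).

    Order-preserving, affine-invariant and idempotent.  A trace whose range
    is at or below ``epsilon`` (in signal units) cannot define a full scale
    and raises :class:`DegenerateTraceError`.
    """
    if len(trace) == 0:
        raise ValidationError("cannot rescale an empty trace")
    lo = float(trace.values.min())
    hi = float(trace.values.max())
    if hi - lo <= epsilon:
        raise DegenerateTraceError(
            f"trace {trace.channel_id!r}: range {hi - lo:.3e} <= epsilon "
            f"{epsilon:.3e}; cannot rescale to percent full scale"
        )
    return trace.replace_values((trace.values - lo) / (hi - lo) * 100.0)


def ensemble_average(traces: list[KineticTrace]) -> EnsembleTrace:
    """Per-cycle mean and sample sd across cycle-aligned traces.

    Traces are aligned by cycle index (all sensors are read within one
    multiplexer cycle), so they must share the sample count.  Bin times are
    the across-sensor mean times of each cycle.  With a single trace the sd
    is zero by convention.
    """
    if not traces:
        raise ValidationError("ensemble_average needs at least one trace")
    lengths = {len(t) for t in traces}
    if len(lengths) > 1:
        raise ValidationError(f"traces have unequal lengths: {sorted(lengths)}")
    values = np.vstack([t.values for t in traces])
    times = np.vstack([t.times for t in traces])
    n = len(traces)
    sd = np.std(values, axis=0, ddof=1) if n > 1 else np.zeros(values.shape[1])
    return EnsembleTrace(
        bin_times=times.mean(axis=0),
        mean_pct_fs=values.mean(axis=0),
        sd_pct_fs=sd,
        n=n,
    )


def process_sensor_run(
    run: SensorArrayRun,
    t_ref: float = BASELINE_REFERENCE_S,
    rescale_epsilon: float = 1e-9,
) -> EnsembleTrace:
    """Full conditioning chain for one sensor-array run.

    boxcar average per cycle -> per-sensor baseline offset at ``t_ref`` ->
    percent-full-scale rescale -> cross-sensor ensemble average.
    """
    processed = []
    for tr in run.sensors:
        tr = boxcar_average_cycles(tr)
        tr = baseline_offset(tr, t_ref)
        tr = rescale_percent_fs(tr, rescale_epsilon)
        processed.append(tr)
    ens = ensemble_average(processed)
    ens.meta = dict(run.meta)
    return ens


def write_ensemble_csv(ens: EnsembleTrace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bin_time_s": ens.bin_times,
            "mean_pct_fs": ens.mean_pct_fs,
            "sd_pct_fs": ens.sd_pct_fs,
            "n": ens.n,
        }
    ).to_csv(path, index=False, float_format="%.17g")
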