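"""In-memory containers for kinetic traces and sensor-array runs."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .errors import ValidationError

__all__ = ["KineticTrace", "SensorArrayRun", "DilutionEntry", "DilutionSeriesData"]

MODALITIES = ("optical", "electrical")


@dataclass
class KineticTrace:
    """One channel's kinetic time series.

    ``values`` are AU for the optical modality and nA for the electrical
    modality (``%FS`` after rescaling).  ``cycles`` optionally tags each
    sample with its multiplexer measurement-cycle index; electrical raw
    records carry several samples per cycle which are later boxcar averaged.
    """

    channel_id: str
    modality: str
    times: np.ndarray
    values: np.ndarray
    cycles: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValidationError(
                f"trace {self.channel_id!r}: times and values must be 1-D and the "
                f"same length ({self.times.shape} vs {self.values.shape})"
            )
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"trace {self.channel_id!r}: times must be strictly increasing"
            )
        if self.cycles is not None:
            self.cycles = np.asarray(self.cycles, dtype=int)
            if self.cycles.shape != self.times.shape:
                raise ValidationError(
                    f"trace {self.channel_id!r}: cycles must align with times"
                )

    def __len__(self) -> int:
        return int(self.times.size)

    def replace_values(self, values: np.ndarray) -> "KineticTrace":
        """New trace with the same time base / metadata and new values."""
        return KineticTrace(
            channel_id=self.channel_id,
            modality=self.modality,
            times=self.times.copy(),
            values=np.asarray(values, dtype=float),
            cycles=None if self.cycles is None else self.cycles.copy(),
            meta=dict(self.meta),
        )


@dataclass
class SensorArrayRun:
    """Aligned multi-sensor electrical traces sharing a cycle index.

    ``cycle_times`` are the per-cycle timestamps (cycle midpoints) shared by
    all sensors of the multiplexed array (default array size: 7).
    """

    run_id: str
    sensors: list[KineticTrace]
    cycle_times: np.ndarray
    cycle_period_mean_s: float
    cycle_period_sd_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cycle_times = np.asarray(self.cycle_times, dtype=float)
        if not self.sensors:
            raise ValidationError(f"run {self.run_id!r}: needs at least one sensor")
        counts = {}
        for tr in self.sensors:
            if tr.cycles is None:
                raise ValidationError(
                    f"run {self.run_id!r}: sensor {tr.channel_id!r} lacks cycle tags"
                )
            counts[tr.channel_id] = int(np.unique(tr.cycles).size)
        if len(set(counts.values())) > 1:
            raise ValidationError(
                f"run {self.run_id!r}: sensors have unequal cycle counts: {counts}"
            )
        n_cycles = next(iter(counts.values()))
        if self.cycle_times.size != n_cycles:
            raise ValidationError(
                f"run {self.run_id!r}: {self.cycle_times.size} cycle times for "
                f"{n_cycles} cycles"
            )

    @property
    def n_sensors(self) -> int:
        return len(self.sensors)

    @property
    def n_cycles(self) -> int:
        return int(self.cycle_times.size)


@dataclass
class DilutionEntry:
    """One labelled dataset of a dilution series."""

    alt_activity: float
    replicate: int
    data: Union[KineticTrace, SensorArrayRun]


@dataclass
class DilutionSeriesData:
    """A dilution series: one entry per (activity, replicate) pair."""

    modality: str
    entries: list[DilutionEntry]

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        seen = set()
        for e in self.entries:
            if e.alt_activity < 0:
                raise ValidationError("activities must be >= 0")
            key = (float(e.alt_activity), int(e.replicate))
            if key in seen:
                raise ValidationError(
                    f"duplicate (activity, replicate) pair {key} in dilution series"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def activities(self) -> np.ndarray:
        return np.array(sorted({e.alt_activity for e in self.entries}))
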