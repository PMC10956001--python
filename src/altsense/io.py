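"""CSV dialects for plate-reader kinetic tables and multiplexed sensor logs.

Both dialects are long (tidy) layouts, UTF-8, comma-separated, '.' decimal,
times in seconds from reagent addition (t=0 = injection).

Plate dialect: columns ``time_s, well, alt_u_per_l, replicate, absorbance_au``.
Sensor dialect: comment header lines (``# key=value``) carrying run metadata
and the shared cycle timestamps, then columns
``cycle, sensor_id, time_s, current_na``.

Values are written with 17 significant digits so a write -> read round trip
is identity on the floats.  Schema violations raise :class:`SchemaError`
naming the offending column or key; rows are never silently dropped.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .traces import DilutionEntry, DilutionSeriesData, KineticTrace, SensorArrayRun

__all__ = [
    "read_plate_csv",
    "write_plate_csv",
    "read_sensor_csv",
    "write_sensor_csv",
    "write_sensor_series",
    "read_sensor_series",
]

PLATE_COLUMNS = ["time_s", "well", "alt_u_per_l", "replicate", "absorbance_au"]
SENSOR_COLUMNS = ["cycle", "sensor_id", "time_s", "current_na"]
_FLOAT_FMT = "%.17g"


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def write_plate_csv(data: DilutionSeriesData, path: str | Path) -> None:
    """Write an optical dilution series as a long-format plate CSV."""
    if data.modality != "optical":
        raise ValidationError("write_plate_csv expects an optical dilution series")
    frames = []
    for e in data.entries:
        tr = e.data
        if not isinstance(tr, KineticTrace):
            raise ValidationError("optical entries must hold KineticTrace data")
        frames.append(
            pd.DataFrame(
                {
                    "time_s": tr.times,
                    "well": tr.channel_id,
                    "alt_u_per_l": e.alt_activity,
                    "replicate": e.replicate,
                    "absorbance_au": tr.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_plate_csv(path: str | Path) -> DilutionSeriesData:
    """Read a long-format plate CSV into a dilution series of optical traces."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: no such file")
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PLATE_COLUMNS, path)
    dup = df.duplicated(subset=["well", "time_s"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise SchemaError(
            f"{path}: duplicated (well, time_s) key "
            f"({row['well']!r}, {row['time_s']})"
        )
    entries = []
    for well, grp in df.groupby("well", sort=False):
        t = grp["time_s"].to_numpy(dtype=float)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise SchemaError(f"{path}: non-monotone time_s within well {well!r}")
        alt = grp["alt_u_per_l"].to_numpy(dtype=float)
        rep = grp["replicate"].to_numpy()
        if np.unique(alt).size > 1 or np.unique(rep).size > 1:
            raise SchemaError(
                f"{path}: well {well!r} mixes multiple (alt_u_per_l, replicate) labels"
            )
        entries.append(
            DilutionEntry(
                alt_activity=float(alt[0]),
                replicate=int(rep[0]),
                data=KineticTrace(
                    channel_id=str(well),
                    modality="optical",
                    times=t,
                    values=grp["absorbance_au"].to_numpy(dtype=float),
                    meta={"alt_u_per_l": float(alt[0]), "replicate": int(rep[0])},
                ),
            )
        )
    return DilutionSeriesData(modality="optical", entries=entries)


def write_sensor_csv(run: SensorArrayRun, path: str | Path) -> None:
    """Write one sensor-array run as a long-format CSV with a metadata header."""
    lines = ["# altsense sensor run v1", f"# run_id={run.run_id}"]
    for key in ("alt_u_per_l", "replicate"):
        if key in run.meta:
            lines.append(f"# {key}={run.meta[key]:g}")
    lines.append(f"# cycle_period_mean_s={run.cycle_period_mean_s:.17g}")
    lines.append(f"# cycle_period_sd_s={run.cycle_period_sd_s:.17g}")
    lines.append("# cycle_times=" + ",".join(f"{t:.17g}" for t in run.cycle_times))
    frames = []
    for tr in run.sensors:
        frames.append(
            pd.DataFrame(
                {
                    "cycle": tr.cycles,
                    "sensor_id": tr.channel_id,
                    "time_s": tr.times,
                    "current_na": tr.values,
                }
            )
        )
    body = pd.concat(frames, ignore_index=True).to_csv(
        index=False, float_format=_FLOAT_FMT
    )
    Path(path).write_text("\n".join(lines) + "\n" + body)


def _parse_header(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            line = line[1:].strip()
            if "=" in line:
                key, val = line.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


def read_sensor_csv(path: str | Path) -> SensorArrayRun:
    """Read one sensor-array run; sensors must share the cycle count."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: no such file")
    header = _parse_header(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _require_columns(df, SENSOR_COLUMNS, path)

    counts = {
        str(sid): int(grp["cycle"].nunique())
        for sid, grp in df.groupby("sensor_id", sort=False)
    }
    if len(set(counts.values())) > 1:
        bad = {k: v for k, v in counts.items()}
        raise SchemaError(f"{path}: sensors have unequal cycle counts: {bad}")

    sensors = []
    meta = {}
    for key in ("alt_u_per_l", "replicate"):
        if key in header:
            meta[key] = float(header[key]) if key == "alt_u_per_l" else int(
                float(header[key])
            )
    for sid, grp in df.groupby("sensor_id", sort=False):
        sensors.append(
            KineticTrace(
                channel_id=str(sid),
                modality="electrical",
                times=grp["time_s"].to_numpy(dtype=float),
                values=grp["current_na"].to_numpy(dtype=float),
                cycles=grp["cycle"].to_numpy(dtype=int),
            )
        )
    if "cycle_times" not in header:
        raise SchemaError(f"{path}: missing '# cycle_times=' header line")
    cycle_times = np.array([float(x) for x in header["cycle_times"].split(",")])
    return SensorArrayRun(
        run_id=header.get("run_id", path.stem),
        sensors=sensors,
        cycle_times=cycle_times,
        cycle_period_mean_s=float(header.get("cycle_period_mean_s", "nan")),
        cycle_period_sd_s=float(header.get("cycle_period_sd_s", "nan")),
        meta=meta,
    )


def write_sensor_series(data: DilutionSeriesData, out_dir: str | Path) -> list[Path]:
    """Write each run of an electrical dilution series to ``out_dir``."""
    if data.modality != "electrical":
        raise ValidationError("write_sensor_series expects an electrical series")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for e in data.entries:
        run = e.data
        if not isinstance(run, SensorArrayRun):
            raise ValidationError("electrical entries must hold SensorArrayRun data")
        run.meta.setdefault("alt_u_per_l", float(e.alt_activity))
        run.meta.setdefault("replicate", int(e.replicate))
        p = out_dir / f"sensor_a{e.alt_activity:g}_r{e.replicate}.csv"
        write_sensor_csv(run, p)
        paths.append(p)
    return paths


def read_sensor_series(in_dir: str | Path) -> DilutionSeriesData:
    """Read every ``sensor_*.csv`` in a directory into a dilution series."""
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob("sensor_*.csv"))
    if not paths:
        raise SchemaError(f"{in_dir}: no sensor_*.csv files found")
    entries = []
    for p in paths:
        run = read_sensor_csv(p)
        if "alt_u_per_l" not in run.meta or "replicate" not in run.meta:
            raise SchemaError(f"{p}: header lacks alt_u_per_l/replicate metadata")
        entries.append(
            DilutionEntry(
                alt_activity=float(run.meta["alt_u_per_l"]),
                replicate=int(run.meta["replicate"]),
                data=run,
            )
        )
    return DilutionSeriesData(modality="electrical", entries=entries)
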