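"""Mechanistic simulator of the coupled ALT -> POX -> ferricyanide assay.

The model integrates three species in the well: pyruvate, ferricyanide and
ferrocyanide (uM).  Pyruvate is produced at the constant zero-order rate
``v_eff = alt_activity * sample_fraction`` uM/min (ALT substrates saturating;
1 U converts 1 umol/min), consumed by Michaelis-Menten pyruvate oxidase, and
each consumed pyruvate reduces ``ferri_per_pyruvate`` (default 2)
ferricyanide ions.  FAD/FADH2 recycling is treated as instantaneous: the
terminal, rate-observed oxidant is ferricyanide itself.  The reaction halts
smoothly as ferricyanide exhausts.

Two renderers turn the reaction states into instrument records: a
Beer-Lambert 420 nm absorbance trace sampled at fixed intervals, and a
multiplexed nanowire sensor-array run sampled at jittered measurement
cycles.  A Debye-length utility estimates the electrostatic sensing range of
the nanowire surface in an electrolyte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants as sc
from scipy.integrate import solve_ivp

from .config import (
    KineticParams,
    NoiseModel,
    OpticalRender,
    ReagentConditions,
    SensorRender,
    SimulationConfig,
)
from .errors import SimulationError, ValidationError
from .traces import DilutionEntry, DilutionSeriesData, KineticTrace, SensorArrayRun

__all__ = [
    "ReactionStates",
    "SensorDieParams",
    "draw_sensor_die",
    "simulate_reaction",
    "render_optical_trace",
    "render_sensor_run",
    "generate_dilution_series",
    "compute_debye_length",
]

# Integrator tolerances are fixed (not exposed) so the species-conservation
# guarantee of the model is meaningful and test-able.
_ODE_RTOL = 1e-8
_ODE_ATOL = 1e-10


@dataclass(frozen=True)
class ReactionStates:
    """Reaction trajectory on a fixed time grid (all concentrations uM)."""

    t: np.ndarray
    pyruvate: np.ndarray
    ferricyanide: np.ndarray
    ferrocyanide: np.ndarray
    ferricyanide0: float

    def __len__(self) -> int:
        return int(self.t.size)

    def ferro_fraction(self, at: np.ndarray) -> np.ndarray:
        """Converted ferrocyanide fraction, linearly interpolated at times ``at``."""
        if self.ferricyanide0 <= 0:
            return np.zeros_like(np.asarray(at, dtype=float))
        return np.interp(at, self.t, self.ferrocyanide) / self.ferricyanide0

    def ferricyanide_at(self, at: np.ndarray) -> np.ndarray:
        return np.interp(at, self.t, self.ferricyanide)


def simulate_reaction(
    alt_activity: float,
    conditions: ReagentConditions | None = None,
    kinetics: KineticParams | None = None,
    duration: float = 1200.0,
    step: float = 1.0,
) -> ReactionStates:
    """Integrate the coupled reaction for a sample of ``alt_activity`` U/L.

    ``alt_activity`` is the serum-scale activity of the sample; the in-well
    pyruvate production rate is ``alt_activity * sample_fraction`` uM/min.
    States are returned on the grid ``0, step, 2*step, ... duration``.
    """
    if alt_activity < 0:
        raise ValidationError("alt_activity must be >= 0")
    if duration <= 0 or step <= 0:
        raise ValidationError("duration and step must be > 0")
    conditions = conditions or ReagentConditions()
    kinetics = kinetics or KineticParams()

    f0 = conditions.ferricyanide0_um
    v_prod = alt_activity * conditions.sample_fraction / 60.0  # uM/s
    vmax = kinetics.resolved_vmax(conditions) / 60.0  # uM/s
    km = kinetics.pox_km_um
    stoich = kinetics.ferri_per_pyruvate
    gate = kinetics.ferri_gate_um

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        p = max(y[0], 0.0)
        f = max(y[1], 0.0)
        v_pox = vmax * p / (km + p) * (f / (f + gate))
        return [v_prod - v_pox, -stoich * v_pox, stoich * v_pox]

    t_eval = np.arange(0.0, duration + 0.5 * step, step)
    t_eval = t_eval[t_eval <= duration + 1e-9]
    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval[-1])),
        [0.0, f0, 0.0],
        method="LSODA",
        t_eval=t_eval,
        rtol=_ODE_RTOL,
        atol=_ODE_ATOL,
    )
    if not sol.success:
        raise SimulationError(f"ODE integration failed: {sol.message}")
    y = sol.y
    if np.any(~np.isfinite(y)):
        raise SimulationError("ODE integration produced non-finite concentrations")
    if y.min() < -1e-6:
        raise SimulationError(
            f"ODE integration produced negative concentration {y.min():.3e} uM"
        )
    y = np.clip(y, 0.0, None)
    return ReactionStates(
        t=sol.t,
        pyruvate=y[0],
        ferricyanide=y[1],
        ferrocyanide=y[2],
        ferricyanide0=f0,
    )


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def render_optical_trace(
    states: ReactionStates,
    render: OpticalRender | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | int | None = 0,
    channel_id: str = "well",
    meta: dict | None = None,
) -> KineticTrace:
    """Render reaction states as a 420 nm plate-reader absorbance trace.

    A(t) = a_background + epsilon*l*[ferricyanide](t) - drift*t + read noise,
    sampled every ``sample_interval_s``.
    """
    if len(states) == 0:
        raise ValidationError("states must be nonempty")
    render = render or OpticalRender()
    noise = noise or NoiseModel()
    rng = _as_rng(rng)

    t = np.arange(0.0, states.t[-1] + 1e-9, render.sample_interval_s)
    absorbance = (
        render.a_background_au
        + render.gain_au_per_um * states.ferricyanide_at(t)
        - noise.blank_drift_au_per_s * t
    )
    if noise.optical_read_sd_au > 0:
        absorbance = absorbance + rng.normal(0.0, noise.optical_read_sd_au, t.size)
    return KineticTrace(
        channel_id=channel_id,
        modality="optical",
        times=t,
        values=absorbance,
        meta=meta or {},
    )


@dataclass(frozen=True)
class SensorDieParams:
    """Per-sensor characteristics of one physical die.

    A die's sensors keep their baseline current, transduction gain and
    settling amplitude across assays, so a dilution series measured on one
    die draws these once and reuses them for every run.
    """

    baselines_na: np.ndarray
    gains_na: np.ndarray
    settle_amplitudes_na: np.ndarray

    @property
    def n_sensors(self) -> int:
        return int(self.baselines_na.size)


def draw_sensor_die(
    n_sensors: int,
    noise: NoiseModel,
    render: SensorRender,
    rng: np.random.Generator,
) -> SensorDieParams:
    """Draw one die's per-sensor baselines, gains and settling amplitudes."""
    if n_sensors < 1:
        raise ValidationError("n_sensors must be >= 1")

    def _spread(sd: float) -> np.ndarray:
        return rng.normal(0.0, sd, n_sensors) if sd > 0 else np.zeros(n_sensors)

    return SensorDieParams(
        baselines_na=noise.baseline_current_mean_na + _spread(noise.baseline_current_sd_na),
        gains_na=render.gain_na * (1.0 + _spread(noise.gain_cv)),
        settle_amplitudes_na=render.settle_amplitude_na * (1.0 + _spread(noise.settle_cv)),
    )


def render_sensor_run(
    states: ReactionStates,
    n_sensors: int | None = None,
    noise: NoiseModel | None = None,
    render: SensorRender | None = None,
    rng: np.random.Generator | int | None = 0,
    run_id: str = "run",
    meta: dict | None = None,
    die: SensorDieParams | None = None,
) -> SensorArrayRun:
    """Render reaction states as a multiplexed nanowire sensor-array run.

    Sensor i's raw current is::

        I_i(t) = baseline_i + settle_i * exp(-t / tau)
                 - gain_i * ferro_fraction(t) - drift * t + read noise

    Per-sensor baselines, gains and settling amplitudes come from ``die``
    (drawn once per run if not given; a dilution series shares one die);
    cycle periods are Normal(cycle_period_mean, cycle_period_sd) and the
    cycle index is shared across sensors.  Each sensor contributes
    ``raw_samples_per_cycle`` raw samples per cycle within its multiplexer
    slot; these are later boxcar averaged by the signal pipeline.
    """
    if len(states) == 0:
        raise ValidationError("states must be nonempty")
    render = render or SensorRender()
    noise = noise or NoiseModel()
    n = render.n_sensors if n_sensors is None else int(n_sensors)
    if n < 1:
        raise ValidationError("n_sensors must be >= 1")
    rng = _as_rng(rng)

    duration = float(states.t[-1])
    n_cycles = int(duration // noise.cycle_period_mean_s)
    if n_cycles < 1:
        raise ValidationError("record shorter than one measurement cycle")
    periods = noise.cycle_period_mean_s + (
        rng.normal(0.0, noise.cycle_period_sd_s, n_cycles)
        if noise.cycle_period_sd_s > 0
        else np.zeros(n_cycles)
    )
    starts = np.concatenate(([0.0], np.cumsum(periods[:-1])))
    cycle_times = starts + 0.5 * periods

    if die is None:
        die = draw_sensor_die(n, noise, render, rng)
    elif die.n_sensors != n:
        raise ValidationError(
            f"die has {die.n_sensors} sensors but n_sensors={n} requested"
        )
    baselines = die.baselines_na
    gains = die.gains_na
    settles = die.settle_amplitudes_na

    m = render.raw_samples_per_cycle
    raw_offsets = (np.arange(m) - (m - 1) / 2.0) * render.raw_sample_spacing_s
    cycle_idx = np.repeat(np.arange(n_cycles), m)

    sensors = []
    for i in range(n):
        slot = (i + 0.5) / n * noise.cycle_period_mean_s
        t = (starts[:, None] + slot + raw_offsets[None, :]).ravel()
        current = (
            baselines[i]
            + settles[i] * np.exp(-t / render.settle_tau_s)
            - gains[i] * states.ferro_fraction(t)
            - noise.electrical_drift_na_per_s * t
        )
        if noise.electrical_read_sd_na > 0:
            current = current + rng.normal(0.0, noise.electrical_read_sd_na, t.size)
        sensors.append(
            KineticTrace(
                channel_id=f"s{i}",
                modality="electrical",
                times=t,
                values=current,
                cycles=cycle_idx.copy(),
            )
        )
    return SensorArrayRun(
        run_id=run_id,
        sensors=sensors,
        cycle_times=cycle_times,
        cycle_period_mean_s=float(np.mean(periods)),
        cycle_period_sd_s=float(np.std(periods, ddof=1)) if n_cycles > 1 else 0.0,
        meta=meta or {},
    )


def generate_dilution_series(
    activities: list[float] | None = None,
    replicates: int | None = None,
    modality: str = "optical",
    config: SimulationConfig | None = None,
) -> DilutionSeriesData:
    """Generate one labelled synthetic dataset per (activity, replicate).

    The default grid is 0-450 U/L in 50 U/L steps with 3 replicates, the
    conditions used throughout for calibration.  Deterministic under the
    config seed: every entry draws from its own child of one root
    ``SeedSequence``, so regeneration is bit-for-bit reproducible and entries
    are statistically independent.  An electrical series is measured on one
    die: per-sensor baselines, gains and settling amplitudes are drawn once
    and shared by every run of the series.
    """
    config = config or SimulationConfig()
    activities = list(config.activities) if activities is None else list(activities)
    replicates = config.replicates if replicates is None else int(replicates)
    if not activities:
        raise ValidationError("activities must be nonempty")
    if any(a < 0 for a in activities):
        raise ValidationError("activities must be >= 0")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if modality not in ("optical", "electrical"):
        raise ValidationError(f"unknown modality {modality!r}")

    root = np.random.SeedSequence((config.seed, 0 if modality == "optical" else 1))
    children = root.spawn(len(activities) * replicates + 1)
    die = None
    if modality == "electrical":
        die = draw_sensor_die(
            config.sensor.n_sensors,
            config.noise,
            config.sensor,
            np.random.default_rng(children[-1]),
        )

    entries: list[DilutionEntry] = []
    k = 0
    for a in activities:
        states = simulate_reaction(
            a,
            conditions=config.conditions,
            kinetics=config.kinetics,
            duration=config.duration_s,
            step=config.ode_step_s,
        )
        for r in range(replicates):
            rng = np.random.default_rng(children[k])
            k += 1
            label = {"alt_u_per_l": float(a), "replicate": int(r)}
            if modality == "optical":
                data: KineticTrace | SensorArrayRun = render_optical_trace(
                    states,
                    render=config.optical,
                    noise=config.noise,
                    rng=rng,
                    channel_id=f"a{a:g}_r{r}",
                    meta=dict(label),
                )
            else:
                data = render_sensor_run(
                    states,
                    noise=config.noise,
                    render=config.sensor,
                    rng=rng,
                    run_id=f"a{a:g}_r{r}",
                    meta=dict(label),
                    die=die,
                )
            entries.append(DilutionEntry(alt_activity=float(a), replicate=r, data=data))
    return DilutionSeriesData(modality=modality, entries=entries)


def compute_debye_length(
    ionic_strength: float = 0.15,
    temperature: float = 310.0,
    relative_permittivity: float = 74.0,
) -> float:
    """Debye screening length (nm) of an electrolyte.

    lambda_D = sqrt(eps_r eps_0 k_B T / (2 N_A e^2 I)) with the ionic
    strength ``I`` in mol/L (converted to mol/m^3 internally).  Defaults are
    physiological saline at 37 C, for which the length is ~0.7-0.8 nm -- the
    electrostatic sensing range of the nanowire surface.
    """
    if ionic_strength <= 0 or temperature <= 0 or relative_permittivity <= 0:
        raise ValidationError("all Debye-length inputs must be > 0")
    i_si = ionic_strength * 1000.0  # mol/m^3
    lam = np.sqrt(
        relative_permittivity
        * sc.epsilon_0
        * sc.Boltzmann
        * temperature
        / (2.0 * sc.Avogadro * sc.elementary_charge**2 * i_si)
    )
    return float(lam * 1e9)
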