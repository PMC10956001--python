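"""Configuration models for the coupled ALT assay simulator.

The assay couples three reactions: ALT converts L-alanine and
alpha-ketoglutarate to pyruvate (+ glutamate); pyruvate oxidase (POX)
decarboxylates pyruvate, reducing FAD to FADH2; FADH2 is reoxidised by
ferricyanide (two Fe(CN)6^3- per FADH2), giving ferrocyanide.  Ferricyanide
loss is the assay observable, read either as absorbance at 420 nm or as a
baseline-current decrease on an array of nanowire field-effect sensors.

All reagent concentrations refer to the assay *mixture* before the sample is
added; in-well values are derived with ``sample_fraction`` (default 4 ul of
sample into 196 ul of mixture, i.e. 4/200).  A :class:`SimulationConfig`
(including its seed) fully determines a synthetic experiment.  Unknown keys
in a config file are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field
from pydantic import ValidationError as _PydanticValidationError

from .errors import ValidationError

__all__ = [
    "ReagentConditions",
    "KineticParams",
    "NoiseModel",
    "OpticalRender",
    "SensorRender",
    "SimulationConfig",
    "load_config",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ReagentConditions(_StrictModel):
    """Composition of the assay mixture and the sample dilution it receives.

    Concentrations are in mM of the mixture; POX is in U/mL of the mixture
    (1 U converts 1 umol substrate per minute).  ``sample_fraction`` is the
    sample volume over the total well volume.
    """

    alanine_mm: float = Field(default=500.0, ge=0)
    akg_mm: float = Field(default=15.0, ge=0, description="alpha-ketoglutarate")
    ferricyanide_mm: float = Field(default=3.5, ge=0)
    phosphate_mm: float = Field(default=25.0, ge=0)
    tpp_mm: float = Field(default=0.23, ge=0, description="thiamine pyrophosphate")
    mgcl2_mm: float = Field(default=20.0, ge=0)
    pox_u_per_ml: float = Field(default=10.0, ge=0)
    sample_fraction: float = Field(default=4.0 / 200.0, gt=0, le=1)

    @property
    def mixture_dilution(self) -> float:
        """Fraction of the well volume occupied by assay mixture."""
        return 1.0 - self.sample_fraction

    @property
    def ferricyanide0_um(self) -> float:
        """Initial in-well ferricyanide concentration (uM)."""
        return self.ferricyanide_mm * 1000.0 * self.mixture_dilution

    @property
    def pox_vmax_um_per_min(self) -> float:
        """POX Vmax in the well (uM/min); 1 U/mL == 1000 uM/min before dilution."""
        return self.pox_u_per_ml * 1000.0 * self.mixture_dilution


class KineticParams(_StrictModel):
    """Kinetic constants of the coupled reaction model.

    ALT substrates (500 mM alanine, 15 mM AKG) are far above typical Km, so
    pyruvate production is zero-order at the diluted sample activity.  POX is
    Michaelis-Menten in pyruvate; the default Km of 300 uM is a
    literature-typical placeholder, configurable.  ``ferri_gate_um`` softens
    the halt of the reaction as ferricyanide exhausts (keeps the ODE smooth).
    """

    pox_km_um: float = Field(default=300.0, gt=0)
    pox_vmax_um_per_min: float | None = Field(
        default=None, gt=0,
        description="Defaults to the value implied by the reagent conditions.",
    )
    ferri_per_pyruvate: float = Field(default=2.0, gt=0)
    ferri_gate_um: float = Field(default=0.1, gt=0)

    def resolved_vmax(self, conditions: ReagentConditions) -> float:
        if self.pox_vmax_um_per_min is not None:
            return self.pox_vmax_um_per_min
        return conditions.pox_vmax_um_per_min


class NoiseModel(_StrictModel):
    """Stochastic components of both read-out modalities.

    Cycle timing (31.7 +/- 0.12 s) and the optical blank rate (1.1e-4 AU/s)
    reproduce the multiplexer and plate-reader behaviour of the assay; the
    remaining magnitudes are documented instrument-realistic defaults.
    ``electrical_read_sd_na`` applies to each *raw* sample, before the
    per-cycle boxcar average.
    """

    optical_read_sd_au: float = Field(default=5e-4, ge=0)
    blank_drift_au_per_s: float = Field(default=1.1e-4, ge=0)
    electrical_read_sd_na: float = Field(default=0.06, ge=0)
    electrical_drift_na_per_s: float = Field(default=1e-3, ge=0)
    baseline_current_mean_na: float = Field(default=800.0)
    baseline_current_sd_na: float = Field(default=50.0, ge=0)
    gain_cv: float = Field(default=0.10, ge=0)
    settle_cv: float = Field(default=0.20, ge=0)
    cycle_period_mean_s: float = Field(default=31.7, gt=0)
    cycle_period_sd_s: float = Field(default=0.12, ge=0)

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        """All stochastic magnitudes and drifts zeroed (timing jitter included)."""
        return cls(
            optical_read_sd_au=0.0,
            blank_drift_au_per_s=0.0,
            electrical_read_sd_na=0.0,
            electrical_drift_na_per_s=0.0,
            baseline_current_sd_na=0.0,
            gain_cv=0.0,
            settle_cv=0.0,
            cycle_period_sd_s=0.0,
        )


class OpticalRender(_StrictModel):
    """Beer-Lambert rendering of ferricyanide into 420 nm absorbance.

    Absorbance is sampled every ``sample_interval_s`` (default 30 s).  The
    molar absorptivity and path length are documented defaults for a 200 ul
    well, both configurable; the absolute optical gain of the instrument is
    not pinned down by the assay itself.
    """

    epsilon_ferri_au_per_m_cm: float = Field(default=1040.0, gt=0)
    pathlength_cm: float = Field(default=0.57, gt=0)
    a_background_au: float = Field(default=0.05, ge=0)
    sample_interval_s: float = Field(default=30.0, gt=0)

    @property
    def gain_au_per_um(self) -> float:
        """Absorbance per uM of ferricyanide."""
        return self.epsilon_ferri_au_per_m_cm * self.pathlength_cm * 1e-6


class SensorRender(_StrictModel):
    """Transduction of the reaction into per-sensor nanowire current.

    Each sensor's current is its baseline, minus a linear response to the
    converted ferrocyanide fraction (``gain_na`` per unit fraction), minus a
    decaying injection/settling transient (amplitude ``settle_amplitude_na``,
    time constant ``settle_tau_s``) that dominates the raw record's excursion
    -- the reason traces are baseline-offset at 144 s before analysis.  Each
    measurement cycle contributes ``raw_samples_per_cycle`` raw readings,
    taken within the sensor's multiplexer slot.
    """

    gain_na: float = Field(default=60.0, ge=0)
    settle_amplitude_na: float = Field(default=40.0, ge=0)
    settle_tau_s: float = Field(default=40.0, gt=0)
    raw_samples_per_cycle: int = Field(default=8, ge=1)
    raw_sample_spacing_s: float = Field(default=0.25, gt=0)
    n_sensors: int = Field(default=7, ge=1)


_DEFAULT_ACTIVITIES = tuple(float(a) for a in range(0, 451, 50))


class SimulationConfig(_StrictModel):
    """Everything needed to regenerate a synthetic experiment bit-for-bit."""

    conditions: ReagentConditions = Field(default_factory=ReagentConditions)
    kinetics: KineticParams = Field(default_factory=KineticParams)
    noise: NoiseModel = Field(default_factory=NoiseModel)
    optical: OpticalRender = Field(default_factory=OpticalRender)
    sensor: SensorRender = Field(default_factory=SensorRender)
    activities: list[float] = Field(default=list(_DEFAULT_ACTIVITIES))
    replicates: int = Field(default=3, ge=1)
    duration_s: float = Field(default=1200.0, gt=0)
    ode_step_s: float = Field(default=1.0, gt=0)
    seed: int = Field(default=0, ge=0)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")


def load_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a JSON or TOML file.

    Unknown keys anywhere in the document raise :class:`ValidationError`
    naming the key.
    """
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        payload = tomllib.loads(path.read_text())
    else:
        payload = json.loads(path.read_text())
    try:
        return SimulationConfig.model_validate(payload)
    except _PydanticValidationError as exc:
        raise ValidationError(f"invalid simulation config {path}: {exc}") from exc
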