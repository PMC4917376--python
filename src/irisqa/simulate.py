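"""Synthetic measurement sessions with the noise structure of monthly QA.

The generator emulates the clinical acquisition protocol: repeated 100 MU
exposures of the 12 clinical iris apertures and the fixed 60 mm reference
cone, read out with the large-area chamber.  Each exposure reading is built
from the deterministic DAP forward model and perturbed by the error sources
that measurably contribute in practice:

* output drift — per-exposure multiplicative noise on the linac output
  (SD 0.04% by default, the value recovered from 60 consecutive exposures
  over 30 minutes);
* MU-delivery uncertainty — per-exposure multiplicative noise on the
  delivered monitor units (SD 0.04% by default, size-independent);
* aperture-size jitter — per-exposure normal jitter of the *iris* aperture
  diameter (SD 0.02 mm by default; the iris reproducibility is specified
  below 0.05 mm, and fixed cones have no size jitter at all);
* systematic aperture offsets — configurable true field-size errors per
  iris aperture, the quantity QA is designed to detect;
* chamber misalignment — a lateral offset of the chamber from the beam
  axis, applied to every exposure of a session;
* beam detuning — the shoulder depression of the profile model.

All draws are independent normals; randomness is seeded through a
SeedSequence stream-splitting scheme (one child stream per session) so a
fixed seed reproduces every session bit-for-bit.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beam import (
    ApertureSpec,
    BeamProfileModel,
    ChamberSpec,
    CLINICAL_IRIS_DIAMETERS_MM,
    FIXED_REFERENCE_DIAMETER_MM,
    OutputFactorTable,
    detune,
    interpolate_of,
)
from .dap import dap_offset, dap_radial
from .errors import ValidationError
from .session import MeasurementSession

__all__ = ["SimulationConfig", "simulate_session", "simulate_longterm"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Noise magnitudes default to the values characterizing the emulated
    machine: output drift and MU-delivery SD 0.04% each, iris size jitter
    0.02 mm, no misalignment, no detuning, no systematic offsets.
    ``fixed_reference_reading_nc`` calibrates the model units so the fixed
    60 mm cone reads ≈143.4 nC per 100 MU, matching the scale of the
    printed DAP means.
    """

    seed: int = 0
    n_repeats: int = 5
    mu: float = 100.0
    output_drift_sd_pct: float = 0.04
    mu_delivery_sd_pct: float = 0.04
    aperture_jitter_sd_mm: float = 0.02
    misalignment_mm: float = 0.0
    detune_level: float = 0.0
    aperture_offsets_mm: dict[float, float] = field(default_factory=dict)
    calibration_drift_mm_per_session: float = 0.0
    fixed_reference_reading_nc: float = 143.4

    def __post_init__(self):
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")
        for name in ("output_drift_sd_pct", "mu_delivery_sd_pct",
                     "aperture_jitter_sd_mm"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.misalignment_mm < 0:
            raise ValidationError("misalignment_mm must be >= 0")
        if self.detune_level < 0:
            raise ValidationError("detune_level must be >= 0")
        if self.mu <= 0:
            raise ValidationError("mu must be positive")
        if self.fixed_reference_reading_nc <= 0:
            raise ValidationError("fixed_reference_reading_nc must be positive")

    def offset_for(self, diameter_mm: float) -> float:
        for d, off in self.aperture_offsets_mm.items():
            if abs(float(d) - diameter_mm) < 1e-9:
                return float(off)
        return 0.0


def _calibration_nc(model: BeamProfileModel, chamber: ChamberSpec,
                    config: SimulationConfig) -> float:
    """nC per model DAP unit, anchored on the aligned nominal fixed cone."""
    ref = dap_radial(model, ApertureSpec.fixed(), 1.0, chamber).value
    return config.fixed_reference_reading_nc / ref


def _exposure_reading(model, of_table, chamber, config, cal_nc, rng,
                      nominal_d: float, collimator: str,
                      systematic_offset_mm: float) -> float:
    """One exposure: draw the true aperture, integrate, apply output noise."""
    if collimator == "iris":
        jitter = (rng.normal(0.0, config.aperture_jitter_sd_mm)
                  if config.aperture_jitter_sd_mm > 0 else 0.0)
        true_d = nominal_d + systematic_offset_mm + jitter
        # OF query clamped into the table's supported range so that jitter
        # draws at the extreme apertures cannot step over the ±0.2 mm slack
        lo = of_table.diameters_mm[0] - 0.2
        hi = of_table.diameters_mm[-1] + 0.2
        of = interpolate_of(of_table, min(max(true_d, lo), hi))
    else:
        # fixed cones have no field-size jitter and carry the reference OF
        true_d = nominal_d
        of = 1.0
    dap = dap_offset(model, ApertureSpec(true_d, collimator), of, chamber,
                     config.misalignment_mm).value
    drift = (rng.normal(0.0, config.output_drift_sd_pct / 100.0)
             if config.output_drift_sd_pct > 0 else 0.0)
    mu_noise = (rng.normal(0.0, config.mu_delivery_sd_pct / 100.0)
                if config.mu_delivery_sd_pct > 0 else 0.0)
    return cal_nc * dap * (config.mu / 100.0) * (1.0 + drift) * (1.0 + mu_noise)


def simulate_session(model: BeamProfileModel, of_table: OutputFactorTable,
                     chamber: ChamberSpec, config: SimulationConfig,
                     session_id: str = "S001",
                     date: datetime.date = datetime.date(2014, 1, 15),
                     rng: np.random.Generator | None = None,
                     extra_offset_mm: float = 0.0) -> MeasurementSession:
    """Generate one measurement session.

    Exposure order is deterministic: iris apertures in ascending diameter,
    then the fixed 60 mm reference, ``n_repeats`` exposures each.  With all
    noise SDs zero and no offsets, readings equal the deterministic forward
    model exactly.  ``extra_offset_mm`` adds a session-level systematic
    offset to every iris aperture (used for calibration drift over a long
    series).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if config.detune_level > 0:
        model = detune(model, config.detune_level)
    cal_nc = _calibration_nc(model, chamber, config)
    rows = []
    plan = [("iris", d) for d in CLINICAL_IRIS_DIAMETERS_MM]
    plan.append(("fixed", FIXED_REFERENCE_DIAMETER_MM))
    for collimator, d in plan:
        offset = config.offset_for(d) + extra_offset_mm if collimator == "iris" else 0.0
        for k in range(config.n_repeats):
            reading = _exposure_reading(model, of_table, chamber, config,
                                        cal_nc, rng, d, collimator, offset)
            rows.append({"collimator": collimator, "aperture_mm": d,
                         "mu": config.mu, "repeat_index": k,
                         "reading_nC": reading})
    return MeasurementSession(session_id=session_id, date=date,
                              records=pd.DataFrame(rows))


def simulate_longterm(model: BeamProfileModel, of_table: OutputFactorTable,
                      chamber: ChamberSpec, config: SimulationConfig,
                      n_sessions: int,
                      start_date: datetime.date = datetime.date(2014, 1, 15),
                      spacing_days: int = 21) -> list[MeasurementSession]:
    """Generate an independent long-term series of sessions.

    Each session draws from its own child stream of the seed (SeedSequence
    spawn), so the series is reproducible and sessions are statistically
    independent.  ``calibration_drift_mm_per_session`` (from the config)
    adds a linearly growing systematic offset to all iris apertures,
    emulating a slow calibration drift; it is 0 by default.
    """
    if n_sessions < 1:
        raise ValidationError("n_sessions must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(n_sessions)
    sessions = []
    for i, child in enumerate(children):
        sessions.append(simulate_session(
            model, of_table, chamber, config,
            session_id=f"S{i + 1:03d}",
            date=start_date + datetime.timedelta(days=spacing_days * i),
            rng=np.random.default_rng(child),
            extra_offset_mm=config.calibration_drift_mm_per_session * i,
        ))
    return sessions
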