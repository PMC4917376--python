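"""Dose-area products by integration of the beam model over the chamber.

The large-area chamber reading is modelled as the output-factor-weighted
integral of the off-center ratio over the chamber's sensitive disk:

    DAP(d) = OF(d) * ∫∫_chamber OCR(r, d) dA

For an aligned chamber the integrand is radial and the integral reduces to
``OF * ∫_0^rmax OCR(r) 2πr dr``.  For a chamber whose center is offset by
``s`` from the beam axis, the integration is carried out in beam-centered
polar coordinates: circles of radius ``u`` around the beam axis intersect
the chamber disk along an arc whose angle is known in closed form, so the
2-D integral over the offset disk reduces exactly to

    DAP = OF * ∫_0^{s+rmax} OCR(u) * arc(u; s, rmax) * u du

with ``arc = 2π`` where the circle lies fully inside the chamber and
``arc = 2 arccos((u² + s² − rmax²)/(2 u s))`` in the partial-overlap band.
Both integrals use adaptive Gauss–Kronrod quadrature with breakpoints at
the profile's structural radii.

Ideal step profiles (zero penumbra width) are evaluated in closed form
(disk and lens areas), which makes the closed-form tolerance-limit checks
exact.

The module also derives *calculated* tolerance limits: the percentage
change of DAP when the nominal aperture is perturbed by ±0.2 mm (the
manufacturer's reproducibility specification), with the output factor
interpolated to the perturbed diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .beam import (
    ApertureSpec,
    BeamProfileModel,
    ChamberSpec,
    OutputFactorTable,
    interpolate_of,
)
from .errors import DomainError, IntegrationError

__all__ = [
    "DapValue",
    "ToleranceLimits",
    "dap_radial",
    "dap_offset",
    "theta",
    "calculated_limits",
    "calculated_limits_table",
]

#: Manufacturer's aperture reproducibility specification, mm at SAD 800 mm.
SPEC_PERTURBATION_MM = 0.2


@dataclass(frozen=True)
class DapValue:
    """A dose-area product in model units (proportional to nC).

    ``shift_mm`` records the chamber offset from the beam axis at which the
    value was computed (0 for an aligned chamber).
    """

    value: float
    aperture: ApertureSpec
    shift_mm: float = 0.0

    def __post_init__(self):
        if self.value < 0:
            raise DomainError("DAP must be >= 0")
        if self.shift_mm < 0:
            raise DomainError("chamber shift must be >= 0")

    def __float__(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class ToleranceLimits:
    """Per-aperture δ tolerance limits (percent), measured or calculated.

    ``limits`` maps nominal aperture diameter (mm) to ``(δ_plus, δ_minus)``
    with δ_plus > 0 > δ_minus.
    """

    limits: dict[float, tuple[float, float]]
    source: str  # "measured" | "calculated"

    def __post_init__(self):
        if self.source not in ("measured", "calculated"):
            raise DomainError("limits source must be 'measured' or 'calculated'")
        for d, (plus, minus) in self.limits.items():
            if not (plus > 0 > minus):
                raise DomainError(
                    f"limits at {d} mm must satisfy delta_plus > 0 > delta_minus, "
                    f"got ({plus}, {minus})"
                )

    def at(self, diameter_mm: float) -> tuple[float, float]:
        for d, pair in self.limits.items():
            if abs(d - diameter_mm) < 1e-9:
                return pair
        raise KeyError(f"no limits for aperture {diameter_mm} mm")


def _is_step(model: BeamProfileModel) -> bool:
    return model.penumbra_mm == 0.0 and model.flatness == 0.0 and model.detune_level == 0.0


def _profile_breakpoints(model: BeamProfileModel, R: float) -> list[float]:
    """Radii where the integrand changes character (field edge, detune
    window edges, penumbra extent)."""
    pts = {R, 0.4 * R, 0.5 * R, 0.9 * R}
    if model.penumbra_mm > 0:
        pts.update({max(R - 5 * model.penumbra_mm, 0.0), R + 5 * model.penumbra_mm})
    return sorted(pts)


def _quad(func, a, b, points, epsrel, what):
    inner = [p for p in points if a < p < b]
    val, err = integrate.quad(func, a, b, points=inner or None,
                              epsabs=0.0, epsrel=epsrel, limit=300)
    if val != 0.0 and not (err <= 10 * epsrel * abs(val) + 1e-12):
        raise IntegrationError(
            f"{what}: quadrature error estimate {err:.3e} exceeds tolerance "
            f"for value {val:.6e}"
        )
    return val


def dap_radial(model: BeamProfileModel, aperture: ApertureSpec, of: float,
               chamber: ChamberSpec) -> DapValue:
    """DAP of an aligned chamber: ``OF * ∫_0^rmax OCR(r) 2πr dr``.

    Deterministic adaptive quadrature (relative tolerance 1e-10). Ideal
    step profiles are evaluated in closed form.
    """
    if of < 0:
        raise DomainError("output factor must be >= 0")
    R = model.field_radius_mm(aperture, chamber)
    rmax = chamber.active_radius_mm
    if _is_step(model):
        area = np.pi * min(R, rmax) ** 2
        return DapValue(of * area, aperture, 0.0)
    val = _quad(lambda r: model.ocr(r, R) * 2.0 * np.pi * r,
                0.0, rmax, _profile_breakpoints(model, R), 1e-10,
                f"dap_radial(d={aperture.diameter_mm})")
    return DapValue(of * val, aperture, 0.0)


def _lens_area(r_field: float, r_chamber: float, separation: float) -> float:
    """Area of intersection of two disks with center separation ``separation``."""
    a, b, s = r_field, r_chamber, separation
    if s >= a + b:
        return 0.0
    if s <= abs(a - b):
        return np.pi * min(a, b) ** 2
    alpha = np.arccos((s * s + a * a - b * b) / (2 * s * a))
    beta = np.arccos((s * s + b * b - a * a) / (2 * s * b))
    return (a * a * (alpha - np.sin(2 * alpha) / 2)
            + b * b * (beta - np.sin(2 * beta) / 2))


def _arc_angle(u: float, s: float, rmax: float) -> float:
    """Angle of the circle of radius u (about the beam axis) lying inside
    the chamber disk (radius rmax, center offset s)."""
    if u <= rmax - s:
        return 2.0 * np.pi
    if u >= rmax + s:
        return 0.0
    c = (u * u + s * s - rmax * rmax) / (2.0 * u * s)
    return 2.0 * np.arccos(np.clip(c, -1.0, 1.0))


def dap_offset(model: BeamProfileModel, aperture: ApertureSpec, of: float,
               chamber: ChamberSpec, shift_mm: float) -> DapValue:
    """DAP of a chamber whose center is offset ``shift_mm`` from the beam axis.

    The 2-D integral of the radial OCR over the offset chamber disk reduces
    exactly to a 1-D radial integral weighted by the in-chamber arc angle
    (see module docstring); at ``shift_mm = 0`` it coincides with
    :func:`dap_radial` by construction.
    """
    if shift_mm < 0:
        raise DomainError("chamber shift must be >= 0")
    if of < 0:
        raise DomainError("output factor must be >= 0")
    if shift_mm == 0.0:
        v = dap_radial(model, aperture, of, chamber)
        return DapValue(v.value, aperture, 0.0)
    R = model.field_radius_mm(aperture, chamber)
    rmax = chamber.active_radius_mm
    s = float(shift_mm)
    if _is_step(model):
        return DapValue(of * _lens_area(R, rmax, s), aperture, s)
    pts = _profile_breakpoints(model, R) + [abs(rmax - s), rmax, rmax + s]
    val = _quad(lambda u: model.ocr(u, R) * _arc_angle(u, s, rmax) * u,
                0.0, rmax + s, sorted(set(pts)), 1e-9,
                f"dap_offset(d={aperture.diameter_mm}, shift={s})")
    return DapValue(of * val, aperture, s)


def theta(dap_iris: DapValue | float, dap_fixed: DapValue | float) -> float:
    """QA quotient θ(d) = DAP_Iris(d) / DAP_Fixed(60 mm).

    Means are taken before the quotient when working from repeat readings.
    """
    num = float(dap_iris)
    den = float(dap_fixed)
    if den <= 0:
        raise DomainError("reference DAP must be positive")
    return num / den


def calculated_limits(model: BeamProfileModel, of_table: OutputFactorTable,
                      aperture: ApertureSpec, chamber: ChamberSpec,
                      perturbation_mm: float = SPEC_PERTURBATION_MM,
                      ) -> tuple[float, float]:
    """Calculated tolerance limits δ_calculation,±0.2(d) for one aperture.

    The baseline DAP uses the nominal diameter and tabulated OF; the
    perturbed DAPs rescale the field radius to the projected radius of
    ``d ± perturbation`` (penumbra width unchanged) and interpolate the
    output factor OF′ at the perturbed nominal diameter.  Returns
    ``(δ_plus, δ_minus)`` in percent.  The fixed-reference denominator of θ
    is unperturbed and cancels, so the limits are computed from the iris
    DAP ratio directly.
    """
    d0 = aperture.diameter_mm
    base = dap_radial(model, aperture, interpolate_of(of_table, d0), chamber).value
    if base <= 0:
        raise DomainError("baseline DAP must be positive")
    out = []
    for sign in (+1.0, -1.0):
        d_pert = d0 + sign * perturbation_mm
        pert = dap_radial(model, ApertureSpec(d_pert, aperture.kind),
                          interpolate_of(of_table, d_pert), chamber).value
        out.append((pert / base - 1.0) * 100.0)
    return out[0], out[1]


def calculated_limits_table(model: BeamProfileModel, of_table: OutputFactorTable,
                            chamber: ChamberSpec,
                            diameters_mm=None,
                            perturbation_mm: float = SPEC_PERTURBATION_MM,
                            ) -> ToleranceLimits:
    """Calculated limits for a set of apertures (default: the clinical set)."""
    from .beam import CLINICAL_IRIS_DIAMETERS_MM

    diameters = diameters_mm if diameters_mm is not None else CLINICAL_IRIS_DIAMETERS_MM
    limits = {}
    for d in diameters:
        plus, minus = calculated_limits(model, of_table, ApertureSpec.iris(d),
                                        chamber, perturbation_mm)
        limits[float(d)] = (plus, minus)
    return ToleranceLimits(limits=limits, source="calculated")
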