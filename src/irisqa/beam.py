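"""Parametric model of the photon beam at the chamber measurement plane.

The Iris variable aperture collimator produces a 12-sided, approximately
circular field whose diameter ``d`` is specified at the nominal source-axis
distance (SAD) of 800 mm.  For dose-area-product (DAP) quality assurance a
large-area parallel-plate ionization chamber sits closer to the source
(SAD 791 mm), so nominal diameters are projected onto the chamber plane.

The beam is modelled as radially symmetric: a flat (optionally gently
peaked) core with a sigmoid penumbra described by the complementary error
function.  Off-center ratios OCR(r, d) are normalized to 1 on the central
axis.  The model supports deliberate "detuning" — a multiplicative
depression of the profile shoulder emulating a linac whose gun voltage /
grid bias have drifted to a clinically unacceptable state.

The model is parametric by necessity: it stands in for water-tank
commissioning profiles, which are clinic-specific.  Every quantity that
depends on the actual profile shape (misalignment sensitivities, absolute
DAP values) is therefore configurable, and defaults are chosen to be
plausible for a 6 MV flattening-filter-free beam.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc, erfinv

from .errors import DomainError, RangeError

__all__ = [
    "NOMINAL_SAD_MM",
    "CLINICAL_IRIS_DIAMETERS_MM",
    "FIXED_REFERENCE_DIAMETER_MM",
    "ApertureSpec",
    "ChamberSpec",
    "BeamProfileModel",
    "OutputFactorTable",
    "project_diameter",
    "ocr",
    "interpolate_of",
    "detune",
    "default_output_factor_table",
]

#: SAD (mm) at which nominal aperture diameters are specified.
NOMINAL_SAD_MM = 800.0

#: The 12 iris diameters (mm at SAD 800 mm) available for clinical use.
CLINICAL_IRIS_DIAMETERS_MM = (
    5.0, 7.5, 10.0, 12.5, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 50.0, 60.0,
)

#: Diameter (mm) of the fixed cone used as the reference denominator of θ.
FIXED_REFERENCE_DIAMETER_MM = 60.0

# erfc argument scale such that ``penumbra_mm`` equals the 80%-20% fall-off
# width of the profile: 0.5*erfc(z) = 0.8 and 0.2 at z = ∓erfinv(0.6).
_PENUMBRA_K = float(2.0 * erfinv(0.6))

# Diameter slack (mm) tolerated beyond the output-factor table endpoints.
OF_EXTRAPOLATION_SLACK_MM = 0.2


@dataclass(frozen=True)
class ApertureSpec:
    """A collimator aperture.

    Parameters
    ----------
    diameter_mm
        Nominal field diameter in mm at SAD 800 mm. Must be positive.
    kind
        ``"iris"`` (variable aperture) or ``"fixed"`` (fixed cone).
    """

    diameter_mm: float
    kind: str = "iris"

    def __post_init__(self):
        if self.kind not in ("iris", "fixed"):
            raise DomainError(f"aperture kind must be 'iris' or 'fixed', got {self.kind!r}")
        if not (self.diameter_mm > 0):
            raise DomainError(f"aperture diameter must be positive, got {self.diameter_mm}")

    @property
    def is_clinical(self) -> bool:
        """Whether the diameter is one of the 12 clinical iris settings."""
        return any(abs(self.diameter_mm - d) < 1e-9 for d in CLINICAL_IRIS_DIAMETERS_MM)

    @classmethod
    def iris(cls, diameter_mm: float) -> "ApertureSpec":
        return cls(float(diameter_mm), "iris")

    @classmethod
    def fixed(cls, diameter_mm: float = FIXED_REFERENCE_DIAMETER_MM) -> "ApertureSpec":
        return cls(float(diameter_mm), "fixed")


@dataclass(frozen=True)
class ChamberSpec:
    """Geometry of the large-area parallel-plate chamber.

    Defaults describe a Bragg-peak type chamber with an 81.6 mm active-area
    diameter, mounted at SAD 791 mm.  The entrance window thickness is
    metadata only; it does not enter any calculation.
    """

    active_radius_mm: float = 40.8
    plane_sad_mm: float = 791.0
    entrance_window_mm: float = 3.47

    def __post_init__(self):
        if not (self.active_radius_mm > 0):
            raise DomainError("chamber active radius must be positive")
        if not (self.plane_sad_mm > 0):
            raise DomainError("chamber plane SAD must be positive")


def project_diameter(aperture: ApertureSpec, chamber: ChamberSpec) -> float:
    """Project a nominal aperture diameter onto the chamber plane.

    Field sizes are specified at SAD 800 mm while the chamber sits at
    ``chamber.plane_sad_mm``; by beam divergence the diameter scales
    linearly with distance from the source:

        d_plane = d_nominal * plane_sad / 800

    Returns the projected diameter in mm.
    """
    if not (aperture.diameter_mm > 0):
        raise DomainError("diameter must be positive")
    if not (chamber.plane_sad_mm > 0):
        raise DomainError("plane SAD must be positive")
    return aperture.diameter_mm * chamber.plane_sad_mm / NOMINAL_SAD_MM


@dataclass(frozen=True)
class BeamProfileModel:
    """Radially symmetric off-center-ratio model OCR(r, d).

    The profile is a flat core with a sigmoid penumbra::

        OCR(r) = core(r) * 1/2 erfc((r - R) * k / p) * detuning(r)

    where ``R`` is the projected field radius, ``p = penumbra_mm`` is the
    80–20 penumbra width (``k`` fixed so that p has exactly that meaning),
    and ``core(r) = 1 + flatness * (min(r, R)/R)^2`` allows mildly "horned"
    FFF-like profiles.  ``penumbra_mm = 0`` degenerates to an ideal step
    profile (used for closed-form checks).

    ``detune_level`` depresses the shoulder region (0.5R–0.9R) by
    ``4 * detune_level`` percent with smooth cosine tapers, emulating the
    worst-case mistuned beam; the central axis stays normalized to 1.
    """

    penumbra_mm: float = 3.0
    flatness: float = 0.0
    detune_level: float = 0.0

    def __post_init__(self):
        if self.penumbra_mm < 0:
            raise DomainError("penumbra width must be >= 0")
        if self.flatness < 0:
            raise DomainError("flatness must be >= 0")
        if self.detune_level < 0:
            raise DomainError("detune level must be >= 0")

    def field_radius_mm(self, aperture: ApertureSpec, chamber: ChamberSpec) -> float:
        """Projected field radius R(d) at the chamber plane, in mm."""
        return 0.5 * project_diameter(aperture, chamber)

    def _detune_weight(self, r: np.ndarray, field_radius_mm: float) -> np.ndarray:
        """Shoulder window: 1 on [0.5R, 0.9R], cosine tapers to 0 at 0.4R and R."""
        R = field_radius_mm
        x = r / R
        w = np.zeros_like(x)
        w[(x >= 0.5) & (x <= 0.9)] = 1.0
        lo = (x > 0.4) & (x < 0.5)
        w[lo] = 0.5 * (1.0 - np.cos(np.pi * (x[lo] - 0.4) / 0.1))
        hi = (x > 0.9) & (x < 1.0)
        w[hi] = 0.5 * (1.0 + np.cos(np.pi * (x[hi] - 0.9) / 0.1))
        return w

    def ocr(self, r, field_radius_mm: float):
        """Off-center ratio at radial distance ``r`` (mm) from the beam axis.

        Vectorized over ``r``. Raises :class:`DomainError` for negative r.
        """
        r_arr = np.asarray(r, dtype=float)
        if np.any(r_arr < 0):
            raise DomainError("radial distance must be >= 0")
        R = field_radius_mm
        if self.penumbra_mm == 0.0:
            base = np.where(r_arr < R, 1.0, np.where(r_arr == R, 0.5, 0.0))
        else:
            base = 0.5 * erfc((r_arr - R) * _PENUMBRA_K / self.penumbra_mm)
            # central-axis normalization: for small fields the penumbra
            # reaches the axis, so divide by the on-axis profile value
            base = base / (0.5 * erfc(-R * _PENUMBRA_K / self.penumbra_mm))
        if self.flatness != 0.0:
            base = base * (1.0 + self.flatness * (np.minimum(r_arr, R) / R) ** 2)
        if self.detune_level != 0.0:
            base = base * (1.0 - 0.04 * self.detune_level * self._detune_weight(r_arr, R))
        if np.ndim(r) == 0:
            return float(base)
        return base


def ocr(model: BeamProfileModel, aperture: ApertureSpec, r,
        chamber: ChamberSpec | None = None):
    """OCR(r, d) for ``aperture`` with the nominal diameter projected to the
    chamber plane (default chamber geometry if none is given)."""
    chamber = chamber if chamber is not None else ChamberSpec()
    return model.ocr(r, model.field_radius_mm(aperture, chamber))


def detune(model: BeamProfileModel, level: float) -> BeamProfileModel:
    """Return a copy of ``model`` with the shoulder depressed by 4·level %.

    ``level = 0`` returns an identical model; ``level = 1`` reproduces the
    worst-case mistuned beam (≈4% shoulder dose decrease). The central axis
    remains normalized to OCR(0) = 1.
    """
    if level < 0:
        raise DomainError("detune level must be >= 0")
    return dataclasses.replace(model, detune_level=float(level))


@dataclass(frozen=True)
class OutputFactorTable:
    """Tabulated output factors OF(d) with interpolation to perturbed sizes.

    The output factor is the central-axis dose per MU of an aperture
    relative to the reference; here the table is normalized so that the
    fixed 60 mm reference cone has OF = 1.  Diameters must be strictly
    increasing and factors positive and non-decreasing (small-field output
    saturates toward the largest aperture).

    ``extrapolation`` controls behaviour within a ±0.2 mm slack beyond the
    endpoints: ``"clamp"`` (default) holds the endpoint value flat;
    ``"linear"`` continues the endmost segment's slope, which better
    represents the steep small-field output gradient below the smallest
    tabulated aperture.
    """

    diameters_mm: tuple[float, ...]
    factors: tuple[float, ...]
    extrapolation: str = "clamp"

    def __post_init__(self):
        d = np.asarray(self.diameters_mm, dtype=float)
        f = np.asarray(self.factors, dtype=float)
        if d.size != f.size or d.size < 2:
            raise DomainError("output-factor table needs >= 2 (diameter, OF) pairs")
        if np.any(np.diff(d) <= 0):
            raise DomainError("table diameters must be strictly increasing")
        if np.any(f <= 0):
            raise DomainError("output factors must be positive")
        if np.any(np.diff(f) < 0):
            raise DomainError("output factors must be non-decreasing with diameter")
        if self.extrapolation not in ("clamp", "linear"):
            raise DomainError("extrapolation must be 'clamp' or 'linear'")
        object.__setattr__(self, "diameters_mm", tuple(float(x) for x in d))
        object.__setattr__(self, "factors", tuple(float(x) for x in f))

    def __call__(self, d: float) -> float:
        return interpolate_of(self, d)


def interpolate_of(table: OutputFactorTable, d: float) -> float:
    """Output factor OF′(d) by piecewise-linear interpolation.

    Within the tabulated range this interpolates linearly between adjacent
    knots; up to 0.2 mm beyond either endpoint the table extrapolates
    (flat by default, see :class:`OutputFactorTable`); farther outside
    raises :class:`RangeError`.
    """
    dd = np.asarray(table.diameters_mm)
    ff = np.asarray(table.factors)
    lo, hi = dd[0], dd[-1]
    if d < lo - OF_EXTRAPOLATION_SLACK_MM or d > hi + OF_EXTRAPOLATION_SLACK_MM:
        raise RangeError(
            f"diameter {d} mm outside output-factor table range "
            f"[{lo}, {hi}] mm (+/- {OF_EXTRAPOLATION_SLACK_MM} mm slack)"
        )
    if table.extrapolation == "linear":
        if d < lo:
            slope = (ff[1] - ff[0]) / (dd[1] - dd[0])
            return float(ff[0] + slope * (d - lo))
        if d > hi:
            slope = (ff[-1] - ff[-2]) / (dd[-1] - dd[-2])
            return float(ff[-1] + slope * (d - hi))
    return float(np.interp(d, dd, ff))


def default_output_factor_table(extrapolation: str = "clamp") -> OutputFactorTable:
    """Synthetic default output-factor table at the 12 clinical diameters.

    The real OF curve is clinic-specific commissioning data and is not
    published; this stand-in has the characteristic shape — steep rise in
    the small-field region, saturating plateau toward 60 mm — and is
    normalized to the fixed 60 mm reference cone (OF = 1), so the iris
    60 mm aperture carries OF = 0.951 and the ideal-model DAP quotient
    θ(60 mm) ≈ 0.951.  Any report built on it must be read as synthetic.
    """
    return OutputFactorTable(
        diameters_mm=CLINICAL_IRIS_DIAMETERS_MM,
        factors=(0.680, 0.750, 0.800, 0.840, 0.870, 0.905,
                 0.925, 0.935, 0.942, 0.946, 0.949, 0.951),
        extrapolation=extrapolation,
    )
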