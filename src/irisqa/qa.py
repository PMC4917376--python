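"""QA statistics for DAP-based field-size monitoring.

Everything here operates on the QA quotient

    θ(d) = DAP_Iris(d) / DAP_Fixed(60 mm)

and its percentage deviation from the commissioning baseline,

    δ(d) = (θ(d) / θ_baseline(d) − 1) · 100 .

Because DAP scales with the field area, a percentage deviation converts to
an equivalent geometric field-size deviation through pure area scaling:

    δ  →  Δd = d (√(1 + δ/100) − 1)        (mm)
    Δd →  δ  = ((d + Δd)² / d² − 1) · 100   (%)

The conversion deliberately ignores the output-factor variation with
diameter — it is the diagnostic ruler used to express deviations in mm, not
a forward model — and the two directions are exact inverses of each other.

The module also provides: measured tolerance limits from ±0.2 mm perturbed
acquisitions, characterization fits (power law DAP ∝ d^c, through-origin
θ-vs-area slope), an error budget combined in quadrature, reproducibility
and stability summaries across sessions, and the per-session QA evaluation
against baseline and limits.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .beam import CLINICAL_IRIS_DIAMETERS_MM, FIXED_REFERENCE_DIAMETER_MM
from .dap import ToleranceLimits
from .errors import DomainError, ValidationError
from .session import MeasurementSession

__all__ = [
    "BaselineRecord",
    "QAResult",
    "ErrorBudget",
    "SeriesSummary",
    "PowerLawFit",
    "delta",
    "misalign_error",
    "beamchange_error",
    "delta_to_mm",
    "mm_to_delta",
    "measured_limits",
    "fit_dap_power_law",
    "fit_theta_linear",
    "error_budget",
    "reproducibility_summary",
    "stability_summary",
    "evaluate_qa",
    "baseline_from_sessions",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineRecord:
    """Commissioning baseline: θ_baseline per clinical aperture."""

    thetas: dict[float, float]
    date: datetime.date | None = None
    n_repeats: int = 5

    def __post_init__(self):
        items = sorted(self.thetas.items())
        if not items:
            raise ValidationError("baseline must contain at least one aperture")
        ds = np.array([d for d, _ in items])
        ts = np.array([t for _, t in items])
        if np.any(ts <= 0):
            raise ValidationError("baseline θ values must be positive")
        if np.any(np.diff(ts) <= 0):
            raise ValidationError(
                "baseline θ must increase strictly with aperture area"
            )
        object.__setattr__(self, "thetas", {float(d): float(t) for d, t in items})

    def at(self, diameter_mm: float) -> float:
        for d, t in self.thetas.items():
            if abs(d - diameter_mm) < 1e-9:
                return t
        raise KeyError(f"no baseline θ for aperture {diameter_mm} mm")


@dataclass(frozen=True)
class QAResult:
    """Outcome of evaluating one session against baseline and limits.

    ``table`` has one row per baseline aperture with columns: aperture_mm,
    theta, delta_pct, delta_mm, limit_plus_pct, limit_minus_pct, passed,
    reason (empty string when evaluable).
    """

    session_id: str
    table: pd.DataFrame = field(repr=False)
    overall_pass: bool
    limits_source: str


@dataclass(frozen=True)
class ErrorBudget:
    """Error components (percent of θ) and their quadrature combination.

    ``envelope_pct`` is a conservative working value reported alongside the
    quadrature sum; it is configuration, not a computed quantity.
    """

    output_pct: float
    mu_pct: float
    misalign_pct: float
    lac_pct: float
    combined_pct: float
    envelope_pct: float

    @property
    def components(self) -> tuple[float, float, float, float]:
        return (self.output_pct, self.mu_pct, self.misalign_pct, self.lac_pct)


@dataclass(frozen=True)
class SeriesSummary:
    """Per-aperture spread statistics across a series of sessions.

    ``kind`` is "reproducibility" (spread of DAP repeats within sessions)
    or "stability" (spread of θ across sessions).  ``per_aperture`` is a
    DataFrame indexed by row with aperture/collimator identification and
    the statistics in percent and mm.
    """

    kind: str
    per_aperture: pd.DataFrame = field(repr=False)


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of DAP = b · d^c (log-log space by default)."""

    b: float
    c: float
    residuals: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def _ratio_deviation_pct(num: float, den: float, what: str) -> float:
    if den <= 0:
        raise DomainError(f"{what}: denominator must be positive")
    return (num / den - 1.0) * 100.0


def delta(theta: float, theta_baseline: float) -> float:
    """QA deviation δ = (θ/θ_baseline − 1)·100, in percent."""
    return _ratio_deviation_pct(theta, theta_baseline, "delta")


def misalign_error(theta_misaligned: float, theta_aligned: float) -> float:
    """Δ_misalign = (θ_misaligned/θ_aligned − 1)·100, in percent."""
    return _ratio_deviation_pct(theta_misaligned, theta_aligned, "misalign_error")


def beamchange_error(theta_detuned: float, theta_unmodified: float) -> float:
    """Δ_beamchange = (θ_detuned/θ_unmodified − 1)·100, in percent."""
    return _ratio_deviation_pct(theta_detuned, theta_unmodified, "beamchange_error")


def delta_to_mm(delta_pct: float, diameter_mm: float) -> float:
    """Equivalent field-size deviation in mm for a δ in percent.

    Under pure area scaling DAP ∝ d², a relative DAP change 1 + δ/100
    corresponds to a diameter change d(√(1 + δ/100) − 1). The sign of the
    result follows δ.
    """
    if delta_pct <= -100.0:
        raise DomainError("delta must be > -100 percent")
    if diameter_mm <= 0:
        raise DomainError("diameter must be positive")
    return diameter_mm * (np.sqrt(1.0 + delta_pct / 100.0) - 1.0)


def mm_to_delta(dd_mm: float, diameter_mm: float) -> float:
    """Equivalent δ in percent for a field-size deviation in mm.

    Exact inverse of :func:`delta_to_mm`: ((d + Δd)²/d² − 1)·100.
    """
    if diameter_mm <= 0:
        raise DomainError("diameter must be positive")
    if diameter_mm + dd_mm <= 0:
        raise DomainError("perturbed diameter must be positive")
    return ((diameter_mm + dd_mm) ** 2 / diameter_mm ** 2 - 1.0) * 100.0


# ---------------------------------------------------------------------------
# tolerance limits from measurement
# ---------------------------------------------------------------------------

def measured_limits(theta_plus: dict[float, float],
                    theta_minus: dict[float, float],
                    baseline: BaselineRecord) -> ToleranceLimits:
    """Measured tolerance limits δ_measurement,±0.2(d).

    ``theta_plus``/``theta_minus`` are the per-aperture mean quotients from
    acquisitions with the aperture deliberately set to d + 0.2 mm and
    d − 0.2 mm.  Each limit is the percentage deviation of the perturbed
    mean from baseline.
    """
    limits: dict[float, tuple[float, float]] = {}
    missing = []
    for d in baseline.thetas:
        tp = _lookup(theta_plus, d)
        tm = _lookup(theta_minus, d)
        if tp is None or tm is None:
            missing.append(f"aperture {d} mm missing a perturbed θ mean")
            continue
        limits[d] = (delta(tp, baseline.at(d)), delta(tm, baseline.at(d)))
    if missing:
        raise ValidationError("measured_limits: incomplete perturbed data", missing)
    return ToleranceLimits(limits=limits, source="measured")


def _lookup(mapping: dict[float, float], d: float) -> float | None:
    for k, v in mapping.items():
        if abs(k - d) < 1e-9:
            return v
    return None


# ---------------------------------------------------------------------------
# characterization fits
# ---------------------------------------------------------------------------

def fit_dap_power_law(points, method: str = "loglog") -> PowerLawFit:
    """Fit DAP = b·d^c to (diameter, DAP) pairs.

    The default fits a straight line in log-log space, which weights the
    ~50-fold dynamic range between the 5 mm and 60 mm apertures scale-free.
    ``method="nls"`` performs raw nonlinear least squares instead (residual
    weighting then favours the large apertures).
    """
    pts = [(float(d), float(v)) for d, v in points]
    if len(pts) < 3:
        raise ValidationError("power-law fit needs >= 3 points")
    d = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    if np.any(d <= 0) or np.any(v <= 0):
        raise ValidationError("power-law fit needs positive diameters and values")
    if method == "loglog":
        c, logb = np.polyfit(np.log(d), np.log(v), 1)
        b = float(np.exp(logb))
        resid = np.log(v) - (np.log(b) + c * np.log(d))
    elif method == "nls":
        (b, c), _ = optimize.curve_fit(lambda x, b_, c_: b_ * x ** c_, d, v,
                                       p0=(v[-1] / d[-1] ** 2, 2.0))
        resid = v - b * d ** c
    else:
        raise DomainError("method must be 'loglog' or 'nls'")
    return PowerLawFit(b=float(b), c=float(c), residuals=np.asarray(resid))


def fit_theta_linear(points) -> float:
    """Through-origin least-squares slope of θ against aperture area (cm²).

    Returns b = Σxy / Σx² for the model θ = b·area.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 1:
        raise ValidationError("linear fit needs >= 1 point")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValidationError("linear fit undefined for all-zero areas")
    return float(np.sum(x * y) / sxx)


# ---------------------------------------------------------------------------
# error budget
# ---------------------------------------------------------------------------

def error_budget(output_pct: float = 0.04, mu_pct: float = 0.04,
                 misalign_pct: float = 0.0, lac_pct: float = 0.0,
                 envelope_pct: float = 0.2) -> ErrorBudget:
    """Combine independent error components (percent of θ) in quadrature.

    The combination is the root-sum-square of the components — order
    invariant and never below the largest component.  ``envelope_pct`` is a
    conservative working value reported alongside (default 0.2%); it is not
    derived from the components.
    """
    comps = (output_pct, mu_pct, misalign_pct, lac_pct)
    if any(c < 0 for c in comps):
        raise DomainError("error components must be >= 0")
    combined = float(np.sqrt(sum(c * c for c in comps)))
    return ErrorBudget(output_pct=output_pct, mu_pct=mu_pct,
                       misalign_pct=misalign_pct, lac_pct=lac_pct,
                       combined_pct=combined, envelope_pct=envelope_pct)


# ---------------------------------------------------------------------------
# series summaries
# ---------------------------------------------------------------------------

def reproducibility_summary(sessions: list[MeasurementSession]) -> SeriesSummary:
    """Within-session spread of DAP repeats, summarized across sessions.

    For each (collimator, aperture): the sample standard deviation (n−1
    denominator) of the repeat readings in each session, in percent of the
    session mean; then the median and first/third quartiles of those
    per-session values across sessions. mm equivalents convert the percent
    values through the area-scaling rule at that aperture.
    """
    if len(sessions) < 2:
        raise ValidationError("reproducibility summary needs >= 2 sessions")
    keys = sorted(
        {(c, float(a)) for s in sessions
         for c, a in zip(s.records["collimator"], s.records["aperture_mm"])},
        key=lambda k: (k[0], k[1]),
    )
    rows = []
    for collimator, d in keys:
        sds = []
        for s in sessions:
            r = s.readings(collimator, d)
            if r.size < 2:
                raise ValidationError(
                    f"session {s.session_id!r} has < 2 repeats for {collimator} {d} mm"
                )
            sds.append(float(np.std(r, ddof=1) / np.mean(r) * 100.0))
        q1, med, q3 = np.percentile(sds, [25, 50, 75])
        rows.append({
            "collimator": collimator, "aperture_mm": d,
            "sd_median_pct": med, "sd_q1_pct": q1, "sd_q3_pct": q3,
            "sd_median_mm": delta_to_mm(med, d),
            "sd_q1_mm": delta_to_mm(q1, d),
            "sd_q3_mm": delta_to_mm(q3, d),
            "n_sessions": len(sessions),
        })
    return SeriesSummary(kind="reproducibility", per_aperture=pd.DataFrame(rows))


def stability_summary(theta_series: dict[float, "np.ndarray"]) -> SeriesSummary:
    """Spread and trend of θ(d) across sessions.

    ``theta_series`` maps aperture diameter to the ordered θ values across
    sessions.  Reports the sample SD in percent of the mean and its mm
    equivalent, plus an ordinary least-squares slope of θ versus session
    index (with standard error) as the trend statistic backing a
    "no trend in time" check.
    """
    rows = []
    for d, series in sorted(theta_series.items()):
        y = np.asarray(series, dtype=float)
        if y.size < 2:
            raise ValidationError("stability summary needs >= 2 sessions per aperture")
        mean = float(np.mean(y))
        sd_pct = float(np.std(y, ddof=1) / mean * 100.0)
        x = np.arange(y.size, dtype=float)
        if np.allclose(y, y[0]):
            slope, stderr = 0.0, 0.0
        else:
            fit = stats.linregress(x, y)
            slope, stderr = float(fit.slope), float(fit.stderr)
        rows.append({
            "aperture_mm": float(d),
            "theta_mean": mean,
            "sd_pct": sd_pct,
            "sd_mm": delta_to_mm(sd_pct, float(d)),
            "trend_slope_per_session": slope,
            "trend_slope_stderr": stderr,
            "n_sessions": int(y.size),
        })
    return SeriesSummary(kind="stability", per_aperture=pd.DataFrame(rows))


def theta_series(sessions: list[MeasurementSession]) -> dict[float, np.ndarray]:
    """Collect per-aperture θ across sessions, in session order."""
    series: dict[float, list[float]] = {}
    for s in sessions:
        for d, t in s.thetas().items():
            series.setdefault(float(d), []).append(t)
    return {d: np.asarray(v) for d, v in series.items()}


# ---------------------------------------------------------------------------
# QA evaluation
# ---------------------------------------------------------------------------

def evaluate_qa(session: MeasurementSession, baseline: BaselineRecord,
                limits: ToleranceLimits) -> QAResult:
    """Evaluate one session against the commissioning baseline and limits.

    For every baseline aperture: θ(d) from session means, δ(d) against
    baseline, the mm equivalent, and a pass/fail against the per-aperture
    limits.  A δ exactly on a limit counts as a pass (the ±0.2 mm
    specification is inclusive).  An aperture missing from the session is
    reported as failed with a reason, never silently skipped; a missing
    fixed 60 mm reference is a validation error.
    """
    ref = session.readings("fixed", FIXED_REFERENCE_DIAMETER_MM)
    if ref.size == 0:
        raise ValidationError(
            f"session {session.session_id!r}: fixed 60 mm reference aperture "
            "is required for θ but missing"
        )
    ref_mean = float(ref.mean())
    rows = []
    all_pass = True
    for d in baseline.thetas:
        lim_plus, lim_minus = limits.at(d)
        r = session.readings("iris", d)
        if r.size == 0:
            rows.append({
                "aperture_mm": d, "theta": np.nan, "delta_pct": np.nan,
                "delta_mm": np.nan, "limit_plus_pct": lim_plus,
                "limit_minus_pct": lim_minus, "passed": False,
                "reason": "aperture missing from session",
            })
            all_pass = False
            continue
        th = float(r.mean()) / ref_mean
        dlt = delta(th, baseline.at(d))
        ok = bool(lim_minus <= dlt <= lim_plus)
        all_pass = all_pass and ok
        rows.append({
            "aperture_mm": d, "theta": th, "delta_pct": dlt,
            "delta_mm": delta_to_mm(dlt, d), "limit_plus_pct": lim_plus,
            "limit_minus_pct": lim_minus, "passed": ok, "reason": "",
        })
    return QAResult(session_id=session.session_id, table=pd.DataFrame(rows),
                    overall_pass=all_pass, limits_source=limits.source)


def baseline_from_sessions(sessions: list[MeasurementSession],
                           date: datetime.date | None = None) -> BaselineRecord:
    """Aggregate commissioning sessions into a baseline (mean θ per aperture)."""
    if not sessions:
        raise ValidationError("baseline aggregation needs >= 1 session")
    series = theta_series(sessions)
    thetas = {d: float(np.mean(v)) for d, v in series.items()}
    n = int(round(np.mean([
        s.readings("iris", d).size for s in sessions for d in series
    ]))) if sessions else 0
    return BaselineRecord(thetas=thetas,
                         date=date or sessions[0].date,
                         n_repeats=max(n, 1))
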