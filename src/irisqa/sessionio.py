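"""Readers and writers for sessions, baselines, limits, reports and config.

File formats are deliberately plain text:

* **Session CSV** — one row per exposure with the exact header
  ``session_id,date,collimator,aperture_mm,mu,repeat_index,reading_nC``;
  ISO-8601 dates, decimal points, UTF-8.
* **Baseline / limits** — YAML with metadata plus a per-aperture mapping;
  aperture keys are strings with one decimal ("7.5") to avoid float-key
  drift; numeric values round-trip at full precision.
* **Report** — JSON carrying the tool version, a configuration hash and
  the per-aperture QA table (percentages on the 0–100 scale, mm to three
  decimals in the rendered text, full precision in the JSON numbers).
* **Config** — YAML with ``chamber``, ``profile``, ``of_table`` and
  ``simulation`` sections.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beam import (
    BeamProfileModel,
    ChamberSpec,
    OutputFactorTable,
    default_output_factor_table,
)
from .dap import ToleranceLimits
from .errors import ValidationError
from .qa import BaselineRecord, QAResult
from .session import MeasurementSession
from .simulate import SimulationConfig

__all__ = [
    "SESSION_COLUMNS",
    "read_session",
    "write_session",
    "read_baseline",
    "write_baseline",
    "read_limits",
    "write_limits",
    "write_report",
    "read_report",
    "load_config",
    "default_config",
    "config_hash",
]

SESSION_COLUMNS = ["session_id", "date", "collimator", "aperture_mm",
                   "mu", "repeat_index", "reading_nC"]


def _format_aperture(d: float) -> str:
    return f"{float(d):.1f}"


# ---------------------------------------------------------------------------
# session CSV
# ---------------------------------------------------------------------------

def write_session(session: MeasurementSession, path) -> None:
    path = Path(path)
    df = session.records.copy()
    df.insert(0, "session_id", session.session_id)
    df.insert(1, "date", session.date.isoformat())
    df["aperture_mm"] = df["aperture_mm"].map(_format_aperture)
    df = df[SESSION_COLUMNS]
    df.to_csv(path, index=False)


def read_session(path) -> MeasurementSession:
    """Read a session CSV, reporting every malformed row with its line number."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"session file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != SESSION_COLUMNS:
        raise ValidationError(
            f"{path}: header must be exactly {','.join(SESSION_COLUMNS)}, "
            f"got {','.join(df.columns)}"
        )
    problems: list[str] = []
    rows = []
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after the header line
        rec = {}
        for col, caster in (("aperture_mm", float), ("mu", float),
                            ("repeat_index", int), ("reading_nC", float)):
            try:
                rec[col] = caster(row[col])
            except ValueError:
                problems.append(f"line {line}: non-numeric {col} {row[col]!r}")
        if row["collimator"] not in ("iris", "fixed"):
            problems.append(f"line {line}: collimator must be iris|fixed, "
                            f"got {row['collimator']!r}")
        if "reading_nC" in rec and rec["reading_nC"] <= 0:
            problems.append(f"line {line}: reading_nC must be positive")
        rec["collimator"] = row["collimator"]
        rows.append(rec)
    if problems:
        raise ValidationError(f"{path}: malformed session rows", problems)

    seen: dict[tuple, int] = {}
    for i, rec in enumerate(rows):
        key = (rec["collimator"], rec["aperture_mm"], rec["repeat_index"])
        if key in seen:
            problems.append(
                f"line {i + 2}: duplicate (collimator, aperture_mm, repeat_index) "
                f"{key} first seen on line {seen[key]}"
            )
        else:
            seen[key] = i + 2
    if problems:
        raise ValidationError(f"{path}: duplicate exposures", problems)

    session_ids = set(df["session_id"])
    dates = set(df["date"])
    if len(session_ids) != 1 or len(dates) != 1:
        raise ValidationError(f"{path}: file must contain exactly one session/date")
    session = MeasurementSession(
        session_id=session_ids.pop(),
        date=datetime.date.fromisoformat(dates.pop()),
        records=pd.DataFrame(rows),
    )
    session.validate(require_clinical=False)
    return session


# ---------------------------------------------------------------------------
# baseline / limits YAML
# ---------------------------------------------------------------------------

def write_baseline(baseline: BaselineRecord, path) -> None:
    doc = {
        "kind": "irisqa-baseline",
        "version": __version__,
        "date": baseline.date.isoformat() if baseline.date else None,
        "n_repeats": baseline.n_repeats,
        "theta_baseline": {_format_aperture(d): float(t)
                           for d, t in sorted(baseline.thetas.items())},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_baseline(path) -> BaselineRecord:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(doc, dict) or doc.get("kind") != "irisqa-baseline":
        raise ValidationError(f"{path}: not an irisqa baseline file")
    return BaselineRecord(
        thetas={float(k): float(v) for k, v in doc["theta_baseline"].items()},
        date=datetime.date.fromisoformat(doc["date"]) if doc.get("date") else None,
        n_repeats=int(doc.get("n_repeats", 5)),
    )


def write_limits(limits: ToleranceLimits, path) -> None:
    doc = {
        "kind": "irisqa-limits",
        "version": __version__,
        "source": limits.source,
        "delta_limits_pct": {
            _format_aperture(d): {"plus": float(p), "minus": float(m)}
            for d, (p, m) in sorted(limits.limits.items())
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_limits(path) -> ToleranceLimits:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(doc, dict) or doc.get("kind") != "irisqa-limits":
        raise ValidationError(f"{path}: not an irisqa limits file")
    return ToleranceLimits(
        limits={float(k): (float(v["plus"]), float(v["minus"]))
                for k, v in doc["delta_limits_pct"].items()},
        source=doc["source"],
    )


# ---------------------------------------------------------------------------
# QA report
# ---------------------------------------------------------------------------

def write_report(result: QAResult, path, config: dict | None = None) -> None:
    """Write a QA report as JSON (θ to 6 significant figures, percentages on
    the 0–100 scale, mm to 3 decimals in the summary lines)."""
    rows = []
    for _, r in result.table.iterrows():
        rows.append({
            "aperture_mm": _format_aperture(r["aperture_mm"]),
            "theta": None if np.isnan(r["theta"]) else float(f"{r['theta']:.6g}"),
            "delta_pct": None if np.isnan(r["delta_pct"]) else float(r["delta_pct"]),
            "delta_mm": None if np.isnan(r["delta_mm"]) else float(r["delta_mm"]),
            "limit_plus_pct": float(r["limit_plus_pct"]),
            "limit_minus_pct": float(r["limit_minus_pct"]),
            "passed": bool(r["passed"]),
            "reason": str(r["reason"]),
        })
    doc = {
        "kind": "irisqa-report",
        "version": __version__,
        "session_id": result.session_id,
        "limits_source": result.limits_source,
        "config_hash": config_hash(config) if config is not None else None,
        "overall_pass": result.overall_pass,
        "apertures": rows,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_report(path) -> dict:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("kind") != "irisqa-report":
        raise ValidationError(f"{path}: not an irisqa report file")
    return doc


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Default configuration dictionary (synthetic OF table, nominal chamber)."""
    table = default_output_factor_table()
    return {
        "chamber": {"active_diameter_mm": 81.6, "plane_sad_mm": 791.0,
                    "entrance_window_mm": 3.47},
        "profile": {"penumbra_mm": 3.0, "flatness": 0.0, "detune_level": 0.0},
        "of_table": {
            "extrapolation": "clamp",
            "values": [[d, f] for d, f in zip(table.diameters_mm, table.factors)],
        },
        "simulation": {
            "n_repeats": 5, "mu": 100.0,
            "output_drift_sd_pct": 0.04, "mu_delivery_sd_pct": 0.04,
            "aperture_jitter_sd_mm": 0.02, "misalignment_mm": 0.0,
            "detune_level": 0.0, "aperture_offsets_mm": {},
            "calibration_drift_mm_per_session": 0.0,
            "fixed_reference_reading_nc": 143.4,
        },
    }


def parse_config(doc: dict) -> tuple[BeamProfileModel, OutputFactorTable,
                                     ChamberSpec, SimulationConfig]:
    """Build model objects from a configuration dictionary."""
    doc = dict(doc or {})
    seed = int(doc.pop("seed", 0))
    merged = default_config()
    for section, values in doc.items():
        if section not in merged:
            raise ValidationError(f"unknown config section {section!r}")
        if section == "of_table" and "values" in values:
            merged[section]["values"] = values["values"]
            merged[section]["extrapolation"] = values.get(
                "extrapolation", merged[section]["extrapolation"])
        else:
            merged[section].update(values)
    ch = merged["chamber"]
    chamber = ChamberSpec(active_radius_mm=float(ch["active_diameter_mm"]) / 2.0,
                          plane_sad_mm=float(ch["plane_sad_mm"]),
                          entrance_window_mm=float(ch.get("entrance_window_mm", 3.47)))
    pr = merged["profile"]
    model = BeamProfileModel(penumbra_mm=float(pr["penumbra_mm"]),
                             flatness=float(pr["flatness"]),
                             detune_level=float(pr["detune_level"]))
    of = merged["of_table"]
    table = OutputFactorTable(
        diameters_mm=tuple(float(p[0]) for p in of["values"]),
        factors=tuple(float(p[1]) for p in of["values"]),
        extrapolation=of["extrapolation"],
    )
    sim = dict(merged["simulation"])
    sim["aperture_offsets_mm"] = {float(k): float(v)
                                  for k, v in sim.get("aperture_offsets_mm", {}).items()}
    config = SimulationConfig(seed=seed, **sim)
    return model, table, chamber, config


def load_config(path) -> tuple[BeamProfileModel, OutputFactorTable,
                               ChamberSpec, SimulationConfig]:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return parse_config(doc)


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a configuration dictionary (canonical JSON)."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()
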