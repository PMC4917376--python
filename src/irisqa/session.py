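"""In-memory container for a measurement session.

A session is one dated series of repeated chamber readings: for each of the
12 clinical iris apertures plus the fixed 60 mm reference cone, a fixed
number of 100 MU exposures is delivered and the uncorrected chamber reading
(nC) recorded.  The records live in a pandas DataFrame with one row per
exposure.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beam import CLINICAL_IRIS_DIAMETERS_MM, FIXED_REFERENCE_DIAMETER_MM
from .errors import ValidationError

__all__ = ["MeasurementSession", "RECORD_COLUMNS"]

RECORD_COLUMNS = ["collimator", "aperture_mm", "mu", "repeat_index", "reading_nC"]


@dataclass
class MeasurementSession:
    """One dated series of repeated chamber readings per aperture.

    ``records`` columns: collimator ("iris"|"fixed"), aperture_mm (float),
    mu (float), repeat_index (int, 0-based within an aperture), reading_nC
    (float, > 0).
    """

    session_id: str
    date: datetime.date
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"session records missing columns: {missing}")
        self.records = self.records[RECORD_COLUMNS].reset_index(drop=True)

    # -- access helpers -------------------------------------------------

    def readings(self, collimator: str, aperture_mm: float) -> np.ndarray:
        """Ordered repeat readings (nC) for one (collimator, aperture)."""
        m = (self.records["collimator"] == collimator) & (
            np.isclose(self.records["aperture_mm"], aperture_mm)
        )
        sub = self.records.loc[m].sort_values("repeat_index")
        return sub["reading_nC"].to_numpy(dtype=float)

    def mean_dap(self, collimator: str, aperture_mm: float) -> float:
        r = self.readings(collimator, aperture_mm)
        if r.size == 0:
            raise ValidationError(
                f"session {self.session_id!r} has no readings for "
                f"{collimator} {aperture_mm} mm"
            )
        return float(r.mean())

    def iris_diameters(self) -> list[float]:
        m = self.records["collimator"] == "iris"
        return sorted(set(float(d) for d in self.records.loc[m, "aperture_mm"]))

    def thetas(self) -> dict[float, float]:
        """Per-aperture QA quotient θ(d) from session means.

        θ(d) = mean(DAP_Iris(d)) / mean(DAP_Fixed(60 mm)); the arithmetic
        means are taken first, then the quotient.
        """
        ref = self.mean_dap("fixed", FIXED_REFERENCE_DIAMETER_MM)
        return {d: self.mean_dap("iris", d) / ref for d in self.iris_diameters()}

    # -- validation -----------------------------------------------------

    def validate(self, require_clinical: bool = True) -> None:
        """Check structural invariants; raise ValidationError listing all
        violations."""
        problems: list[str] = []
        if (self.records["reading_nC"] <= 0).any():
            bad = self.records.index[self.records["reading_nC"] <= 0].tolist()
            problems.append(f"non-positive readings at record index {bad}")
        dup = self.records.duplicated(subset=["collimator", "aperture_mm", "repeat_index"])
        if dup.any():
            problems.append(
                "duplicate (collimator, aperture_mm, repeat_index) at record "
                f"index {self.records.index[dup].tolist()}"
            )
        fixed = self.records[
            (self.records["collimator"] == "fixed")
            & np.isclose(self.records["aperture_mm"], FIXED_REFERENCE_DIAMETER_MM)
        ]
        if fixed.empty:
            problems.append("fixed 60 mm reference aperture is required but missing")
        if require_clinical:
            present = self.iris_diameters()
            for d in CLINICAL_IRIS_DIAMETERS_MM:
                if not any(np.isclose(d, p) for p in present):
                    problems.append(f"clinical iris aperture {d} mm missing")
        if problems:
            raise ValidationError(
                f"session {self.session_id!r} failed validation", problems
            )
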