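"""Subject records and their CSV dialect.

A subject is one volunteer: three physical attributes (age in years, weight
in kilograms, height in metres) and four tibial-rotation angles in degrees —
right/left tibial external/internal rotation (RTER, RTIR, LTER, LTIR).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: Rotation components, in canonical order.
ROTATIONS = ("RTER", "RTIR", "LTER", "LTIR")

#: Attribute name on :class:`Subject` for each rotation component.
ROTATION_FIELDS = {"RTER": "rter", "RTIR": "rtir", "LTER": "lter", "LTIR": "ltir"}

#: CSV header, in column order.
CSV_COLUMNS = (
    "age",
    "weight_kg",
    "height_m",
    "rter_deg",
    "rtir_deg",
    "lter_deg",
    "ltir_deg",
)

_FIELD_TO_COLUMN = {
    "age": "age",
    "weight": "weight_kg",
    "height": "height_m",
    "rter": "rter_deg",
    "rtir": "rtir_deg",
    "lter": "lter_deg",
    "ltir": "ltir_deg",
}


class SubjectError(ValueError):
    """A subject record violates its physical constraints."""


@dataclass(frozen=True)
class Subject:
    """One volunteer's physical attributes and tibial-rotation angles.

    Parameters
    ----------
    age : float
        Age in years, strictly positive.
    weight : float
        Body weight in kilograms, strictly positive.
    height : float
        Standing height in metres, strictly positive. Values above 3 are
        rejected as almost certainly centimetre inputs.
    rter, rtir, lter, ltir : float
        Tibial-rotation angles in degrees, each within [0, 90].
    """

    age: float
    weight: float
    height: float
    rter: float
    rtir: float
    lter: float
    ltir: float

    def __post_init__(self) -> None:
        for name in ("age", "weight", "height"):
            value = getattr(self, name)
            if not value > 0:
                raise SubjectError(f"{name} must be strictly positive, got {value!r}")
        if self.height > 3:
            raise SubjectError(
                f"height {self.height!r} m is implausible — heights above 3 m "
                "look like centimetre inputs; convert to metres"
            )
        for name in ROTATION_FIELDS.values():
            angle = getattr(self, name)
            if not 0 <= angle <= 90:
                raise SubjectError(
                    f"rotation angle {name} must lie in [0, 90] degrees, got {angle!r}"
                )

    def angle(self, rotation: str) -> float:
        """Return the angle of one rotation component (``"RTER"`` etc.)."""
        try:
            return getattr(self, ROTATION_FIELDS[rotation.upper()])
        except KeyError:
            raise KeyError(
                f"unknown rotation {rotation!r}; expected one of {ROTATIONS}"
            ) from None


def subjects_to_frame(subjects: Iterable[Subject]) -> pd.DataFrame:
    """Convert subjects to a DataFrame in the CSV column layout."""
    rows = [
        {_FIELD_TO_COLUMN[f.name]: getattr(s, f.name) for f in fields(Subject)}
        for s in subjects
    ]
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def frame_to_subjects(frame: pd.DataFrame) -> list[Subject]:
    """Build validated subjects from a DataFrame with the CSV columns."""
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise SubjectError(f"subject table is missing columns: {sorted(missing)}")
    column_to_field = {v: k for k, v in _FIELD_TO_COLUMN.items()}
    subjects = []
    for i, row in enumerate(frame.itertuples(index=False)):
        values = dict(zip(frame.columns, row))
        try:
            subjects.append(
                Subject(**{column_to_field[c]: float(values[c]) for c in CSV_COLUMNS})
            )
        except SubjectError as exc:
            raise SubjectError(f"row {i}: {exc}") from exc
    return subjects


def read_subjects_csv(path: str | Path) -> list[Subject]:
    """Read a subject table from CSV (UTF-8, decimal point)."""
    return frame_to_subjects(pd.read_csv(path, float_precision="round_trip"))


def write_subjects_csv(subjects: Sequence[Subject], path: str | Path) -> None:
    """Write subjects to CSV in the canonical column order."""
    # %.17g round-trips doubles exactly
    subjects_to_frame(subjects).to_csv(path, index=False, float_format="%.17g")
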