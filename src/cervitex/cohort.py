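"""Bundled 46-patient cohort: loading, validation and usage-band assignment.

The study cohort is shipped with the package as a plain CSV, one row per
patient: demographics (gender, age), self-reported daily hours of
social-media use (``h_mean``), the two vertebral-curve tangent angles and
the chord-enclosed area measured on the lateral radiograph, the four GLCM
texture features, the questionnaire class (1 = normal / no perceived neck
pain, 0 = abnormal / perceived pain), the deployed sigmoid-model score
(``gep_h``) and the class it predicts at the 0.5 threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

NORMAL = 1
ABNORMAL = 0

#: canonical column order of the cohort CSV
COLUMNS = [
    "patient_id", "gender", "age", "h_mean", "angle_1", "angle_2", "area",
    "contrast", "homogeneity", "correlation", "energy",
    "input_class", "gep_h", "predicted_class",
]

#: per-feature (min, max) reference bounds of the cohort, as printed.
#: Values are printed at 2 decimals for the texture features, so bound
#: checks allow half an ulp of the printed precision.
FEATURE_BOUNDS = {
    "age": (24.00, 58.00, 0.0),
    "h_mean": (0.5, 9.0, 0.0),
    "angle_1": (38.29, 101.89, 0.005),
    "angle_2": (34.24, 74.22, 0.005),
    "area": (269.00, 1305.00, 0.005),
    "contrast": (0.08, 2.88, 0.005),
    "homogeneity": (0.75, 0.98, 0.005),
    "correlation": (0.50, 0.95, 0.005),
    "energy": (0.16, 0.76, 0.005),
}

#: labels of the five usage bands (band 1 is the pain-free group)
BAND_LABELS = {
    1: "no-pain/normal",
    2: "2-3 h",
    3: "3-6 h",
    4: "6-9 h",
    5: ">9 h",
}


class CohortLoadError(ValueError):
    """Raised when a cohort file cannot be parsed into valid records."""


@dataclass(frozen=True)
class PatientRecord:
    patient_id: int
    gender: str                 # "male" | "female"
    age: int
    h_mean: float               # daily social-media hours
    angle_1: float              # tangent angle at C7 vs horizontal, degrees
    angle_2: float              # tangent angle at C1 vs horizontal, degrees
    area: float                 # curve-chord enclosed area, as printed
    contrast: float
    homogeneity: float
    correlation: float
    energy: float
    input_class: int            # questionnaire class: 1 normal, 0 abnormal
    gep_h: float                # deployed sigmoid-model score in [0, 1]
    predicted_class: int        # class implied by gep_h >= 0.5

    def feature(self, name: str):
        return getattr(self, name)


@dataclass
class UsageBand:
    band_index: int
    label: str


@dataclass
class ValidationReport:
    n_records: int
    class_counts: dict
    gender_counts: dict
    bound_checks: dict = field(default_factory=dict)  # field -> {min, max, ok}
    prediction_consistent: bool = True
    violations: list = field(default_factory=list)

    @property
    def all_passed(self) -> bool:
        return not self.violations

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def bundled_cohort_path() -> Path:
    """Filesystem path of the packaged cohort CSV."""
    return Path(resources.files("cervitex").joinpath("data/cohort.csv"))


def load_cohort(source: str | Path | None = None) -> list[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects.

    ``source=None`` loads the bundled 46-patient study cohort.  Row order
    is preserved.  A missing column, unparseable cell, or class value
    outside {0, 1} raises :class:`CohortLoadError` naming row and column.
    """
    path = Path(source) if source is not None else bundled_cohort_path()
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise CohortLoadError(f"no records in {path}") from None
    if df.empty:
        raise CohortLoadError(f"no records in {path}")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortLoadError(f"missing column(s): {', '.join(missing)}")

    records = []
    for idx, row in df.iterrows():
        rec = {}
        for col in COLUMNS:
            val = row[col]
            try:
                if col == "gender":
                    val = str(val).strip().lower()
                    if val not in ("male", "female"):
                        raise ValueError(val)
                elif col in ("patient_id", "age", "input_class", "predicted_class"):
                    val = int(val)
                else:
                    val = float(val)
            except (TypeError, ValueError):
                raise CohortLoadError(
                    f"unparseable cell at row {idx + 1}, column '{col}': {row[col]!r}"
                ) from None
            rec[col] = val
        for col in ("input_class", "predicted_class"):
            if rec[col] not in (0, 1):
                raise CohortLoadError(
                    f"class value outside {{0,1}} at row {idx + 1}, column '{col}'"
                )
        records.append(PatientRecord(**rec))
    return records


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Serialise records to CSV in the canonical column order."""
    cohort_frame(records).to_csv(path, index=False)


def cohort_frame(records: Iterable[PatientRecord] | None = None) -> pd.DataFrame:
    """Cohort as a DataFrame (bundled cohort when ``records`` is None)."""
    if records is None:
        records = load_cohort()
    return pd.DataFrame([asdict(r) for r in records], columns=COLUMNS)


def validate_cohort(records: Sequence[PatientRecord]) -> ValidationReport:
    """Check class/gender composition, feature bounds and score consistency.

    Violations are reported, never raised: the report lists class counts,
    gender counts, per-field min/max checks against the printed reference
    bounds, and whether ``predicted_class`` matches ``gep_h >= 0.5``.
    """
    if not records:
        raise ValueError("validate_cohort requires a non-empty record list")
    df = cohort_frame(records)
    report = ValidationReport(
        n_records=len(df),
        class_counts={
            "normal": int((df.input_class == NORMAL).sum()),
            "abnormal": int((df.input_class == ABNORMAL).sum()),
        },
        gender_counts=df.gender.value_counts().to_dict(),
    )
    for col, (lo, hi, tol) in FEATURE_BOUNDS.items():
        cmin, cmax = float(df[col].min()), float(df[col].max())
        ok = cmin >= lo - tol and cmax <= hi + tol
        report.bound_checks[col] = {"min": cmin, "max": cmax, "ok": ok}
        if not ok:
            report.violations.append(
                f"{col} outside [{lo}, {hi}]: observed [{cmin}, {cmax}]"
            )
    consistent = ((df.gep_h >= 0.5).astype(int) == df.predicted_class).all()
    report.prediction_consistent = bool(consistent)
    if not consistent:
        report.violations.append("predicted_class inconsistent with gep_h >= 0.5")
    return report


def band_of_usage(h_mean: float, input_class: int) -> UsageBand:
    """Assign the usage band of a subject.

    Normal subjects (no perceived pain) form band 1 regardless of hours.
    Subjects with perceived pain are banded by daily hours with
    right-closed intervals: h <= 3 -> band 2 ("2-3 h"), 3 < h <= 6 ->
    band 3, 6 < h <= 9 -> band 4, h > 9 -> band 5.  Painful subjects
    reporting under 2 h are folded into band 2 by convention.
    """
    if h_mean < 0:
        raise ValueError(f"negative usage hours: {h_mean}")
    if input_class == NORMAL:
        idx = 1
    elif h_mean <= 3:
        idx = 2
    elif h_mean <= 6:
        idx = 3
    elif h_mean <= 9:
        idx = 4
    else:
        idx = 5
    return UsageBand(idx, BAND_LABELS[idx])
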