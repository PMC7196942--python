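"""CSV interfaces for vessel, endpoint and score tables.

Dialect: UTF-8, comma-separated, header row required, '.' decimal point,
missing values as empty fields.  Schema violations raise
:class:`~casus.errors.ValidationError` with the offending line number
(1-based, counting the header as line 1) so shell users can locate them.
"""

from __future__ import annotations

import math
from typing import List

import pandas as pd

from .errors import ValidationError
from .prognostics import EVENT_TYPES, EndpointRecord
from .scoring import (
    GRADE_LABELS,
    MODALITIES,
    SIDES,
    VESSEL_NAMES,
    StenosisGrade,
    VesselRecord,
    grade_from_percent,
)

VESSEL_COLUMNS = [
    "patient_id", "vessel", "side", "modality",
    "stenosis_percent", "grade", "blood_flow_ml_min",
]
ENDPOINT_COLUMNS = [
    "patient_id", "event_type", "event_day", "followup_end_day", "lost_to_followup",
]
SCORE_COLUMNS = ["patient_id", "tss", "ri_tss", "gbf_ml_min"]


def _require_columns(df: pd.DataFrame, required: List[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} table lacks columns: {', '.join(missing)}")


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def read_vessel_table(path) -> pd.DataFrame:
    """Read and schema-check a vessel CSV (one row per vessel × modality)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "grade": str})
    if df.empty:
        raise ValidationError(f"vessel table {path} contains no rows")
    _require_columns(df, ["patient_id", "vessel", "side"], "vessel")
    for optional in ("modality", "stenosis_percent", "grade", "blood_flow_ml_min"):
        if optional not in df.columns:
            df[optional] = "" if optional in ("modality", "grade") else float("nan")
    df["modality"] = df["modality"].fillna("ultrasound").replace("", "ultrasound")
    return df


def vessel_records_from_frame(df: pd.DataFrame) -> List[VesselRecord]:
    """Turn a vessel table into validated :class:`VesselRecord` objects.

    ``grade`` takes precedence over ``stenosis_percent`` when both are
    present; if they disagree the row is rejected.  A row with neither is a
    clean (grade ``none``) vessel.
    """
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            vessel = str(row["vessel"]).strip()
            side = str(row["side"]).strip().lower()
            modality = str(row["modality"]).strip().lower()
            if vessel not in VESSEL_NAMES:
                raise ValidationError(f"unknown vessel {vessel!r}")
            if side not in SIDES:
                raise ValidationError(f"unknown side {side!r}")
            if modality not in MODALITIES:
                raise ValidationError(f"unknown modality {modality!r}")
            percent = None if _is_missing(row.get("stenosis_percent")) else float(
                row["stenosis_percent"]
            )
            grade_cell = row.get("grade")
            if not _is_missing(grade_cell):
                grade = StenosisGrade.from_label(str(grade_cell))
                if percent is not None and grade_from_percent(percent).score != grade.score:
                    raise ValidationError(
                        f"grade {grade.label!r} contradicts stenosis percent {percent}"
                    )
            elif percent is not None:
                grade = grade_from_percent(percent)
            else:
                grade = StenosisGrade.from_label("none")
            flow_cell = row.get("blood_flow_ml_min")
            flow = None if _is_missing(flow_cell) else float(flow_cell)
            records.append(
                VesselRecord(
                    patient_id=str(row["patient_id"]),
                    vessel=vessel,
                    side=side,
                    modality=modality,
                    grades_along_vessel=[grade],
                    stenosis_percent=percent,
                    blood_flow_ml_min=flow,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"vessel table line {line}: {exc}") from exc
    return records


def read_vessel_records(path) -> List[VesselRecord]:
    return vessel_records_from_frame(read_vessel_table(path))


def read_endpoint_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "event_type": str})
    if df.empty:
        raise ValidationError(f"endpoint table {path} contains no rows")
    _require_columns(df, ["patient_id", "followup_end_day"], "endpoint")
    for optional in ("event_type", "event_day", "lost_to_followup"):
        if optional not in df.columns:
            df[optional] = "" if optional == "event_type" else float("nan")
    return df


def endpoint_records_from_frame(df: pd.DataFrame) -> List[EndpointRecord]:
    """One :class:`EndpointRecord` per patient from the event-per-row table."""
    records = []
    for pid, sub in df.groupby("patient_id", sort=False):
        events = []
        end_days = set()
        lost = False
        for idx, row in sub.iterrows():
            line = idx + 2
            end_days.add(int(row["followup_end_day"]))
            cell = row.get("lost_to_followup")
            if not _is_missing(cell):
                lost = lost or str(cell).strip().lower() in ("1", "true", "yes")
            etype = row.get("event_type")
            if _is_missing(etype):
                continue
            etype = str(etype).strip()
            if etype not in EVENT_TYPES:
                raise ValidationError(
                    f"endpoint table line {line}: unknown event type {etype!r}"
                )
            if _is_missing(row.get("event_day")):
                raise ValidationError(
                    f"endpoint table line {line}: event {etype} lacks a day"
                )
            events.append((etype, int(row["event_day"])))
        if len(end_days) != 1:
            raise ValidationError(
                f"patient {pid}: inconsistent followup_end_day values {sorted(end_days)}"
            )
        try:
            records.append(
                EndpointRecord(
                    patient_id=str(pid),
                    events=events,
                    followup_end_day=end_days.pop(),
                    lost_to_followup=lost,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"patient {pid}: {exc}") from exc
    return records


def read_endpoint_records(path) -> List[EndpointRecord]:
    return endpoint_records_from_frame(read_endpoint_table(path))


def read_score_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    if df.empty:
        raise ValidationError(f"score table {path} contains no rows")
    _require_columns(df, ["patient_id", "tss", "gbf_ml_min"], "score")
    if "ri_tss" not in df.columns:
        df["ri_tss"] = float("nan")
    return df


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
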