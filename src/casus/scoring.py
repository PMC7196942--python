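"""Per-vessel stenosis grading and patient-level score aggregation.

The scale grades each extracranial supply vessel on ultrasound into five
categories — no stenosis (0), mild <50% (1), moderate 50–69% (2), severe
70–99% (3), occlusion 100% (4).  When a vessel carries several stenotic
segments, the narrowest segment (highest grade) scores the vessel.  A
patient's total stenosis score (TSS) is the sum over the bilateral common
carotid (CCA), internal carotid (ICA) and vertebral (VA, V1–V3) arteries;
the same sum computed from CTA/MRA grades is the radiological-imaging total
(RI-TSS).  Global blood flow (GBF, mL/min) is the sum of volumetric flow
over the measured vessels — bilateral ICA and VA by default — with occluded
vessels contributing 0 because no flow can be measured through them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import pandas as pd

from .errors import DomainError, MissingDataError, ValidationError

logger = logging.getLogger(__name__)

GRADE_LABELS = ("none", "mild", "moderate", "severe", "occlusion")
_LABEL_TO_SCORE = {label: score for score, label in enumerate(GRADE_LABELS)}

VESSEL_NAMES = ("CCA", "ICA", "VA")
SIDES = ("left", "right")
MODALITIES = ("ultrasound", "angiography")

#: Vessels whose grades enter the total stenosis score (six-vessel convention).
TSS_VESSEL_SET: Tuple[Tuple[str, str], ...] = tuple(
    (v, s) for v in VESSEL_NAMES for s in SIDES
)
#: Vessels whose flow enters global blood flow (flow is measured on ICA and VA).
GBF_VESSEL_SET: Tuple[Tuple[str, str], ...] = tuple(
    (v, s) for v in ("ICA", "VA") for s in SIDES
)


@dataclass(frozen=True)
class StenosisGrade:
    """One stenosis category with its fixed 0–4 score."""

    label: str
    score: int

    def __post_init__(self) -> None:
        if self.label not in _LABEL_TO_SCORE:
            raise ValidationError(f"unknown stenosis grade label {self.label!r}")
        if _LABEL_TO_SCORE[self.label] != self.score:
            raise ValidationError(
                f"grade label {self.label!r} is inconsistent with score {self.score}"
            )

    @classmethod
    def from_label(cls, label: str) -> "StenosisGrade":
        label = str(label).strip().lower()
        if label not in _LABEL_TO_SCORE:
            raise ValidationError(f"unknown stenosis grade label {label!r}")
        return cls(label, _LABEL_TO_SCORE[label])

    @classmethod
    def from_score(cls, score: int) -> "StenosisGrade":
        score = int(score)
        if not 0 <= score <= 4:
            raise DomainError(f"stenosis score must be in 0..4, got {score}")
        return cls(GRADE_LABELS[score], score)


NONE_GRADE = StenosisGrade("none", 0)
OCCLUSION = StenosisGrade("occlusion", 4)


def grade_from_percent(percent: float) -> StenosisGrade:
    """Map a diameter-reduction percentage to its grade.

    0 → none; (0, 50) → mild; [50, 70) → moderate; [70, 100) → severe;
    exactly 100 → occlusion.  The boundaries are half-open so that the
    printed category labels (<50, 50–69, 70–99, 100) are honoured.
    """
    percent = float(percent)
    if not 0.0 <= percent <= 100.0:
        raise DomainError(f"stenosis percent must be in [0, 100], got {percent}")
    if percent == 0.0:
        return NONE_GRADE
    if percent < 50.0:
        return StenosisGrade.from_score(1)
    if percent < 70.0:
        return StenosisGrade.from_score(2)
    if percent < 100.0:
        return StenosisGrade.from_score(3)
    return OCCLUSION


@dataclass
class VesselRecord:
    """One vessel's assessment on one modality.

    ``grades_along_vessel`` lists one grade per detected stenotic segment
    (a single ``none`` when the vessel is clean); the narrowest-segment rule
    reduces the list to the vessel's stenosis score.  ``stenosis_percent``
    refers to the narrowest segment when given, and must agree with the
    grade that :func:`grade_from_percent` assigns to it.
    """

    patient_id: str
    vessel: str
    side: str
    modality: str = "ultrasound"
    grades_along_vessel: Sequence[StenosisGrade] = field(
        default_factory=lambda: [NONE_GRADE]
    )
    stenosis_percent: Optional[float] = None
    blood_flow_ml_min: Optional[float] = None

    def __post_init__(self) -> None:
        if self.vessel not in VESSEL_NAMES:
            raise ValidationError(f"unknown vessel {self.vessel!r}")
        if self.side not in SIDES:
            raise ValidationError(f"unknown side {self.side!r}")
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if not self.grades_along_vessel:
            raise ValidationError("grades_along_vessel must be non-empty")
        if self.blood_flow_ml_min is not None and self.blood_flow_ml_min < 0:
            raise ValidationError("blood flow must be non-negative")
        ss = vessel_ss(self)
        if ss == 4 and self.blood_flow_ml_min not in (None, 0, 0.0):
            raise ValidationError(
                f"occluded vessel {self.vessel}-{self.side} of patient "
                f"{self.patient_id} must have zero flow, got {self.blood_flow_ml_min}"
            )
        if self.stenosis_percent is not None:
            implied = grade_from_percent(self.stenosis_percent)
            if implied.score != ss:
                raise ValidationError(
                    f"stenosis percent {self.stenosis_percent} implies grade "
                    f"{implied.label!r} but the vessel's grade is "
                    f"{GRADE_LABELS[ss]!r} ({self.vessel}-{self.side}, "
                    f"patient {self.patient_id})"
                )

    @property
    def is_occluded(self) -> bool:
        return vessel_ss(self) == 4


def vessel_ss(record: VesselRecord) -> int:
    """Stenosis score of one vessel: the narrowest segment governs (max grade)."""
    if not record.grades_along_vessel:
        raise ValidationError("grades_along_vessel must be non-empty")
    return max(g.score for g in record.grades_along_vessel)


def _check_duplicates(records: Sequence[VesselRecord], modality: str) -> dict:
    seen: dict = {}
    for rec in records:
        if rec.modality != modality:
            continue
        key = (rec.vessel, rec.side)
        if key in seen:
            raise ValidationError(
                f"duplicate record for {rec.vessel}-{rec.side} "
                f"({modality}) of patient {rec.patient_id}"
            )
        seen[key] = rec
    return seen


def total_stenosis_score(
    vessels: Sequence[VesselRecord],
    modality: str = "ultrasound",
    vessel_set: Sequence[Tuple[str, str]] = TSS_VESSEL_SET,
    strict: bool = False,
) -> int:
    """Sum of vessel stenosis scores over ``vessel_set`` for one patient.

    ``modality='ultrasound'`` yields the TSS, ``modality='angiography'`` the
    RI-TSS under identical rules.  Missing vessels count as grade ``none``
    with a logged warning so partial records remain scoreable; ``strict=True``
    raises instead.
    """
    if modality not in MODALITIES:
        raise ValidationError(f"unknown modality {modality!r}")
    by_key = _check_duplicates(vessels, modality)
    total = 0
    for key in vessel_set:
        rec = by_key.get(key)
        if rec is None:
            pid = vessels[0].patient_id if vessels else "?"
            if strict:
                raise MissingDataError(
                    f"missing {modality} record for {key[0]}-{key[1]} of patient {pid}"
                )
            logger.warning(
                "patient %s: no %s record for %s-%s, scored as no stenosis",
                pid, modality, key[0], key[1],
            )
            continue
        total += vessel_ss(rec)
    return total


def global_blood_flow(
    vessels: Sequence[VesselRecord],
    vessel_set: Sequence[Tuple[str, str]] = GBF_VESSEL_SET,
    modality: str = "ultrasound",
) -> float:
    """Global blood flow: summed vessel flow over ``vessel_set`` (mL/min).

    Occluded vessels contribute 0 (flow cannot be measured through an
    occlusion); a missing flow on any other contributing vessel raises
    :class:`MissingDataError` — no silent imputation.
    """
    by_key = _check_duplicates(vessels, modality)
    total = 0.0
    for key in vessel_set:
        rec = by_key.get(key)
        if rec is None:
            pid = vessels[0].patient_id if vessels else "?"
            raise MissingDataError(
                f"no {modality} record for GBF vessel {key[0]}-{key[1]} "
                f"of patient {pid}"
            )
        if rec.is_occluded:
            continue  # occlusion convention: flow taken as 0
        if rec.blood_flow_ml_min is None:
            raise MissingDataError(
                f"missing blood flow for non-occluded vessel {key[0]}-{key[1]} "
                f"of patient {rec.patient_id}"
            )
        total += float(rec.blood_flow_ml_min)
    return total


@dataclass(frozen=True)
class PatientScore:
    """Derived per-patient quantities: TSS, optional RI-TSS, and GBF."""

    patient_id: str
    tss: int
    gbf_ml_min: float
    ri_tss: Optional[int] = None

    def __post_init__(self) -> None:
        if self.tss < 0 or (self.ri_tss is not None and self.ri_tss < 0):
            raise ValidationError("total stenosis scores must be non-negative")
        if self.gbf_ml_min < 0:
            raise ValidationError("GBF must be non-negative")


def score_patient(
    vessels: Sequence[VesselRecord],
    tss_vessel_set: Sequence[Tuple[str, str]] = TSS_VESSEL_SET,
    gbf_vessel_set: Sequence[Tuple[str, str]] = GBF_VESSEL_SET,
    strict: bool = False,
) -> PatientScore:
    """Compute TSS, RI-TSS (when angiography records exist) and GBF for one patient."""
    if not vessels:
        raise ValidationError("cannot score a patient with no vessel records")
    pid = vessels[0].patient_id
    if any(v.patient_id != pid for v in vessels):
        raise ValidationError("score_patient expects records of a single patient")
    tss = total_stenosis_score(vessels, "ultrasound", tss_vessel_set, strict=strict)
    ri_tss: Optional[int] = None
    if any(v.modality == "angiography" for v in vessels):
        ri_tss = total_stenosis_score(
            vessels, "angiography", tss_vessel_set, strict=strict
        )
    gbf = global_blood_flow(vessels, gbf_vessel_set)
    return PatientScore(patient_id=pid, tss=tss, ri_tss=ri_tss, gbf_ml_min=gbf)


def score_cohort(
    records: Iterable[VesselRecord],
    tss_vessel_set: Sequence[Tuple[str, str]] = TSS_VESSEL_SET,
    gbf_vessel_set: Sequence[Tuple[str, str]] = GBF_VESSEL_SET,
    strict: bool = False,
) -> pd.DataFrame:
    """Score every patient in a stream of vessel records.

    Returns a DataFrame with columns ``patient_id, tss, ri_tss, gbf_ml_min``,
    one row per patient, in first-appearance order.
    """
    grouped: dict = {}
    for rec in records:
        grouped.setdefault(rec.patient_id, []).append(rec)
    if not grouped:
        raise ValidationError("no vessel records supplied")
    rows = []
    for pid, vessels in grouped.items():
        ps = score_patient(vessels, tss_vessel_set, gbf_vessel_set, strict=strict)
        rows.append(
            {
                "patient_id": pid,
                "tss": ps.tss,
                "ri_tss": ps.ri_tss,
                "gbf_ml_min": ps.gbf_ml_min,
            }
        )
    df = pd.DataFrame(rows)
    df["ri_tss"] = df["ri_tss"].astype("Int64")
    return df
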