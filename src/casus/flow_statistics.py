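"""Flow-based validation statistics for the stenosis scale.

The scale's central validation argument is hemodynamic: if the 0–4 grade is
a faithful severity measure, the mean blood-flow (BF) reduction of each
grade relative to the no-stenosis mean should scale linearly with the
grade.  The *calculated stenosis score* formalises this — each grade's mean
BF reduction divided by the mild-grade (reference) reduction, so mild is 1
by construction, and an occluded vessel is fixed at score 4 with flow 0.

Also here: the Cochrane imputation for the SD of a within-group change from
baseline, and cohort-level summary arithmetic (stenotic-vessel percentages,
endpoint incidences, GBF quintile binning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .scoring import StenosisGrade

logger = logging.getLogger(__name__)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention of clinical tables).

    numpy/python ``round`` rounds half to even; printed clinical percentages
    and score charts round half up, so this is explicit.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GradeFlowSummary:
    """Mean ± SD blood flow (or flow reduction) of one vessel type at one grade."""

    vessel: str
    grade: StenosisGrade
    mean_bf: float
    sd_bf: float
    n: int = 1

    def __post_init__(self) -> None:
        if self.sd_bf < 0:
            raise ValidationError("sd_bf must be non-negative")
        if self.n < 1:
            raise ValidationError("n must be at least 1")


#: Published flow chart: per-vessel no-stenosis mean BF and per-grade mean BF
#: reduction (mL/min, mean and SD).  These are inputs to the calculated-SS
#: statistic, not quantities this package re-derives.
DEFAULT_FLOW_CHART: Mapping[str, Mapping[str, tuple]] = {
    "ICA": {
        "none": (418.4, 73.5),
        "mild": (109.1, 76.3),
        "moderate": (189.4, 66.9),
        "severe": (301.0, 63.8),
    },
    "VA": {
        "none": (172.2, 32.9),
        "mild": (53.2, 31.9),
        "moderate": (86.5, 30.7),
        "severe": (141.3, 28.5),
    },
}


def bf_reduction(mean_no_stenosis: float, mean_with_grade: float) -> float:
    """Mean BF reduction of a grade: no-stenosis mean minus the grade's mean."""
    if mean_no_stenosis < 0 or mean_with_grade < 0:
        raise DomainError("mean flows must be non-negative")
    reduction = mean_no_stenosis - mean_with_grade
    if reduction < 0:
        logger.warning(
            "negative BF reduction (%.1f): grade mean exceeds no-stenosis mean",
            reduction,
        )
    return reduction


def calculated_ss(
    reduction: float,
    reference_reduction: float,
    is_occlusion: bool = False,
    decimals: Optional[int] = 1,
) -> float:
    """Calculated stenosis score: the grade's BF reduction over the mild reference.

    Occlusion is fixed at 4 by convention (its flow is unmeasurable and taken
    as 0).  The quotient is reported rounded half-up to ``decimals`` places
    (1 by default, matching the printed chart); ``decimals=None`` returns it
    unrounded.
    """
    if is_occlusion:
        return 4.0
    if reference_reduction <= 0:
        raise DomainError(
            "reference (mild) BF reduction must be positive for a non-occluded grade"
        )
    quotient = reduction / reference_reduction
    if decimals is None:
        return quotient
    return round_half_up(quotient, decimals)


def approximate_ss(calculated: float, is_occlusion: bool = False) -> int:
    """Approximate (integer) stenosis score: the calculated SS rounded to nearest."""
    if is_occlusion:
        return 4
    return int(round_half_up(calculated, 0))


def stenosis_score_chart(
    flow_chart: Mapping[str, Mapping[str, tuple]] = DEFAULT_FLOW_CHART,
) -> pd.DataFrame:
    """Build the flow / calculated-SS / approximate-SS chart from a flow config.

    ``flow_chart`` maps vessel → grade → (mean, sd), where the ``none`` entry
    is the no-stenosis mean BF and the graded entries are mean BF reductions.
    Occlusion needs no entry: its score is 4 by convention.
    """
    rows = []
    for vessel, entries in flow_chart.items():
        if "mild" not in entries:
            raise ValidationError(f"flow chart for {vessel} lacks the mild reference")
        reference = entries["mild"][0]
        for grade in ("none", "mild", "moderate", "severe"):
            if grade not in entries:
                continue
            mean, sd = entries[grade]
            if grade == "none":
                calc, approx, reduction = 0.0, 0, 0.0
            else:
                reduction = mean
                calc = calculated_ss(reduction, reference)
                approx = approximate_ss(calculated_ss(reduction, reference, decimals=None))
            rows.append(
                {
                    "vessel": vessel,
                    "grade": grade,
                    "mean": mean,
                    "sd": sd,
                    "bf_reduction": reduction,
                    "calculated_ss": calc,
                    "approximate_ss": approx,
                }
            )
        rows.append(
            {
                "vessel": vessel,
                "grade": "occlusion",
                "mean": np.nan,
                "sd": np.nan,
                "bf_reduction": entries["none"][0],
                "calculated_ss": 4.0,
                "approximate_ss": 4,
            }
        )
    return pd.DataFrame(rows)


def sd_of_change(sd_baseline: float, sd_final: float, corr: float = 0.5) -> float:
    """Imputed SD of a within-group change from baseline (Cochrane formula).

    ``sqrt(sd1² + sd2² − 2·corr·sd1·sd2)`` — the SD of (baseline − final)
    when only the two cross-sectional SDs and their correlation are known.
    """
    if sd_baseline < 0 or sd_final < 0:
        raise DomainError("standard deviations must be non-negative")
    if not -1.0 <= corr <= 1.0:
        raise DomainError(f"correlation must be in [-1, 1], got {corr}")
    variance = sd_baseline**2 + sd_final**2 - 2.0 * corr * sd_baseline * sd_final
    return float(np.sqrt(max(variance, 0.0)))


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """Percentage rounded half-up, as printed in clinical results text."""
    if total <= 0:
        raise DomainError("total must be positive")
    return round_half_up(100.0 * count / total, decimals)


def gbf_quintiles(gbf: Sequence[float]) -> np.ndarray:
    """Assign each patient to a GBF quintile (1..5, ties to the lower bin).

    Cuts are the empirical 20/40/60/80th percentiles; a value exactly on a
    cut falls in the lower bin.
    """
    values = np.asarray(gbf, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot bin an empty GBF vector")
    cuts = np.quantile(values, [0.2, 0.4, 0.6, 0.8])
    return np.searchsorted(cuts, values, side="left") + 1


def cohort_summary(
    scores: pd.DataFrame,
    vessels: Optional[pd.DataFrame] = None,
    endpoints: Optional[pd.DataFrame] = None,
) -> dict:
    """Descriptive cohort arithmetic.

    Returns a dict with per-vessel-type stenotic counts/percentages (from the
    ultrasound vessel table, ICA and VA), endpoint event counts/percentages,
    and the patient score table augmented with a ``gbf_quintile`` column.
    """
    if scores.empty:
        raise ValidationError("cohort is empty")
    out: dict = {"n_patients": int(len(scores))}

    scored = scores.copy()
    scored["gbf_quintile"] = gbf_quintiles(scored["gbf_ml_min"].to_numpy())
    out["scores"] = scored

    if vessels is not None:
        us = vessels[vessels["modality"] == "ultrasound"]
        us = us[us["vessel"].isin(["ICA", "VA"])]
        stenotic = us[us["grade"] != "none"]
        rows = [
            {
                "vessel": "all",
                "n_vessels": int(len(us)),
                "n_stenotic": int(len(stenotic)),
                "pct_stenotic": percentage(len(stenotic), len(us)),
            }
        ]
        for vessel in ("ICA", "VA"):
            sub = us[us["vessel"] == vessel]
            sub_sten = sub[sub["grade"] != "none"]
            if len(sub):
                rows.append(
                    {
                        "vessel": vessel,
                        "n_vessels": int(len(sub)),
                        "n_stenotic": int(len(sub_sten)),
                        "pct_stenotic": percentage(len(sub_sten), len(sub)),
                    }
                )
        out["stenotic_vessels"] = pd.DataFrame(rows)

    if endpoints is not None:
        n = out["n_patients"]
        events = endpoints.dropna(subset=["event_type"])
        events = events[events["event_type"].astype(str) != ""]
        rows = []
        for event_type, sub in events.groupby("event_type"):
            count = int(sub["patient_id"].nunique())
            rows.append(
                {
                    "event_type": event_type,
                    "n": count,
                    "pct": percentage(count, n),
                }
            )
        out["endpoint_events"] = pd.DataFrame(rows)

    return out


def format_summary(summary: dict) -> str:
    """Human-readable text rendering of :func:`cohort_summary` output."""
    lines = [f"Patients: {summary['n_patients']}"]
    if "stenotic_vessels" in summary:
        lines.append("Stenotic vessels:")
        for _, row in summary["stenotic_vessels"].iterrows():
            lines.append(
                f"  {row['vessel']}: {row['n_stenotic']}/{row['n_vessels']} "
                f"({row['pct_stenotic']}%)"
            )
    if "endpoint_events" in summary:
        lines.append("Endpoint events:")
        for _, row in summary["endpoint_events"].iterrows():
            lines.append(f"  {row['event_type']}: {row['n']} ({row['pct']}%)")
    counts = summary["scores"]["gbf_quintile"].value_counts().sort_index()
    lines.append(
        "GBF quintile sizes: " + ", ".join(f"Q{q}={c}" for q, c in counts.items())
    )
    return "\n".join(lines)
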