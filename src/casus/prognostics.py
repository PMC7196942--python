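"""Endpoint classification and ROC-based prognostic evaluation.

Follow-up endpoints — recurrent symptomatic stroke (primary), composite
cardiovascular events (recurrent stroke, cardiac death, non-fatal MI),
all-cause death, cardiovascular death — are reduced to binary flags at an
assessment horizon (30, 90 or 180 days).  The total stenosis score (TSS),
its angiographic counterpart (RI-TSS) and global blood flow (GBF) are then
evaluated as predictors: AUC by the Mann–Whitney pair-counting estimator
with the Hanley–McNeil standard error, 95% CI as AUC ± 1.96·SE, the best
prediction point (BPP) as the Youden-J-maximising threshold, and pairwise
correlated-AUC comparisons by DeLong's covariance test.  Higher scores mean
higher risk for TSS/RI-TSS; lower flow means higher risk for GBF, whose
values are negated internally so every AUC reads in the same direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import ValidationError

logger = logging.getLogger(__name__)

EVENT_TYPES = ("recurrent_stroke", "cardiac_death", "noncardiac_death", "nonfatal_mi")
DEATH_EVENTS = ("cardiac_death", "noncardiac_death")
#: Components of the composite cardiovascular endpoint.
COMPOSITE_EVENTS = ("recurrent_stroke", "cardiac_death", "nonfatal_mi")

ENDPOINTS = (
    "all_cause_death",
    "cardiovascular_death",
    "recurrent_stroke",
    "nonfatal_mi",
    "composite_cv",
)

HORIZONS = (30, 90, 180)


@dataclass
class EndpointRecord:
    """One patient's follow-up: events with days, censoring day, loss flag."""

    patient_id: str
    events: List[Tuple[str, int]] = field(default_factory=list)
    followup_end_day: int = 180
    lost_to_followup: bool = False

    def __post_init__(self) -> None:
        death_day = None
        for event_type, day in sorted(self.events, key=lambda e: e[1]):
            if event_type not in EVENT_TYPES:
                raise ValidationError(f"unknown event type {event_type!r}")
            if day < 0 or day > self.followup_end_day:
                raise ValidationError(
                    f"event day {day} outside follow-up of patient {self.patient_id}"
                )
            if death_day is not None and day > death_day:
                raise ValidationError(
                    f"patient {self.patient_id} has an event after death"
                )
            if event_type in DEATH_EVENTS:
                death_day = day


def classify_endpoints(record: EndpointRecord, horizon_day: int = 180) -> Dict[str, bool]:
    """Binary endpoint flags at an assessment horizon.

    A flag is true iff the qualifying event occurs on or before
    ``horizon_day``; ``censored_early`` marks patients lost to follow-up
    before the horizon with no event (they leave the ROC denominator).
    """
    if horizon_day not in HORIZONS:
        raise ValidationError(f"horizon must be one of {HORIZONS}, got {horizon_day}")
    by_horizon = [(t, d) for t, d in record.events if d <= horizon_day]
    types = {t for t, _ in by_horizon}
    flags = {
        "recurrent_stroke": "recurrent_stroke" in types,
        "nonfatal_mi": "nonfatal_mi" in types,
        "all_cause_death": bool(types & set(DEATH_EVENTS)),
        "cardiovascular_death": "cardiac_death" in types,
        "composite_cv": bool(types & set(COMPOSITE_EVENTS)),
    }
    flags["primary"] = flags["recurrent_stroke"]
    flags["censored_early"] = (
        record.lost_to_followup
        and record.followup_end_day < horizon_day
        and not by_horizon
    )
    return flags


def auc_mann_whitney(
    scores_pos: Sequence[float], scores_neg: Sequence[float]
) -> Tuple[float, float]:
    """AUC by pair counting (ties count ½) and its Hanley–McNeil SE.

    AUC = Σ over the n_pos·n_neg (case, control) pairs of
    [1 if case > control, ½ if tied, 0 otherwise] / (n_pos·n_neg),
    computed via midranks.  SE uses the Hanley–McNeil exponential
    approximation with Q1 = A/(2−A), Q2 = 2A²/(1+A).
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    n1, n0 = pos.size, neg.size
    auc = (ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n1 - 1) * (q1 - auc**2)
        + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    return float(auc), float(np.sqrt(max(var, 0.0)))


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components V10 (per case) and V01 (per control)."""
    pos = scores[labels]
    neg = scores[~labels]
    n1, n0 = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    auc = (all_ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    v10 = (all_ranks[:n1] - pos_ranks) / n0
    v01 = 1.0 - (all_ranks[n1:] - neg_ranks) / n1
    return float(auc), v10, v01


def delong_auc_variance(scores: Sequence[float], labels: Sequence[bool]) -> Tuple[float, float]:
    """AUC and its DeLong variance for a single predictor."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValidationError("labels must contain both classes")
    auc, v10, v01 = _delong_components(scores, labels)
    var = np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size
    return auc, float(var)


def compare_auc_delong(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
) -> Tuple[float, float, float]:
    """DeLong test for two correlated AUCs measured on the same patients.

    Returns (AUC_a − AUC_b, z, two-sided p).  When the paired variance of
    the difference is zero (identical rankings) the difference is reported
    with z = 0 and p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValidationError("both predictors must score the same patients")
    if labels.all() or not labels.any():
        raise ValidationError("labels must contain both classes")
    auc_a, v10_a, v01_a = _delong_components(a, labels)
    auc_b, v10_b, v01_b = _delong_components(b, labels)
    n1, n0 = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / n1 + s01 / n0
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        return float(diff), 0.0, 1.0
    z = diff / np.sqrt(var_diff)
    p = 2.0 * norm.sf(abs(z))
    return float(diff), float(z), float(p)


def best_prediction_point(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: str = "higher",
) -> float:
    """Threshold maximising Youden's J = sensitivity + specificity − 1.

    ``direction='higher'`` calls a patient positive when score ≥ threshold
    (TSS/RI-TSS); ``direction='lower'`` when score ≤ threshold (GBF).
    Thresholds range over the observed score values; ties in J resolve to
    the smallest qualifying threshold (on the risk-ordered scale), matching
    integer published cut-points.  If no threshold beats J = 0 the smallest
    observed score is returned with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValidationError("need at least one case and one control")
    if direction not in ("higher", "lower"):
        raise ValidationError("direction must be 'higher' or 'lower'")
    work = scores if direction == "higher" else -scores
    thresholds = np.unique(work)
    n1 = labels.sum()
    n0 = (~labels).sum()
    best_j, best_t = -np.inf, None
    for t in thresholds:  # ascending: first maximum is the smallest threshold
        sens = np.sum(work[labels] >= t) / n1
        spec = np.sum(work[~labels] < t) / n0
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    if best_j <= 1e-12:
        logger.warning("no threshold separates the classes (J = 0 everywhere)")
        best_t = thresholds[0]
    return float(best_t if direction == "higher" else -best_t)


@dataclass(frozen=True)
class RocResult:
    """One predictor–endpoint ROC summary row."""

    predictor_name: str
    endpoint: str
    auc: float
    se: float
    ci95: Tuple[float, float]
    best_prediction_point: float
    n_pos: int
    n_neg: int
    accurate: bool  # AUC ≥ 0.7, the conventional accuracy cut-off


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[bool],
    predictor_name: str,
    endpoint: str = "",
    direction: str = "higher",
) -> RocResult:
    """Full ROC summary for one predictor against one binary endpoint."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    work = scores if direction == "higher" else -scores
    auc, se = auc_mann_whitney(work[labels], work[~labels])
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    bpp = best_prediction_point(scores, labels, direction)
    return RocResult(
        predictor_name=predictor_name,
        endpoint=endpoint,
        auc=auc,
        se=se,
        ci95=(lo, hi),
        best_prediction_point=bpp,
        n_pos=int(labels.sum()),
        n_neg=int((~labels).sum()),
        accurate=auc >= 0.7,
    )


#: Risk direction of each standard predictor.
PREDICTOR_DIRECTIONS = {"TSS": "higher", "RI-TSS": "higher", "GBF": "lower"}


def evaluate_predictors(
    scores: pd.DataFrame,
    endpoint_records: Sequence[EndpointRecord],
    horizon_day: int = 180,
    predictors: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """ROC evaluation of TSS, RI-TSS and GBF against every endpoint.

    ``scores`` must have columns ``patient_id, tss, ri_tss, gbf_ml_min``
    (``ri_tss`` may be all-missing, dropping that predictor).  Patients lost
    to follow-up before the horizon with no event are excluded from each
    endpoint's denominator; endpoints with zero events at the horizon are
    skipped with a warning.  Returns (roc table, pairwise DeLong table).
    """
    records = {r.patient_id: r for r in endpoint_records}
    missing = set(scores["patient_id"]) - set(records)
    if missing:
        raise ValidationError(f"no endpoint record for patients {sorted(missing)[:5]}")

    columns = {"TSS": "tss", "RI-TSS": "ri_tss", "GBF": "gbf_ml_min"}
    if predictors is None:
        predictors = [p for p in columns
                      if columns[p] in scores and scores[columns[p]].notna().all()]
    roc_rows: List[dict] = []
    pair_rows: List[dict] = []
    for endpoint in ENDPOINTS:
        flags, censored = {}, {}
        for pid in scores["patient_id"]:
            f = classify_endpoints(records[pid], horizon_day)
            flags[pid] = f[endpoint]
            censored[pid] = f["censored_early"]
        keep = scores["patient_id"].map(lambda p: flags[p] or not censored[p])
        sub = scores[keep]
        labels = sub["patient_id"].map(flags).to_numpy(dtype=bool)
        if not labels.any():
            logger.warning("endpoint %s has zero events by day %d; skipped",
                           endpoint, horizon_day)
            continue
        if labels.all():
            logger.warning("endpoint %s has no controls by day %d; skipped",
                           endpoint, horizon_day)
            continue
        per_pred = {}
        for name in predictors:
            vals = sub[columns[name]].to_numpy(dtype=float)
            res = roc_analysis(vals, labels, name, endpoint,
                               PREDICTOR_DIRECTIONS[name])
            per_pred[name] = vals
            roc_rows.append(
                {
                    "endpoint": endpoint,
                    "predictor": name,
                    "auc": res.auc,
                    "se": res.se,
                    "ci_low": res.ci95[0],
                    "ci_high": res.ci95[1],
                    "bpp": res.best_prediction_point,
                    "n_pos": res.n_pos,
                    "n_neg": res.n_neg,
                    "accurate": res.accurate,
                }
            )
        for i, a in enumerate(predictors):
            for b in predictors[i + 1:]:
                va = per_pred[a] if PREDICTOR_DIRECTIONS[a] == "higher" else -per_pred[a]
                vb = per_pred[b] if PREDICTOR_DIRECTIONS[b] == "higher" else -per_pred[b]
                diff, z, p = compare_auc_delong(va, vb, labels)
                pair_rows.append(
                    {
                        "endpoint": endpoint,
                        "predictor_a": a,
                        "predictor_b": b,
                        "auc_difference": diff,
                        "z": z,
                        "p_value": p,
                    }
                )
    return pd.DataFrame(roc_rows), pd.DataFrame(pair_rows)
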