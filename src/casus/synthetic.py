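"""Synthetic stroke-cohort generator.

No patient-level data are deposited with the scale, so the pipeline is
exercised on simulated cohorts that reproduce the study conditions the
analysis assumes:

* per-grade vessel blood flow ~ Normal with the published flow-chart means
  (no-stenosis mean minus the grade's mean reduction) and the reduction SDs,
  truncated at 0; an occluded vessel flows 0;
* grade prevalence tuned so ~87% of ICA/VA vessels are stenotic;
* a whole-brain compensation curve that bends the mean GBF-versus-TSS
  relation into an inverse S: steep decline below the first knot, a
  collateral-compensated plateau between the knots (defaults 5 and 10),
  steep decline above;
* per-endpoint logistic event models in TSS whose slope is calibrated to a
  design AUC (default 0.75, binormal approximation) and whose intercept is
  root-found so the expected 180-day incidence matches the published rates
  (recurrent stroke 7.7%, all-cause death 5.2%, non-fatal MI 3.4%);
* loss to follow-up at 2.4%.

``generate_cohort`` returns the vessel and endpoint tables in the same CSV
dialects the pipeline consumes, plus the generator's ground truth for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .errors import CalibrationError, ValidationError
from .flow_statistics import DEFAULT_FLOW_CHART
from .scoring import GRADE_LABELS

#: Per-vessel grade probabilities over (none, mild, moderate, severe, occlusion).
#: ICA/VA: ~87% stenotic, mass concentrated in mild/moderate as in a first-stroke
#: cohort; CCA: mostly clean (its grades enter TSS but its flow is not measured).
DEFAULT_GRADE_PROBABILITIES: Mapping[str, Tuple[float, ...]] = {
    "ICA": (0.13, 0.37, 0.25, 0.15, 0.10),
    "VA": (0.14, 0.38, 0.24, 0.14, 0.10),
    "CCA": (0.70, 0.20, 0.07, 0.02, 0.01),
}

#: Death split: published 39 all-cause deaths include 16 cardiac.
CARDIAC_DEATH_FRACTION = 16.0 / 39.0

DEFAULT_EVENT_TARGETS: Mapping[str, float] = {
    "recurrent_stroke": 0.077,
    "all_cause_death": 0.052,
    "nonfatal_mi": 0.034,
}


def _grade_flow_means(flow_chart=DEFAULT_FLOW_CHART) -> Dict[str, Dict[str, Tuple[float, float]]]:
    """Per-grade measured-flow Normal(mean, sd) from the flow chart.

    Grade mean = no-stenosis mean − grade's mean reduction; grade SD = the
    reduction SD (the no-stenosis mean is treated as a fixed anchor).
    """
    out: Dict[str, Dict[str, Tuple[float, float]]] = {}
    for vessel, entries in flow_chart.items():
        base_mean, base_sd = entries["none"]
        grades = {"none": (base_mean, base_sd)}
        for grade in ("mild", "moderate", "severe"):
            red_mean, red_sd = entries[grade]
            grades[grade] = (base_mean - red_mean, red_sd)
        grades["occlusion"] = (0.0, 0.0)
        out[vessel] = grades
    return out


@dataclass(frozen=True)
class CompensationCurve:
    """Piecewise-linear target mean GBF over TSS with an inverse-S plateau.

    ``baseline`` is the expected no-stenosis GBF (four-vessel sum of the
    flow-chart means, 1181.2 mL/min by default); ``slopes`` are the mean-GBF
    change per TSS point below, between and above the knots.  The default
    shape is anchored at both physiological ends — the no-stenosis baseline
    at score 0 and near-zero measurable flow at the all-occluded maximum
    score 24 — with a near-flat collateral plateau between the knots: a
    sharp first decline of 80 mL/min per point, 8 per point across the
    plateau, then 53 per point down to zero.  ``knot_drops`` are small level
    drops at the knots modelling the threshold nature of collateral
    recruitment and exhaustion; they keep the curve monotone while making
    the knot positions identifiable from sampled data (a continuous
    piecewise curve fits equally well with either knot shifted by one score
    step, because the kink point lies on both adjacent pieces).
    """

    knots: Tuple[float, float] = (5.0, 10.0)
    slopes: Tuple[float, float, float] = (-80.0, -8.0, -53.0)
    knot_drops: Tuple[float, float] = (40.0, 50.0)
    baseline: float = 418.4 * 2 + 172.2 * 2

    def __post_init__(self) -> None:
        if not self.knots[0] < self.knots[1]:
            raise ValidationError("compensation knots must be strictly increasing")
        if min(self.knot_drops) < 0:
            raise ValidationError("knot drops must be non-negative")

    def mean_gbf(self, tss: float) -> float:
        t1, t2 = self.knots
        s1, s2, s3 = self.slopes
        d1, d2 = self.knot_drops
        if tss < t1:
            value = self.baseline + s1 * tss
        elif tss <= t2:
            value = self.baseline + s1 * t1 - d1 + s2 * (tss - t1)
        else:
            value = (self.baseline + s1 * t1 - d1 + s2 * (t2 - t1)
                     - d2 + s3 * (tss - t2))
        return max(value, 0.0)


@dataclass
class GeneratorConfig:
    """All knobs of the cohort generator; defaults are the study conditions."""

    n_patients: int = 750
    seed: int = 0
    #: SD (mL/min) of a patient's total-flow deviation from the compensation
    #: curve.  Vessel-level draws keep the flow-chart means but share a
    #: patient-level residual: cerebral autoregulation redistributes flow
    #: between supply vessels, so total flow is far less variable than an
    #: independent four-vessel sum would be — which is also what a strong
    #: cohort-level TSS–GBF fit (R² in the 0.8s) requires.
    total_flow_sd: float = 30.0
    grade_probabilities: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_GRADE_PROBABILITIES)
    )
    flow_chart: Mapping[str, Mapping[str, tuple]] = field(
        default_factory=lambda: dict(DEFAULT_FLOW_CHART)
    )
    compensation_curve: CompensationCurve = field(default_factory=CompensationCurve)
    event_targets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_TARGETS)
    )
    design_auc: float = 0.75
    loss_to_followup_prob: float = 0.024
    #: probability that an angiographic (CTA/MRA) grade deviates one category
    ri_disagreement_prob: float = 0.12
    followup_days: int = 180

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValidationError("n_patients must be positive")
        for vessel, probs in self.grade_probabilities.items():
            probs = np.asarray(probs, dtype=float)
            if probs.size != len(GRADE_LABELS) or probs.min() < 0:
                raise ValidationError(f"bad grade probabilities for {vessel}")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"grade probabilities for {vessel} must sum to 1"
                )
        if not 0.5 <= self.design_auc < 1.0:
            raise ValidationError("design_auc must be in [0.5, 1)")


def _solve_intercept(slope: float, tss: np.ndarray, target: float) -> float:
    def gap(intercept: float) -> float:
        return float(expit(intercept + slope * tss).mean()) - target

    lo, hi = -60.0, 60.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"target incidence {target} unreachable with slope {slope:.4f}"
        )
    intercept = float(brentq(gap, lo, hi, xtol=1e-10))
    if abs(gap(intercept)) > 1e-6:
        raise CalibrationError("intercept root-finding did not converge to 1e-6")
    return intercept


def model_implied_auc(
    intercept: float, slope: float, tss_distribution: Sequence[float]
) -> float:
    """Population AUC of TSS under P(event | TSS) = expit(a + b·TSS).

    Exact over the empirical TSS distribution, counting ties as ½ — the same
    convention the Mann–Whitney estimator uses, so a discrete score's tie
    mass is priced into the design instead of inflating it away.
    """
    tss = np.asarray(tss_distribution, dtype=float)
    values, counts = np.unique(tss, return_counts=True)
    freq = counts / counts.sum()
    p = expit(intercept + slope * values)
    w1 = freq * p
    w0 = freq * (1.0 - p)
    if w1.sum() <= 0 or w0.sum() <= 0:
        raise CalibrationError("event model leaves one outcome class empty")
    w1 /= w1.sum()
    w0 /= w0.sum()
    below = np.concatenate([[0.0], np.cumsum(w0)[:-1]])  # P(T0 < value)
    return float(np.sum(w1 * (below + 0.5 * w0)))


def calibrate_event_model(
    target_incidence: float,
    design_auc: float,
    tss_distribution: Sequence[float],
) -> Tuple[float, float]:
    """Calibrate a logistic event model P(event | TSS) = expit(a + b·TSS).

    The slope is root-found so the model-implied AUC of TSS for the event —
    computed exactly on the empirical TSS distribution with ties counted ½ —
    equals ``design_auc``; at each trial slope the intercept is root-found
    so the expected incidence matches ``target_incidence`` to 1e-6.  (A
    binormal shortcut b = √2·Φ⁻¹(AUC)/σ seeds the bracket but is not the
    final answer: TSS is discrete and its tie mass depresses the realised
    AUC below the continuous approximation.)
    """
    if not 0.5 <= design_auc < 1.0:
        raise CalibrationError("design AUC must be in [0.5, 1)")
    if not 0.0 < target_incidence < 1.0:
        raise CalibrationError("target incidence must be in (0, 1)")
    tss = np.asarray(tss_distribution, dtype=float)
    if design_auc == 0.5:
        return _solve_intercept(0.0, tss, target_incidence), 0.0
    sigma = tss.std()
    if sigma <= 0:
        raise CalibrationError(
            "TSS distribution is degenerate; no slope can reach the design AUC"
        )

    def auc_gap(slope: float) -> float:
        intercept = _solve_intercept(slope, tss, target_incidence)
        return model_implied_auc(intercept, slope, tss) - design_auc

    seed_slope = float(np.sqrt(2.0) * norm.ppf(design_auc) / sigma)
    hi = max(seed_slope * 2.0, 1.0)
    for _ in range(20):
        if auc_gap(hi) >= 0:
            break
        hi *= 2.0
    else:
        raise CalibrationError(
            f"design AUC {design_auc} unreachable on this TSS distribution"
        )
    slope = float(brentq(auc_gap, 0.0, hi, xtol=1e-10))
    intercept = _solve_intercept(slope, tss, target_incidence)
    return intercept, slope


@dataclass
class CohortData:
    """Generator output: pipeline-ready tables plus ground truth."""

    vessels: pd.DataFrame
    endpoints: pd.DataFrame
    scores: pd.DataFrame
    base_flows: pd.DataFrame  # pre-compensation flow draws (ICA/VA, ultrasound)
    ground_truth: dict


_PERCENT_RANGES = {
    "none": (0.0, 0.0),
    "mild": (5.0, 49.0),
    "moderate": (50.0, 69.0),
    "severe": (70.0, 99.0),
    "occlusion": (100.0, 100.0),
}


def _draw_percent(rng: np.random.Generator, grade: str) -> float:
    lo, hi = _PERCENT_RANGES[grade]
    if lo == hi:
        return lo
    return float(np.round(rng.uniform(lo, hi), 1))


def _shift_grade(rng: np.random.Generator, score: int) -> int:
    step = int(rng.choice([-1, 1]))
    return int(np.clip(score + step, 0, 4))


def generate_cohort(config: Optional[GeneratorConfig] = None) -> CohortData:
    """Draw a full synthetic cohort under ``config`` (reproducible by seed)."""
    config = config or GeneratorConfig()
    root = np.random.SeedSequence(config.seed)
    # independent sub-streams so each stage is stable under partial reruns
    rng_grades, rng_flows, rng_events, rng_ri = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    flow_means = _grade_flow_means(config.flow_chart)
    vessels_order = [(v, s) for v in ("CCA", "ICA", "VA") for s in ("left", "right")]

    vessel_rows, base_rows = [], []
    tss_list, ri_tss_list, gbf_list = [], [], []
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        grades: Dict[Tuple[str, str], int] = {}
        for vessel, side in vessels_order:
            probs = np.asarray(config.grade_probabilities[vessel], dtype=float)
            grades[(vessel, side)] = int(rng_grades.choice(5, p=probs))
        tss = sum(grades.values())

        # Base flows: per-grade Table-style draws, with the vessel deviations
        # projected so they sum to a single patient-level total-flow residual
        # e ~ N(0, total_flow_sd²).  Autoregulation redistributes flow between
        # supply vessels, so total flow is far less variable than an
        # independent four-vessel sum; vessel means stay anchored to the chart.
        base = {}
        deviations = {}
        expected_raw = 0.0
        draws, keys, sds = [], [], []
        for vessel, side in vessels_order:
            if vessel == "CCA":
                continue
            grade = GRADE_LABELS[grades[(vessel, side)]]
            mean, sd = flow_means[vessel][grade]
            expected_raw += mean
            if grade == "occlusion":
                base[(vessel, side)] = 0.0
                continue
            keys.append((vessel, side))
            sds.append(sd)
            draws.append(float(rng_flows.normal(mean, sd)))
        e = float(rng_flows.normal(0.0, config.total_flow_sd))
        if keys:
            sds_arr = np.asarray(sds)
            weights = sds_arr**2 / np.sum(sds_arr**2)
            excess = sum(draws) - sum(
                flow_means[v][GRADE_LABELS[grades[(v, s)]]][0] for v, s in keys
            ) - e
            for key, draw, w in zip(keys, draws, weights):
                dev = draw - w * excess - flow_means[key[0]][
                    GRADE_LABELS[grades[key]]][0]
                deviations[key] = dev
                base[key] = max(
                    flow_means[key[0]][GRADE_LABELS[grades[key]]][0] + dev, 0.0
                )

        # Whole-brain compensation: rescale the mean structure so that
        # E[GBF | TSS] follows the inverse-S target curve; the patient's
        # residual rides on top unscaled, keeping GBF noise homoscedastic.
        target = config.compensation_curve.mean_gbf(tss)
        factor = target / expected_raw if expected_raw > 0 else 0.0
        measured = {}
        for key in base:
            if key in deviations:
                mean = flow_means[key[0]][GRADE_LABELS[grades[key]]][0]
                # round per vessel so the emitted table and the recomputed
                # GBF agree exactly
                measured[key] = round(max(mean * factor + deviations[key], 0.0), 1)
            else:
                measured[key] = 0.0
        gbf = sum(measured.values())

        ri_scores: Dict[Tuple[str, str], int] = {}
        for key, score in grades.items():
            if rng_ri.random() < config.ri_disagreement_prob:
                ri_scores[key] = _shift_grade(rng_ri, score)
            else:
                ri_scores[key] = score
        ri_tss = sum(ri_scores.values())

        for vessel, side in vessels_order:
            grade = GRADE_LABELS[grades[(vessel, side)]]
            flow = measured.get((vessel, side))
            vessel_rows.append(
                {
                    "patient_id": pid,
                    "vessel": vessel,
                    "side": side,
                    "modality": "ultrasound",
                    "stenosis_percent": _draw_percent(rng_grades, grade),
                    "grade": grade,
                    "blood_flow_ml_min": flow if flow is not None else np.nan,
                }
            )
            ri_grade = GRADE_LABELS[ri_scores[(vessel, side)]]
            vessel_rows.append(
                {
                    "patient_id": pid,
                    "vessel": vessel,
                    "side": side,
                    "modality": "angiography",
                    "stenosis_percent": _draw_percent(rng_ri, ri_grade),
                    "grade": ri_grade,
                    "blood_flow_ml_min": np.nan,
                }
            )
            if vessel != "CCA":
                base_rows.append(
                    {
                        "patient_id": pid,
                        "vessel": vessel,
                        "side": side,
                        "grade": grade,
                        "blood_flow_ml_min": base[(vessel, side)],
                    }
                )
        tss_list.append(tss)
        ri_tss_list.append(ri_tss)
        gbf_list.append(round(gbf, 1))  # guard against float-sum dust

    tss_arr = np.asarray(tss_list, dtype=float)

    # calibrate the per-endpoint logistic models on the realised TSS values
    calibration: Dict[str, Tuple[float, float]] = {}
    for endpoint, target in config.event_targets.items():
        calibration[endpoint] = calibrate_event_model(
            target, config.design_auc, tss_arr
        )

    # Stratified event allocation: within each TSS value the number of events
    # is the stratum's expected count with stochastic rounding, assigned to
    # random patients.  Marginal risks follow the logistic model while the
    # realised incidence and discrimination concentrate on their design
    # values instead of drifting on binomial noise.
    event_flags: Dict[str, np.ndarray] = {}
    for endpoint, (a, b) in calibration.items():
        flags = np.zeros(config.n_patients, dtype=bool)
        for value in np.unique(tss_arr):
            idx = np.flatnonzero(tss_arr == value)
            expected = idx.size * float(expit(a + b * value))
            k = int(expected) + (rng_events.random() < expected - int(expected))
            k = min(k, idx.size)
            if k:
                flags[rng_events.choice(idx, size=k, replace=False)] = True
        event_flags[endpoint] = flags

    horizon = config.followup_days
    endpoint_rows = []
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        events = []
        for endpoint in calibration:
            if event_flags[endpoint][i]:
                day = int(rng_events.integers(1, horizon + 1))
                if endpoint == "all_cause_death":
                    cardiac = rng_events.random() < CARDIAC_DEATH_FRACTION
                    etype = "cardiac_death" if cardiac else "noncardiac_death"
                else:
                    etype = endpoint
                events.append((etype, day))
        lost = rng_events.random() < config.loss_to_followup_prob
        end_day = int(rng_events.integers(1, horizon)) if lost else horizon
        events = [(t, d) for t, d in sorted(events, key=lambda e: e[1])
                  if d <= end_day]
        # a death terminates the record
        trimmed = []
        for etype, day in events:
            trimmed.append((etype, day))
            if etype in ("cardiac_death", "noncardiac_death"):
                end_day = day
                break
        events = trimmed
        if events:
            for etype, day in events:
                endpoint_rows.append(
                    {
                        "patient_id": pid,
                        "event_type": etype,
                        "event_day": day,
                        "followup_end_day": end_day,
                        "lost_to_followup": lost,
                    }
                )
        else:
            endpoint_rows.append(
                {
                    "patient_id": pid,
                    "event_type": "",
                    "event_day": np.nan,
                    "followup_end_day": end_day,
                    "lost_to_followup": lost,
                }
            )

    scores = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(config.n_patients)],
            "tss": tss_list,
            "ri_tss": ri_tss_list,
            "gbf_ml_min": gbf_list,
        }
    )
    ground_truth = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "design_auc": config.design_auc,
        "compensation_knots": list(config.compensation_curve.knots),
        "compensation_slopes": list(config.compensation_curve.slopes),
        "baseline_gbf": config.compensation_curve.baseline,
        "event_calibration": {
            k: {"intercept": a, "slope": b} for k, (a, b) in calibration.items()
        },
        "event_targets": dict(config.event_targets),
        "loss_to_followup_prob": config.loss_to_followup_prob,
    }
    return CohortData(
        vessels=pd.DataFrame(vessel_rows),
        endpoints=pd.DataFrame(endpoint_rows),
        scores=scores,
        base_flows=pd.DataFrame(base_rows),
        ground_truth=ground_truth,
    )
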