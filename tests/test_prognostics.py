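"""Endpoint classification, AUC machinery, DeLong comparison, Youden point."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from casus.errors import ValidationError
from casus.prognostics import (
    EndpointRecord,
    auc_mann_whitney,
    best_prediction_point,
    classify_endpoints,
    compare_auc_delong,
    delong_auc_variance,
    evaluate_predictors,
    roc_analysis,
)


def brute_force_auc(pos, neg):
    """Independent oracle: direct enumeration of all (case, control) pairs."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestClassifyEndpoints:
    def test_recurrent_stroke_drives_primary_and_composite(self):
        rec = EndpointRecord("p", [("recurrent_stroke", 45)], 180)
        flags = classify_endpoints(rec, 180)
        assert flags["primary"] and flags["recurrent_stroke"]
        assert flags["composite_cv"]
        assert not flags["all_cause_death"]

    def test_noncardiac_death_excluded_from_composite(self):
        rec = EndpointRecord("p", [("noncardiac_death", 20)], 20)
        flags = classify_endpoints(rec, 180)
        assert flags["all_cause_death"]
        assert not flags["cardiovascular_death"]
        assert not flags["composite_cv"]

    def test_event_beyond_horizon_not_counted(self):
        rec = EndpointRecord("p", [("recurrent_stroke", 120)], 180)
        assert not classify_endpoints(rec, 90)["recurrent_stroke"]
        assert classify_endpoints(rec, 180)["recurrent_stroke"]

    def test_lost_without_event_is_censored_early(self):
        rec = EndpointRecord("p", [], 100, lost_to_followup=True)
        flags = classify_endpoints(rec, 180)
        assert flags["censored_early"]
        assert not any(flags[e] for e in ("primary", "composite_cv",
                                          "all_cause_death"))

    def test_event_after_death_rejected(self):
        with pytest.raises(ValidationError):
            EndpointRecord("p", [("cardiac_death", 10),
                                 ("recurrent_stroke", 30)], 180)

    def test_bad_horizon_rejected(self):
        with pytest.raises(ValidationError):
            classify_endpoints(EndpointRecord("p", [], 180), 45)


class TestAucMannWhitney:
    def test_small_worked_example(self):
        # pairs (3,1)+ (3,4)- (5,1)+ (5,4)+ → 3/4
        auc, se = auc_mann_whitney([3, 5], [1, 4])
        assert auc == pytest.approx(0.75)
        assert se > 0

    def test_perfect_separation(self):
        auc, _ = auc_mann_whitney([10, 11], [1, 2, 3])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _ = auc_mann_whitney([5, 5], [5, 5, 5])
        assert auc == 0.5

    def test_agrees_with_pair_counting_on_random_instances(self, rng):
        for _ in range(200):
            n_pos = int(rng.integers(1, 8))
            n_neg = int(rng.integers(1, 8))
            pos = rng.integers(0, 6, n_pos).astype(float)
            neg = rng.integers(0, 6, n_neg).astype(float)
            auc, _ = auc_mann_whitney(pos, neg)
            assert auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_agrees_with_trapezoidal_roc_area(self, rng):
        for _ in range(25):
            labels = rng.integers(0, 2, 60).astype(bool)
            if labels.all() or not labels.any():
                continue
            scores = rng.integers(0, 10, 60).astype(float)
            auc, _ = auc_mann_whitney(scores[labels], scores[~labels])
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @given(st.data())
    @settings(derandomize=True, max_examples=40)
    def test_invariant_under_monotone_transform(self, data):
        pos = data.draw(st.lists(st.integers(0, 20), min_size=1, max_size=10))
        neg = data.draw(st.lists(st.integers(0, 20), min_size=1, max_size=10))
        raw, _ = auc_mann_whitney(pos, neg)
        f = lambda v: np.expm1(np.asarray(v, dtype=float) / 3.0)
        transformed, _ = auc_mann_whitney(f(pos), f(neg))
        assert transformed == pytest.approx(raw, abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            auc_mann_whitney([], [1, 2])


class TestDeLong:
    LABELS = np.array([True, True, True, False, False, False])

    def test_identical_scores_give_p_one(self):
        s = np.array([3.0, 5, 6, 1, 2, 4])
        diff, z, p = compare_auc_delong(s, s, self.LABELS)
        assert diff == 0.0 and p == 1.0

    def test_monotone_transform_gives_zero_difference(self):
        s = np.array([3.0, 5, 6, 1, 2, 4])
        diff, _, _ = compare_auc_delong(s, np.exp(s / 2), self.LABELS)
        assert diff == pytest.approx(0.0, abs=1e-12)

    def test_p_matches_signflip_permutation_oracle(self, rng):
        """Paired-AUC p on a 6-patient set vs. the sign-flip permutation oracle.

        The oracle swaps the two predictors' scores patient-wise; with 6
        patients the 64 swap patterns can be enumerated exactly, and a
        10⁴-draw resampled version must agree with the exhaustive value
        within Monte-Carlo error.
        """
        a = np.array([3.0, 5, 6, 1, 2, 4])
        b = np.array([1.0, 2, 6, 3, 4, 5])
        labels = self.LABELS

        def auc_diff(x, y):
            return (brute_force_auc(x[labels], x[~labels])
                    - brute_force_auc(y[labels], y[~labels]))

        observed = auc_diff(a, b)
        exact_hits = 0
        for mask in itertools.product([0, 1], repeat=6):
            aa = np.where(mask, b, a)
            bb = np.where(mask, a, b)
            if abs(auc_diff(aa, bb)) >= abs(observed) - 1e-12:
                exact_hits += 1
        p_exact = exact_hits / 64.0
        assert p_exact == pytest.approx(0.0625)  # frozen oracle value

        n_resample = 10_000
        masks = rng.integers(0, 2, size=(n_resample, 6)).astype(bool)
        hits = 0
        for mask in masks:
            aa = np.where(mask, b, a)
            bb = np.where(mask, a, b)
            hits += abs(auc_diff(aa, bb)) >= abs(observed) - 1e-12
        p_mc = hits / n_resample
        mc_se = np.sqrt(p_exact * (1 - p_exact) / n_resample)
        assert abs(p_mc - p_exact) < 3 * mc_se + 1e-9

        _, _, p_delong = compare_auc_delong(a, b, labels)
        # asymptotic vs exact on n=6: agreement within the oracle's own
        # lattice spacing (1/64) plus small-sample allowance
        assert abs(p_delong - p_exact) < 0.05

    def test_variance_consistent_with_hanley_mcneil(self, rng):
        scores = np.concatenate([rng.normal(1.0, 1, 120), rng.normal(0, 1, 120)])
        labels = np.repeat([True, False], 120)
        auc_d, var_d = delong_auc_variance(scores, labels)
        auc_h, se_h = auc_mann_whitney(scores[labels], scores[~labels])
        assert auc_d == pytest.approx(auc_h, abs=1e-12)
        assert np.sqrt(var_d) == pytest.approx(se_h, rel=0.2)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValidationError):
            compare_auc_delong([1, 2], [1, 2, 3], [True, False, True])


class TestBestPredictionPoint:
    def test_separable_scores_report_smallest_positive_score(self):
        assert best_prediction_point([8, 9, 10, 1, 2, 3],
                                     [1, 1, 1, 0, 0, 0]) == 8.0

    def test_single_case_single_control(self):
        assert best_prediction_point([10, 1], [1, 0]) == 10.0

    def test_perfectly_mixed_scores_warn_and_return_smallest(self, caplog):
        with caplog.at_level("WARNING"):
            bpp = best_prediction_point([1, 2, 1, 2], [1, 0, 0, 1])
        assert bpp == 1.0
        assert "no threshold" in caplog.text

    def test_matches_full_enumeration_of_youden_j(self, rng):
        scores = rng.integers(0, 12, 80).astype(float)
        labels = rng.random(80) < (scores / 14.0)
        if labels.any() and not labels.all():
            bpp = best_prediction_point(scores, labels)
            best = max(
                np.unique(scores),
                key=lambda t: (np.mean(scores[labels] >= t)
                               + np.mean(scores[~labels] < t) - 1.0 - t * 1e-9),
            )
            assert bpp == best

    def test_lower_direction_flips_risk_ordering(self):
        # events have low flow
        scores = [400.0, 500, 900, 1000]
        labels = [1, 1, 0, 0]
        bpp = best_prediction_point(scores, labels, direction="lower")
        assert bpp == 500.0  # largest flow still called an event


class TestEvaluatePredictors:
    def test_rank_equivalent_predictors_share_auc(self, default_cohort):
        import pandas as pd
        scores = default_cohort.scores.copy()
        scores["gbf_ml_min"] = 2000.0 - 10.0 * scores["tss"]
        from casus.io import endpoint_records_from_frame
        records = endpoint_records_from_frame(default_cohort.endpoints)
        roc, pairs = evaluate_predictors(scores, records)
        by = roc.set_index(["endpoint", "predictor"])
        for endpoint in roc["endpoint"].unique():
            assert by.loc[(endpoint, "TSS"), "auc"] == pytest.approx(
                by.loc[(endpoint, "GBF"), "auc"], abs=1e-12
            )
        tss_gbf = pairs[(pairs.predictor_a == "TSS") & (pairs.predictor_b == "GBF")]
        assert (tss_gbf["p_value"] == 1.0).all()

    def test_label_independent_scores_have_null_auc(self, rng):
        import pandas as pd
        n = 4000
        scores = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "tss": rng.integers(0, 20, n),
            "ri_tss": rng.integers(0, 20, n),
            "gbf_ml_min": rng.uniform(200, 1200, n),
        })
        records = [
            EndpointRecord(f"p{i}",
                           [("recurrent_stroke", 10)] if rng.random() < 0.1 else [],
                           180)
            for i in range(n)
        ]
        roc, _ = evaluate_predictors(scores, records)
        sub = roc[roc.endpoint == "recurrent_stroke"]
        assert np.allclose(sub["auc"], 0.5, atol=0.03)
        assert not sub["accurate"].any()

    def test_report_covers_every_endpoint_and_predictor(self, default_cohort):
        from casus.io import endpoint_records_from_frame
        records = endpoint_records_from_frame(default_cohort.endpoints)
        roc, pairs = evaluate_predictors(default_cohort.scores, records)
        assert set(roc["predictor"]) == {"TSS", "RI-TSS", "GBF"}
        assert len(roc) == 5 * 3  # five endpoints × three predictors
        assert len(pairs) == 5 * 3  # three pairwise comparisons per endpoint
        assert ((roc["ci_low"] <= roc["auc"]) & (roc["auc"] <= roc["ci_high"])).all()

    def test_censored_early_patients_leave_denominator_only(self, default_cohort):
        from casus.io import endpoint_records_from_frame
        records = endpoint_records_from_frame(default_cohort.endpoints)
        flags = {r.patient_id: classify_endpoints(r, 180) for r in records}
        n_censored = sum(f["censored_early"] for f in flags.values())
        n_events = sum(f["recurrent_stroke"] for f in flags.values())
        roc, _ = evaluate_predictors(default_cohort.scores, records)
        row = roc[(roc.endpoint == "recurrent_stroke") &
                  (roc.predictor == "TSS")].iloc[0]
        assert row["n_pos"] == n_events  # exclusion never drops an event
        assert row["n_pos"] + row["n_neg"] == 750 - n_censored
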