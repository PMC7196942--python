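"""Score two patients' vessel assessments into TSS, RI-TSS and GBF.

Builds a minimal vessel table by hand — one patient with a severely
stenosed left ICA (ultrasound 80%, CTA reads it moderate) and one clean
patient — and runs the scoring pipeline on it.
"""

from casus import StenosisGrade, VesselRecord, score_cohort

records = []
for vessel in ("CCA", "ICA", "VA"):
    for side in ("left", "right"):
        severe_here = vessel == "ICA" and side == "left"
        flow = None
        if vessel != "CCA":  # flow is measured on ICA and VA only
            flow = 150.0 if severe_here else 350.0
        records.append(
            VesselRecord(
                patient_id="stroke-01", vessel=vessel, side=side,
                modality="ultrasound",
                grades_along_vessel=[
                    StenosisGrade.from_label("severe" if severe_here else "none")
                ],
                stenosis_percent=80.0 if severe_here else 0.0,
                blood_flow_ml_min=flow,
            )
        )
        # the CTA read of the same vessels (no flow on angiography)
        records.append(
            VesselRecord(
                patient_id="stroke-01", vessel=vessel, side=side,
                modality="angiography",
                grades_along_vessel=[
                    StenosisGrade.from_label("moderate" if severe_here else "none")
                ],
            )
        )
        if vessel != "CCA":
            records.append(
                VesselRecord(
                    patient_id="clean-02", vessel=vessel, side=side,
                    modality="ultrasound",
                    blood_flow_ml_min=418.4 if vessel == "ICA" else 172.2,
                )
            )

scores = score_cohort(records)
print(scores.to_string(index=False))
print()
print("tss sums the 0-4 grade over six vessels (severe left ICA -> 3);")
print("ri_tss applies the same rule to the CTA grades (moderate -> 2);")
print("gbf_ml_min sums measured flow over bilateral ICA and VA, so the")
print("clean patient sits at the no-stenosis total of 1181.2 mL/min.")
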