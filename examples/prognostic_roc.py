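"""Evaluate TSS, RI-TSS and GBF as 180-day stroke-prognosis predictors.

Simulates the default cohort (events calibrated to the published 180-day
incidences with a design AUC of 0.75 for TSS), classifies endpoints at the
180-day horizon, and prints the ROC report: AUC with Hanley-McNeil SE and
normal 95% CI, the Youden best prediction point (BPP), and pairwise DeLong
comparisons between the three predictors.
"""

import pandas as pd

from casus import GeneratorConfig, evaluate_predictors, generate_cohort
from casus.io import endpoint_records_from_frame

pd.set_option("display.width", 120)

cohort = generate_cohort(GeneratorConfig())  # n=750, seed 0
records = endpoint_records_from_frame(cohort.endpoints)
roc, pairs = evaluate_predictors(cohort.scores, records, horizon_day=180)

print(roc.round(3).to_string(index=False))
print()
print(pairs.round(3).to_string(index=False))
print()
print("AUC >= 0.7 marks a conventionally 'accurate' predictor.  TSS and")
print("RI-TSS read high-score = high-risk; GBF is negated internally")
print("(low flow = high risk), and its BPP is reported on the flow scale.")
print("The recurrent-stroke AUC of TSS recovers the generator's design")
print("value 0.75 within sampling error; pairwise DeLong p-values test")
print("whether two correlated AUCs differ on the same patients.")
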