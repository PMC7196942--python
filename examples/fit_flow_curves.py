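"""Fit the inverse-S relation between total stenosis score and global flow.

Simulates the default synthetic cohort (750 first-stroke patients), then
fits a single cubic and a three-segment search over integer breakpoint
pairs, printing the recovered knots against the generator's ground truth.
"""

from casus import GeneratorConfig, fit_cubic, fit_segmented, generate_cohort

cohort = generate_cohort(GeneratorConfig())  # n=750, seed 0
x = cohort.scores["tss"].to_numpy(float)
y = cohort.scores["gbf_ml_min"].to_numpy(float)

cubic = fit_cubic(x, y)
b0, b1, b2, b3 = cubic.coefficients
print(f"cubic fit: GBF = {b0:.1f} + {b1:.1f}*TSS + {b2:.2f}*TSS^2 "
      f"+ {b3:.3f}*TSS^3   (R^2 = {cubic.r_squared:.3f})")

seg = fit_segmented(x, y)
print(f"segmented fit: best breakpoints {seg.breakpoints}, "
      f"pooled R^2 = {seg.pooled_r_squared:.3f}")
print(f"generator truth: knots {tuple(cohort.ground_truth['compensation_knots'])}")
print()
print("GBF declines steeply with TSS until collateral compensation opens")
print("(first knot), stays nearly flat across the compensated plateau, and")
print("collapses again once compensation is exhausted (second knot); the")
print("three-segment fit's pooled R^2 always beats the single cubic on")
print("training data, and the breakpoint search localises the plateau.")
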