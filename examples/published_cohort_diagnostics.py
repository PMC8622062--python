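"""Triage diagnostics of the >=10% rewarming rule on published counts.

A 70-patient cohort assembled from case reports had 62 survivors and 8
non-survivors.  The eight non-survivor HOPE probabilities are published
individually, so the specificity side of the confusion table can be
recomputed from scratch; the survivor side is fixed by the published
counts (61 of 62 above threshold).  The output mirrors a diagnostic
performance table: numerator/denominator, percent, and 95% Wilson
interval for each metric.
"""

from hopescore import (
    CASE_REPORT_COUNTS,
    NON_SURVIVOR_PROBABILITIES,
    calibration_in_the_large,
    confusion,
    diagnostic_report,
)

# Recount the non-survivor side from the eight published probabilities.
table = confusion(NON_SURVIVOR_PROBABILITIES, ["died"] * 8, threshold=0.10)
print(f"non-survivors: tn={table.tn} fp={table.fp} (futile rewarming)")

# Full-table diagnostics from the published counts.
report = diagnostic_report(CASE_REPORT_COUNTS, confidence=0.95)
for metric in report.metrics():
    print(f"{metric.name:>12}: {metric.display()}")
print(f"{'correct':>12}: {report.correct_decision_fraction().display()}")

# Mean predicted probability among the non-survivors: prints as 30%,
# far above the 0% a perfectly sharp score would assign.
summary = calibration_in_the_large(NON_SURVIVOR_PROBABILITIES, ["died"] * 8,
                                   n_bootstrap=0)
print(f"non-survivor mean predicted survival: {summary.mean_predicted:.4f}")
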