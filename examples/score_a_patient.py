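"""Score a single hypothermic cardiac-arrest patient.

The patient here is a published case: a 6-year-old boy submerged in
water, admitted at a core temperature of 17 degC with potassium
7.6 mmol/L, after 95 minutes of CPR before cardiopulmonary bypass.  His
HOPE survival probability lands just under the 10% rewarming threshold —
yet he survived with full recovery, the canonical reminder that the
score informs, but never replaces, clinical judgment (especially in
children, where guidelines recommend expert consultation instead).
"""

from hopescore import (
    PEDIATRIC_SUBMERSION_CASE,
    REWARMING_THRESHOLD,
    classify,
    compute_score,
)

result = compute_score(PEDIATRIC_SUBMERSION_CASE)

print(f"linear score (log-odds): {result.score:.4f}")
print(f"survival probability:    {result.probability:.6f}  ({result.percent(2)})")
print(f">=10% rewarming rule:    {'rewarm' if classify(result.probability, REWARMING_THRESHOLD) else 'below threshold'}")
for note in result.warnings:
    print(f"note: {note}")

# The probability is ~9.93%: below the inclusive 10% criterion, so this
# survivor would have been the rule's single false negative.
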