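"""Scenario analysis when the mechanism of hypothermia is uncertain.

Whether a patient found in cold water was *immersed* (airway above
water, non-asphyxial) or *submerged* (airway under water, asphyxial)
changes the log-odds by the 1.95 asphyxia coefficient — enough to move a
survival estimate from 16% to 57%.  When the events are unclear, the
recommendation is to choose the variant giving the patient the highest
survival probability.
"""

from hopescore import PatientRecord, asphyxia_sensitivity
from hopescore.calibration import shift_probability

# A 44-year-old woman found in water; immersion vs submersion unknown.
patient = PatientRecord(id="uncertain", age=44, sex="female", asphyxia=True,
                        temperature=24.0, potassium=4.3, cpr_duration=150.0)
pair = asphyxia_sensitivity(patient)
print(f"submersion scenario (asphyxial):    {pair.probability_asphyxia:.3f}")
print(f"immersion scenario (non-asphyxial): {pair.probability_non_asphyxia:.3f}")
print(f"log-odds difference: {pair.logit_shift:.2f}  "
      f"(recommended when in doubt: {pair.recommended})")

# The shift is a property of the coefficient alone: any 16% asphyxial
# probability maps to 57% non-asphyxial.
print(f"16% asphyxial -> {shift_probability(0.16, 1.95):.3f} non-asphyxial")
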