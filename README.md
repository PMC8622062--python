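# hopescore

Survival prognostication and model-validation tools for **hypothermic
cardiac arrest treated with extracorporeal life support (ECLS)**.

Accidental hypothermia makes cardiac arrest reversible: patients rewarmed
on ECMO or cardiopulmonary bypass can recover fully after hours of CPR.
The decision to cannulate is therefore a triage problem, and the **HOPE
score** (Hypothermia Outcome Prediction after ECLS) addresses it with a
fixed-coefficient logistic model of in-hospital survival built on six
admission covariates. This package provides, for clinical researchers and
methodologists:

- the **calculator** with the published coefficients, strict input
  validation, and the field's data-preparation conventions (mechanism
  dichotomy, explicit +30 min CPR imputation);
- the **external-validation pipeline**: threshold triage diagnostics
  (sensitivity/specificity/PPV/NPV and false positive/negative fractions,
  each with a 95% Wilson interval), ROC/AUC discrimination with a DeLong
  interval, and calibration-in-the-large;
- a **synthetic-cohort simulator** with an outcome-dependent retention
  filter that reproduces how publication bias in case reports inflates
  observed survival — breaking calibration while leaving discrimination
  untouched.

## The model

For a patient with male indicator $m$, asphyxia indicator $a$
(submersion or avalanche with the head buried ⇒ 1; exposure or immersion
⇒ 0), age (years), potassium $K$ (mmol/L), CPR duration $t$ (minutes,
CPR start to ECLS start) and core temperature $T$ (°C):

$$\mathrm{score} = 2.44 - 1.55\,m - 1.95\,a - 0.0191\,\mathrm{age}
  - 2.07\log_2 K - 0.573\log_2 t + 0.937\,T - 0.0247\,T^2$$

$$P(\text{survival}) = \frac{e^{\mathrm{score}}}{1 + e^{\mathrm{score}}}$$

A survival probability **≥ 10%** (inclusive, on unrounded values) is the
suggested criterion to initiate ECLS rewarming.

## Worked example

```python
from hopescore import PatientRecord, compute_score

boy = PatientRecord(id="case", age=6, sex="male", mechanism="submersion",
                    temperature=17.0, potassium=7.6, cpr_duration=95)
result = compute_score(boy)
print(result.score)        # -2.2052460599850145
print(result.probability)  # 0.09928037938991607
print(result.percent(2))   # 9.93%
```

This is a real published case — a 6-year-old boy submerged in water who
survived with full recovery despite a probability just *under* the 10%
threshold (the rule's single false negative in a 70-patient literature
cohort). The score is decision support, not a verdict; in children,
guidelines recommend expert consultation instead, and the calculator
flags this (`result.warnings`).

Cohort-level evaluation mirrors a diagnostic-performance table
(`examples/published_cohort_diagnostics.py` prints, from the published
counts of that cohort):

```
 sensitivity: 61/62 = 98% (91-100%)
 specificity: 3/8 = 38% (14-69%)
         ppv: 61/66 = 92% (83-97%)
         npv: 3/4 = 75% (30-95%)
```

And `examples/publication_bias_simulation.py` shows the selection-bias
mechanism on a 20,000-patient synthetic cohort (survivors retained at
0.9, non-survivors at 0.05):

```
full cohort   (n=20000): observed 0.400, mean predicted 0.398, AUC 0.850
after filter  (n=7833): observed 0.920, mean predicted 0.583, AUC 0.849
```

Observed survival soars past the mean prediction while the AUC does not
move: selection on the outcome alone destroys calibration but spares
discrimination — which is why scores must be derived and validated on
*consecutive* patients.

There is also a thin CLI: `hope score`, `hope evaluate`,
`hope simulate`, `hope fixtures` (see `hope --help`).

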