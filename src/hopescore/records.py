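"""Patient records and admission-covariate conventions.

The HOPE score estimates in-hospital survival for patients in hypothermic
cardiac arrest who are rewarmed with extracorporeal life support (ECLS).
It uses six covariates available at hospital admission: age, sex, the
mechanism of cooling, core temperature, serum potassium, and the duration
of CPR from its initiation to the start of ECLS.

Two conventions from the score's clinical use live here:

* The mechanism of hypothermia is dichotomised into *asphyxia-related*
  (submersion; avalanche with the head buried under the snow) and
  *non-asphyxia-related* (cold exposure outdoors or indoors; immersion
  with the airway above water).  The asphyxia flag enters the score with
  a large negative weight, so the classification matters clinically.
* When the interval between hospital admission and the start of ECLS is
  not reported, 30 minutes are added to the CPR duration measured up to
  admission.  That imputation is always explicit, never silent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import NamedTuple


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Mechanism(str, Enum):
    """Mechanism of accidental hypothermia."""

    EXPOSURE = "exposure"
    IMMERSION = "immersion"  # in cold water, airway above the surface
    SUBMERSION = "submersion"  # airway under water
    AVALANCHE_HEAD_BURIED = "avalanche_head_buried"
    OTHER_ASPHYXIAL = "other_asphyxial"
    OTHER_NON_ASPHYXIAL = "other_non_asphyxial"


class Outcome(str, Enum):
    SURVIVED = "survived"
    DIED = "died"


#: Mechanisms that compromise the airway before or during cooling.
ASPHYXIAL_MECHANISMS = frozenset(
    {Mechanism.SUBMERSION, Mechanism.AVALANCHE_HEAD_BURIED, Mechanism.OTHER_ASPHYXIAL}
)


def classify_mechanism(mechanism: Mechanism | str) -> bool:
    """Return the asphyxia flag implied by a mechanism of hypothermia.

    Submersion, avalanche burial of the head, and other asphyxial
    mechanisms map to ``True``; exposure to cold and immersion (head above
    water) map to ``False``.

    Raises
    ------
    ValueError
        If ``mechanism`` is not one of the recognised labels.
    """
    try:
        mechanism = Mechanism(mechanism)
    except ValueError:
        valid = ", ".join(m.value for m in Mechanism)
        raise ValueError(
            f"unknown hypothermia mechanism {mechanism!r}; expected one of: {valid}"
        ) from None
    return mechanism in ASPHYXIAL_MECHANISMS


class ImputedMinutes(NamedTuple):
    """A CPR duration carrying a provenance flag for the +30 min rule."""

    minutes: float
    imputed: bool = True


def impute_cpr_from_admission(cpr_before_admission: float) -> ImputedMinutes:
    """Extend a CPR duration measured only up to hospital admission.

    When a report gives the CPR time up to admission but not the interval
    from admission to the start of ECLS, 30 minutes are added to stand in
    for the in-hospital delay to cannulation.  The returned value carries
    ``imputed=True`` so downstream output can disclose the convention.

    Raises
    ------
    ValueError
        If ``cpr_before_admission`` is not strictly positive.
    """
    if not cpr_before_admission > 0:
        raise ValueError(
            f"CPR duration before admission must be positive, got {cpr_before_admission}"
        )
    return ImputedMinutes(float(cpr_before_admission) + 30.0, True)


@dataclass(frozen=True)
class PatientRecord:
    """One patient's admission covariates and, optionally, the outcome.

    Parameters
    ----------
    id : str
        Opaque label used in batch error reporting.
    age : float
        Age in years (>= 0).
    sex : Sex or str
    mechanism : Mechanism, str or None
        Mechanism of hypothermia.  May be omitted if ``asphyxia`` is
        given directly (e.g. data extracted with only the dichotomy).
    asphyxia : bool or None
        Asphyxia flag.  Derived from ``mechanism`` when omitted; if both
        are given they must agree.
    temperature : float
        Core temperature at admission, degrees Celsius.
    potassium : float
        Serum potassium, mmol/L (> 0: the score takes its logarithm).
    cpr_duration : float
        Minutes from CPR initiation to the start of ECLS (> 0).
    cpr_imputed : bool
        True when ``cpr_duration`` includes the +30 min admission-to-ECLS
        imputation.
    outcome : Outcome, str or None
        Survival to hospital discharge, when known.
    cpc : int or None
        Cerebral performance category (1-5) at discharge; only meaningful
        for survivors, and 1-2 counts as a favourable neurological outcome.
    extra : dict
        Passthrough columns preserved by the readers, never interpreted.
    """

    id: str = ""
    age: float | None = None
    sex: Sex | None = None
    mechanism: Mechanism | None = None
    asphyxia: bool | None = None
    temperature: float | None = None
    potassium: float | None = None
    cpr_duration: float | None = None
    cpr_imputed: bool = False
    outcome: Outcome | None = None
    cpc: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex is not None:
            object.__setattr__(self, "sex", Sex(self.sex))
        if self.mechanism is not None:
            object.__setattr__(self, "mechanism", Mechanism(self.mechanism))
        if self.outcome is not None:
            object.__setattr__(self, "outcome", Outcome(self.outcome))

        if self.age is not None and not (self.age >= 0 and math.isfinite(self.age)):
            raise ValueError(f"age must be a finite nonnegative number, got {self.age}")
        if self.potassium is not None and not self.potassium > 0:
            raise ValueError(
                f"potassium must be > 0 mmol/L (its logarithm enters the score), "
                f"got {self.potassium}"
            )
        if self.cpr_duration is not None and not self.cpr_duration > 0:
            raise ValueError(
                f"cpr_duration must be > 0 min (its logarithm enters the score), "
                f"got {self.cpr_duration}"
            )

        if self.mechanism is not None:
            implied = classify_mechanism(self.mechanism)
            if self.asphyxia is None:
                object.__setattr__(self, "asphyxia", implied)
            elif bool(self.asphyxia) != implied:
                raise ValueError(
                    f"asphyxia flag {self.asphyxia} contradicts mechanism "
                    f"{self.mechanism.value!r} (implies asphyxia={implied})"
                )

        if self.cpc is not None:
            if self.cpc not in (1, 2, 3, 4, 5):
                raise ValueError(f"cpc must be an integer 1-5, got {self.cpc}")
            if self.outcome is not None and self.outcome is not Outcome.SURVIVED:
                raise ValueError(
                    "cpc is assessed at hospital discharge and is only meaningful "
                    "for survivors"
                )

    def with_asphyxia(self, flag: bool) -> "PatientRecord":
        """Copy of this record with the asphyxia flag forced to ``flag``.

        The mechanism is dropped so the override cannot contradict it;
        used for scenario analyses when the mechanism is uncertain.
        """
        return replace(self, mechanism=None, asphyxia=bool(flag))

    def with_outcome(self, outcome: Outcome | None) -> "PatientRecord":
        return replace(self, outcome=outcome)
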