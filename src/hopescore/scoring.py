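"""The HOPE score: a fixed-coefficient logistic model of survival.

The linear predictor (log-odds of in-hospital survival) is

    score = 2.44 - 1.55*male - 1.95*asphyxia - 0.0191*age
            - 2.07*log2(potassium) - 0.573*log2(cpr_duration)
            + 0.937*temperature - 0.0247*temperature**2

and the survival probability is the logistic transform
``exp(score) / (1 + exp(score))``.  The coefficients are published
constants; this package never refits them.  Temperature enters as a
concave quadratic whose vertex sits near 19 degrees C, so the log-odds
rise with temperature in the deeply hypothermic range and fall above the
vertex.  All other covariates carry negative weights: survival odds fall
with male sex, asphyxial mechanism, age, potassium and CPR duration.

The calculator is total over valid inputs: covariates outside the ranges
seen in validation cohorts, temperatures above the 32 degrees C hypothermic
cardiac-arrest limit, and paediatric ages produce *warnings*, never
errors — cohort-level exclusions belong to the pipeline, not the formula.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

from scipy.special import expit, logit as _logit

from .records import PatientRecord, Sex

__all__ = [
    "ScoreCoefficients",
    "HopeResult",
    "BatchResult",
    "BatchFailure",
    "MissingCovariateError",
    "DEFAULT_COEFFICIENTS",
    "OBSERVED_RANGES",
    "compute_score",
    "score_batch",
    "logit_to_probability",
    "probability_to_logit",
    "format_probability",
]


@dataclass(frozen=True)
class ScoreCoefficients:
    """The published HOPE log-odds contributions, versioned in one place.

    Overriding any value is an explicit user act; the coefficient set in
    force is echoed into run metadata so scored output is self-describing.
    """

    intercept: float = 2.44
    male: float = -1.55
    asphyxia: float = -1.95
    age: float = -0.0191
    log2_potassium: float = -2.07
    log2_cpr: float = -0.573
    temperature: float = 0.937
    temperature_squared: float = -0.0247

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def temperature_vertex(self) -> float:
        """Temperature (deg C) at which the quadratic log-odds term peaks."""
        return -self.temperature / (2.0 * self.temperature_squared)


DEFAULT_COEFFICIENTS = ScoreCoefficients()

#: Covariate ranges observed across the score's validation cohorts.
#: Values outside these ranges are extrapolations and are flagged.
OBSERVED_RANGES: dict[str, tuple[float, float]] = {
    "age": (1.0, 95.0),
    "temperature": (13.5, 28.9),
    "potassium": (2.4, 16.1),
    "cpr_duration": (20.0, 307.0),
}

#: Core temperature above which cardiac arrest is unlikely to be
#: hypothermia-induced; study cohorts exclude such patients.
HYPOTHERMIC_CA_TEMPERATURE_LIMIT = 32.0

PEDIATRIC_AGE_LIMIT = 18.0


class MissingCovariateError(ValueError):
    """A required HOPE covariate is absent from the record."""

    def __init__(self, record_id: str, missing: Sequence[str]):
        self.record_id = record_id
        self.missing = tuple(missing)
        super().__init__(
            f"record {record_id!r} is missing required covariate(s): "
            + ", ".join(missing)
        )


@dataclass(frozen=True)
class HopeResult:
    """Linear score (log-odds of survival) and survival probability."""

    score: float
    probability: float
    warnings: tuple[str, ...] = ()
    record_id: str = ""

    def percent(self, decimals: int = 1) -> str:
        """Display-rounded percent string; internal precision is unaffected."""
        return format_probability(self.probability, decimals)


def logit_to_probability(score: float) -> float:
    """Logistic transform exp(s)/(1+exp(s)), numerically stable."""
    return float(expit(score))


def probability_to_logit(probability: float) -> float:
    """Inverse of :func:`logit_to_probability` on (0, 1)."""
    if not 0.0 < probability < 1.0:
        raise ValueError(f"probability must lie strictly in (0, 1), got {probability}")
    return float(_logit(probability))


def format_probability(probability: float, decimals: int = 1) -> str:
    """Percent string rounded half away from zero to ``decimals`` places."""
    if decimals not in (0, 1, 2):
        raise ValueError("decimals must be 0, 1 or 2")
    scaled = probability * 100.0 * 10**decimals
    rounded = math.floor(scaled + 0.5)  # half away from zero (values are >= 0)
    value = rounded / 10**decimals
    return f"{value:.{decimals}f}%" if decimals else f"{int(value)}%"


_REQUIRED = ("age", "sex", "asphyxia", "temperature", "potassium", "cpr_duration")


def compute_score(
    record: PatientRecord,
    coefficients: ScoreCoefficients = DEFAULT_COEFFICIENTS,
) -> HopeResult:
    """Evaluate the HOPE score and survival probability for one patient.

    Logarithms are base 2, exactly as in the published equation.  Missing
    covariates raise :class:`MissingCovariateError`; out-of-range values,
    temperatures above 32 degrees C and paediatric ages are scored but
    annotated in ``HopeResult.warnings``.

    Examples
    --------
    >>> from hopescore import PatientRecord, compute_score
    >>> boy = PatientRecord(id="case", age=6, sex="male", mechanism="submersion",
    ...                     temperature=17.0, potassium=7.6, cpr_duration=95)
    >>> round(compute_score(boy).probability, 4)
    0.0993
    """
    missing = [name for name in _REQUIRED if getattr(record, name) is None]
    if missing:
        raise MissingCovariateError(record.id, missing)

    c = coefficients
    male = 1.0 if record.sex is Sex.MALE else 0.0
    asphyxia = 1.0 if record.asphyxia else 0.0
    score = (
        c.intercept
        + c.male * male
        + c.asphyxia * asphyxia
        + c.age * record.age
        + c.log2_potassium * math.log2(record.potassium)
        + c.log2_cpr * math.log2(record.cpr_duration)
        + c.temperature * record.temperature
        + c.temperature_squared * record.temperature**2
    )

    notes: list[str] = []
    if record.temperature > HYPOTHERMIC_CA_TEMPERATURE_LIMIT:
        notes.append(
            f"temperature {record.temperature} degC exceeds the 32 degC limit for "
            "hypothermic cardiac arrest; the score is not validated here and "
            "study cohorts exclude such patients"
        )
    for name, (lo, hi) in OBSERVED_RANGES.items():
        value = getattr(record, name)
        if not lo <= value <= hi:
            notes.append(
                f"{name} {value} outside the range {lo}-{hi} observed in "
                "validation cohorts; the score extrapolates"
            )
    if record.age < PEDIATRIC_AGE_LIMIT:
        notes.append(
            "paediatric patient: guidelines recommend expert consultation "
            "rather than the HOPE score to guide rewarming decisions in children"
        )

    return HopeResult(
        score=float(score),
        probability=logit_to_probability(score),
        warnings=tuple(notes),
        record_id=record.id,
    )


@dataclass(frozen=True)
class BatchFailure:
    record_id: str
    index: int
    error: str


@dataclass(frozen=True)
class BatchResult:
    """Order-preserving batch scores with fail-soft error collection.

    ``results[i]`` is the :class:`HopeResult` for the i-th input record, or
    ``None`` if that record could not be scored; every failure appears in
    ``failures`` with the record id and position.
    """

    results: tuple[HopeResult | None, ...]
    failures: tuple[BatchFailure, ...] = ()

    def probabilities(self) -> list[float | None]:
        return [r.probability if r is not None else None for r in self.results]

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)


def score_batch(
    records: Iterable[PatientRecord],
    coefficients: ScoreCoefficients = DEFAULT_COEFFICIENTS,
) -> BatchResult:
    """Score a sequence of records, preserving order.

    Records that fail validation are reported in ``failures`` with their
    ids; valid records are still scored.  An empty input yields an empty
    result and a ``UserWarning``.
    """
    results: list[HopeResult | None] = []
    failures: list[BatchFailure] = []
    for i, record in enumerate(records):
        try:
            results.append(compute_score(record, coefficients))
        except (ValueError, TypeError) as exc:
            results.append(None)
            failures.append(BatchFailure(record.id, i, str(exc)))
    if not results:
        _warnings.warn("score_batch received an empty cohort", stacklevel=2)
    return BatchResult(tuple(results), tuple(failures))
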