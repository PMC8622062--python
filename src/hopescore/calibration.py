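"""Calibration-in-the-large and scenario sensitivity for the HOPE score.

A score can rank patients well (high AUC) and still be miscalibrated:
when case selection depends on the outcome — as it does for patients
assembled from published case reports, where deaths are under-reported —
the observed survival rate drifts far above the mean predicted
probability while within-class ranking is untouched.  The measure
implemented here, calibration-in-the-large, is exactly that comparison:
mean predicted probability versus observed event rate.

The module also provides the asphyxia scenario analysis used at the
bedside when the mechanism is uncertain (immersion versus submersion):
the two scenario probabilities differ by exactly the 1.95 asphyxia
coefficient on the log-odds scale, and the recommendation when in doubt
is the variant giving the patient the higher survival probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .diagnostics import _as_binary_outcomes
from .records import PatientRecord
from .scoring import (
    DEFAULT_COEFFICIENTS,
    ScoreCoefficients,
    compute_score,
    logit_to_probability,
    probability_to_logit,
)

__all__ = [
    "CalibrationSummary",
    "ScenarioPair",
    "calibration_in_the_large",
    "asphyxia_sensitivity",
    "logistic_recalibration",
]


@dataclass(frozen=True)
class CalibrationSummary:
    """Mean predicted probability against the observed survival rate.

    ``gap`` is observed minus predicted: positive when more patients
    survive than the score expects (the signature of survivor-enriched
    selection).  ``comparison_p`` is a two-sided Mann-Whitney test of the
    predicted-probability distributions of survivors versus
    non-survivors; it is ``None`` when either class is absent.
    """

    n: int
    mean_predicted: float
    observed_rate: float
    gap: float
    group_means: dict[str, float | None]
    range: tuple[float, float]
    comparison_p: float | None
    gap_ci: tuple[float, float] | None = None
    n_missing_outcome: int = 0


def calibration_in_the_large(
    probabilities,
    outcomes,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> CalibrationSummary:
    """Compare mean predicted survival with the observed rate.

    Records with unknown outcomes are excluded (and tallied).  The gap's
    interval is a seeded nonparametric bootstrap over patients
    (``n_bootstrap`` resamples; pass 0 to skip it).

    Raises
    ------
    ValueError
        If no record has a known outcome.
    """
    p = np.asarray(probabilities, dtype=float)
    y = _as_binary_outcomes(outcomes)
    if p.shape != y.shape:
        raise ValueError(
            f"length mismatch: {p.size} probabilities vs {y.size} outcomes"
        )
    known = y >= 0
    n_missing = int(np.sum(~known))
    p, y = p[known], y[known]
    if p.size == 0:
        raise ValueError("calibration requires at least one record with a known outcome")

    surv_p = p[y == 1]
    died_p = p[y == 0]
    mean_pred = float(np.mean(p))
    observed = float(np.mean(y))
    group_means = {
        "survived": float(np.mean(surv_p)) if surv_p.size else None,
        "died": float(np.mean(died_p)) if died_p.size else None,
    }
    if surv_p.size and died_p.size:
        comparison_p = float(
            mannwhitneyu(surv_p, died_p, alternative="two-sided", use_continuity=True).pvalue
        )
    else:
        comparison_p = None

    gap_ci = None
    if n_bootstrap and p.size > 1:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, p.size, size=(n_bootstrap, p.size))
        gaps = np.mean(y[idx], axis=1) - np.mean(p[idx], axis=1)
        lo, hi = np.quantile(gaps, [0.025, 0.975])
        gap_ci = (float(lo), float(hi))

    return CalibrationSummary(
        n=int(p.size),
        mean_predicted=mean_pred,
        observed_rate=observed,
        gap=observed - mean_pred,
        group_means=group_means,
        range=(float(np.min(p)), float(np.max(p))),
        comparison_p=comparison_p,
        gap_ci=gap_ci,
        n_missing_outcome=n_missing,
    )


@dataclass(frozen=True)
class ScenarioPair:
    """Survival probabilities under the two mechanism scenarios.

    When the events are unclear (e.g. immersion versus submersion in
    water), the favourable non-asphyxial variant is the recommended
    when-in-doubt choice: pick the scenario giving the patient the
    highest survival probability.
    """

    probability_asphyxia: float
    probability_non_asphyxia: float
    recommended: str = "non_asphyxia"

    @property
    def logit_shift(self) -> float:
        return probability_to_logit(self.probability_non_asphyxia) - probability_to_logit(
            self.probability_asphyxia
        )


def asphyxia_sensitivity(
    record: PatientRecord,
    coefficients: ScoreCoefficients = DEFAULT_COEFFICIENTS,
) -> ScenarioPair:
    """Score a patient under both asphyxial and non-asphyxial scenarios.

    The two logits differ by exactly the asphyxia coefficient (1.95 with
    the published constants); e.g. a 16% submersion-scenario probability
    corresponds to 57% under immersion.
    """
    asphyxial = compute_score(record.with_asphyxia(True), coefficients)
    non_asphyxial = compute_score(record.with_asphyxia(False), coefficients)
    return ScenarioPair(
        probability_asphyxia=asphyxial.probability,
        probability_non_asphyxia=non_asphyxial.probability,
    )


def shift_probability(probability: float, logit_shift: float) -> float:
    """Apply a log-odds shift to a probability (inverse-logit of logit+shift)."""
    return logit_to_probability(probability_to_logit(probability) + logit_shift)


def logistic_recalibration(probabilities, outcomes):
    """Calibration slope and intercept by logistic recalibration (extension).

    Fits ``outcome ~ a + b * logit(p)`` by maximum likelihood; perfect
    calibration gives (a, b) = (0, 1).  This goes beyond
    calibration-in-the-large and is off by default in the pipeline
    reports; it is provided for users who want the slope diagnostic.
    Returns ``(intercept, slope)``.
    """
    import statsmodels.api as sm

    p = np.asarray(probabilities, dtype=float)
    y = _as_binary_outcomes(outcomes)
    known = y >= 0
    p, y = p[known], y[known]
    if len(np.unique(y)) < 2:
        raise ValueError("recalibration requires both outcome classes")
    lp = np.array([probability_to_logit(v) for v in p])
    model = sm.Logit(y, sm.add_constant(lp)).fit(disp=0)
    return float(model.params[0]), float(model.params[1])
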