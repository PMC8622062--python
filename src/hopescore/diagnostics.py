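"""Threshold-based triage diagnostics and ROC discrimination.

A survival probability of at least 10% is the suggested criterion to
initiate ECLS rewarming: patients at or above the threshold are treated
as predicted survivors ("positive").  This module provides the confusion
accounting for that rule, the six standard diagnostic proportions with
Wilson score intervals, and the area under the ROC curve with a DeLong
confidence interval.

Conventions
-----------
* The threshold comparison is inclusive (``probability >= threshold``)
  and always on unrounded probabilities.
* A *false positive* is a non-survivor who met the rewarming criterion
  (futile rewarming); a *false negative* is a survivor who did not.
* Metrics with a zero denominator are reported as undefined, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata, norm
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from .records import Outcome

__all__ = [
    "ConfusionTable",
    "Proportion",
    "DiagnosticReport",
    "RocResult",
    "REWARMING_THRESHOLD",
    "classify",
    "confusion",
    "wilson_interval",
    "diagnostic_report",
    "roc_auc",
]

#: Survival-probability threshold suggested for the decision to rewarm.
REWARMING_THRESHOLD = 0.10


def classify(probability: float, threshold: float = REWARMING_THRESHOLD) -> bool:
    """True ("positive": rewarm, predicted survivor) iff p >= threshold.

    The comparison is on unrounded values: 0.0992 is negative at a 10%
    threshold even though it displays as 9.9% or 10%.
    """
    if not 0.0 <= probability <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {probability}")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return probability >= threshold


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts at a threshold.  Positive = predicted survivor.

    ``tp`` survivors correctly flagged, ``fn`` survivors missed,
    ``fp`` non-survivors flagged (futile rewarming), ``tn`` non-survivors
    correctly excluded.  ``n_missing_outcome`` records were dropped from
    the table for lack of a known outcome.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float = REWARMING_THRESHOLD
    n_missing_outcome: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn", "n_missing_outcome"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_binary_outcomes(outcomes: Iterable) -> np.ndarray:
    """Map outcomes to 1 (survived), 0 (died), -1 (unknown)."""
    coded = []
    for o in outcomes:
        if o is None or (isinstance(o, float) and math.isnan(o)):
            coded.append(-1)
        elif isinstance(o, Outcome):
            coded.append(1 if o is Outcome.SURVIVED else 0)
        elif isinstance(o, str):
            coded.append(1 if Outcome(o) is Outcome.SURVIVED else 0)
        elif o in (0, 1, True, False):
            coded.append(int(o))
        else:
            raise ValueError(f"cannot interpret outcome {o!r}")
    return np.asarray(coded, dtype=int)


def confusion(
    probabilities: Sequence[float],
    outcomes: Sequence,
    threshold: float = REWARMING_THRESHOLD,
) -> ConfusionTable:
    """Count the 2x2 table for the inclusive >= threshold rule.

    ``outcomes`` may be :class:`Outcome` values, "survived"/"died"
    strings, 0/1, or ``None``/NaN for unknown; unknown-outcome records
    are excluded from the counts and tallied in ``n_missing_outcome``.
    """
    p = np.asarray(probabilities, dtype=float)
    y = _as_binary_outcomes(outcomes)
    if p.shape != y.shape:
        raise ValueError(
            f"length mismatch: {p.size} probabilities vs {y.size} outcomes"
        )
    known = y >= 0
    pos = p[known] >= threshold
    surv = y[known] == 1
    return ConfusionTable(
        tp=int(np.sum(pos & surv)),
        fp=int(np.sum(pos & ~surv)),
        tn=int(np.sum(~pos & ~surv)),
        fn=int(np.sum(~pos & surv)),
        threshold=threshold,
        n_missing_outcome=int(np.sum(~known)),
    )


def wilson_interval(
    successes: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Preferred over the Wald interval at small n and extreme proportions;
    the lower bound is exactly 0 when ``successes == 0`` and the upper
    bound exactly 1 when ``successes == n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must lie in [0, {n}], got {successes}")
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must lie in (0, 1), got {confidence}")
    low, high = proportion_confint(successes, n, alpha=1.0 - confidence, method="wilson")
    # the closed form gives exactly 0 (resp. 1) at the boundary counts;
    # clamp the floating-point evaluation so the guarantee holds
    low = 0.0 if successes == 0 else min(max(float(low), 0.0), 1.0)
    high = 1.0 if successes == n else min(max(float(high), 0.0), 1.0)
    return low, high


@dataclass(frozen=True)
class Proportion:
    """A diagnostic proportion with its Wilson interval.

    ``value`` and the interval are ``None`` when the denominator is zero
    (the metric is undefined, which is reported as such).
    """

    name: str
    numerator: int
    denominator: int
    value: float | None
    ci_low: float | None
    ci_high: float | None

    @property
    def defined(self) -> bool:
        return self.value is not None

    def display(self) -> str:
        """Human layout, e.g. ``61/62 = 98% (91-100%)``."""
        if not self.defined:
            return f"{self.numerator}/{self.denominator} = undefined"
        pct = _round_half_away(self.value * 100.0)
        lo = _round_half_away(self.ci_low * 100.0)
        hi = _round_half_away(self.ci_high * 100.0)
        return f"{self.numerator}/{self.denominator} = {pct}% ({lo}-{hi}%)"


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _proportion(name: str, k: int, n: int, confidence: float) -> Proportion:
    if n == 0:
        return Proportion(name, k, n, None, None, None)
    low, high = wilson_interval(k, n, confidence)
    return Proportion(name, k, n, k / n, low, high)


@dataclass(frozen=True)
class DiagnosticReport:
    """The six proportions behind a threshold-performance table.

    Sensitivity is the probability that the criterion is met among
    survivors; specificity that it is not met among non-survivors; PPV
    the survival proportion among criterion-positive patients; NPV the
    death proportion among criterion-negative patients.  The false
    positive and false negative fractions are computed over all patients.
    """

    table: ConfusionTable
    confidence: float
    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion
    fp_fraction: Proportion
    fn_fraction: Proportion

    def metrics(self) -> tuple[Proportion, ...]:
        return (
            self.sensitivity,
            self.specificity,
            self.ppv,
            self.npv,
            self.fp_fraction,
            self.fn_fraction,
        )

    def correct_decision_fraction(self) -> Proportion:
        """(tp + tn) / total: overall fraction of correct triage decisions."""
        t = self.table
        return _proportion("correct", t.tp + t.tn, t.total, self.confidence)


def diagnostic_report(
    table: ConfusionTable, confidence: float = 0.95
) -> DiagnosticReport:
    """Compute the six diagnostic proportions with Wilson intervals."""
    t = table
    return DiagnosticReport(
        table=t,
        confidence=confidence,
        sensitivity=_proportion("sensitivity", t.tp, t.tp + t.fn, confidence),
        specificity=_proportion("specificity", t.tn, t.tn + t.fp, confidence),
        ppv=_proportion("ppv", t.tp, t.tp + t.fp, confidence),
        npv=_proportion("npv", t.tn, t.tn + t.fn, confidence),
        fp_fraction=_proportion("fp_fraction", t.fp, t.total, confidence),
        fn_fraction=_proportion("fn_fraction", t.fn, t.total, confidence),
    )


@dataclass(frozen=True)
class RocResult:
    """AUC with a 95% interval and the full ROC curve.

    ``auc`` is the Mann-Whitney concordance probability: the chance that
    a random survivor received a higher predicted probability than a
    random non-survivor, ties counting one half.  ``curve`` is the
    sequence of (false-positive rate, true-positive rate) points over all
    distinct thresholds, from (0, 0) to (1, 1).
    """

    auc: float
    ci_low: float
    ci_high: float
    curve: tuple[tuple[float, float], ...]
    confidence: float = 0.95
    ci_method: str = "delong"
    n_survivors: int = 0
    n_non_survivors: int = 0


def _midrank_placements(pos: np.ndarray, neg: np.ndarray):
    """DeLong placement values via midranks (Sun & Xu algorithm).

    Returns (auc, V10, V01) where V10[i] is the placement of survivor i
    among non-survivors and vice versa; their means both equal the AUC.
    """
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    r_all = rankdata(combined)  # midranks
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = float(np.mean(v10))
    return auc, v10, v01


def _delong_ci(
    v10: np.ndarray, v01: np.ndarray, auc: float, confidence: float
) -> tuple[float, float]:
    s10 = np.var(v10, ddof=1)
    s01 = np.var(v01, ddof=1)
    var = s10 / len(v10) + s01 / len(v01)
    z = norm.ppf(0.5 + confidence / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


def _bootstrap_ci(
    pos: np.ndarray,
    neg: np.ndarray,
    confidence: float,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified bootstrap of the AUC (fallback when a class has < 2 members)."""
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        aucs[b], _, _ = _midrank_placements(bp, bn)
    alpha = 1.0 - confidence
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def roc_auc(
    probabilities: Sequence[float],
    outcomes: Sequence,
    confidence: float = 0.95,
    seed: int = 0,
) -> RocResult:
    """Discrimination of predicted probabilities against observed outcomes.

    The AUC is the Mann-Whitney concordance probability with ties counted
    one half; its confidence interval uses the DeLong method, falling back
    to a stratified bootstrap (2000 resamples, seeded) when either outcome
    class has fewer than two members.  Records with unknown outcomes are
    excluded.

    Raises
    ------
    ValueError
        If only one outcome class is present (naming the missing one).
    """
    p = np.asarray(probabilities, dtype=float)
    y = _as_binary_outcomes(outcomes)
    if p.shape != y.shape:
        raise ValueError(
            f"length mismatch: {p.size} probabilities vs {y.size} outcomes"
        )
    p, y = p[y >= 0], y[y >= 0]
    pos, neg = p[y == 1], p[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        missing = "survivors" if len(pos) == 0 else "non-survivors"
        raise ValueError(f"cannot compute discrimination: no {missing} in the data")

    auc, v10, v01 = _midrank_placements(pos, neg)
    if min(len(pos), len(neg)) >= 2:
        ci_low, ci_high = _delong_ci(v10, v01, auc, confidence)
        method = "delong"
    else:
        ci_low, ci_high = _bootstrap_ci(pos, neg, confidence, seed=seed)
        method = "bootstrap(degenerate: a class has a single member)"

    fpr, tpr, _ = _sk_roc_curve(y, p, drop_intermediate=False)
    curve = tuple(zip(fpr.tolist(), tpr.tolist()))

    return RocResult(
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        curve=curve,
        confidence=confidence,
        ci_method=method,
        n_survivors=len(pos),
        n_non_survivors=len(neg),
    )
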