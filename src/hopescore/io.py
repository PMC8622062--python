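"""Cohort readers/writers, published reference values, and descriptive summaries.

The canonical interchange format is a UTF-8 delimited text table (comma
by default) with header columns ``id, age, sex, mechanism, temperature_c,
potassium_mmol_l, cpr_min, outcome, cpc``; sex, mechanism and outcome are
lowercase tokens and missing values are empty fields.  Column order is
free, unknown columns are preserved as passthrough, and row-level
validation failures are collected with their line numbers rather than
aborting the load.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact, mannwhitneyu

from .diagnostics import ConfusionTable
from .records import Mechanism, Outcome, PatientRecord, Sex
from .scoring import BatchResult, ScoreCoefficients

__all__ = [
    "CANONICAL_COLUMNS",
    "PEDIATRIC_SUBMERSION_CASE",
    "NON_SURVIVOR_PROBABILITIES",
    "CASE_REPORT_COUNTS",
    "RowError",
    "CohortReadResult",
    "read_cohort",
    "write_cohort",
    "write_scored_cohort",
    "run_metadata",
    "CohortSummary",
    "summarize_cohort",
]

CANONICAL_COLUMNS = (
    "id",
    "age",
    "sex",
    "mechanism",
    "temperature_c",
    "potassium_mmol_l",
    "cpr_min",
    "outcome",
    "cpc",
)
_MANDATORY = ("age", "sex", "temperature_c", "potassium_mmol_l", "cpr_min")

# ---------------------------------------------------------------------------
# Published reference values used throughout the tests and examples.
# These are fixed facts from the HOPE case-report validation literature
# and must stay byte-identical across releases.

#: The published false-negative case: a 6-year-old boy submerged in water,
#: core temperature 17 degC, potassium 7.6 mmol/L, 95 min of CPR before
#: cardiopulmonary bypass; he survived with full recovery despite a HOPE
#: survival probability just under the 10% rewarming threshold.
PEDIATRIC_SUBMERSION_CASE = PatientRecord(
    id="pediatric-submersion",
    age=6.0,
    sex=Sex.MALE,
    mechanism=Mechanism.SUBMERSION,
    temperature=17.0,
    potassium=7.6,
    cpr_duration=95.0,
    outcome=Outcome.SURVIVED,
    cpc=1,
)

#: HOPE survival probabilities of the eight non-survivors in the published
#: 70-patient case-report cohort (fractions, not percent).
NON_SURVIVOR_PROBABILITIES = (0.007, 0.034, 0.036, 0.147, 0.336, 0.439, 0.553, 0.814)

#: Confusion counts of the >=10% rewarming rule in that cohort:
#: 61 of 62 survivors above threshold, 5 of 8 non-survivors above.
CASE_REPORT_COUNTS = ConfusionTable(tp=61, fp=5, tn=3, fn=1, threshold=0.10)


# ---------------------------------------------------------------------------
# Reading and writing


@dataclass(frozen=True)
class RowError:
    line: int  # 1-based line number in the file, header = line 1
    record_id: str
    error: str


@dataclass(frozen=True)
class CohortReadResult:
    records: list[PatientRecord]
    errors: list[RowError]

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return str(value).strip().lower()


def read_cohort(path: str | Path, delimiter: str = ",") -> CohortReadResult:
    """Load a cohort table, collecting row-level errors instead of failing.

    Raises
    ------
    ValueError
        If any mandatory column (age, sex, temperature_c,
        potassium_mmol_l, cpr_min) is absent, listing the missing ones.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    extra_cols = [c for c in df.columns if c not in CANONICAL_COLUMNS]

    records: list[PatientRecord] = []
    errors: list[RowError] = []
    for i, row in df.iterrows():
        line = int(i) + 2  # header occupies line 1
        rid = str(row["id"]) if "id" in df.columns and row["id"] != "" else f"row-{line}"
        try:
            cpc_raw = _opt_float(row["cpc"]) if "cpc" in df.columns else None
            records.append(
                PatientRecord(
                    id=rid,
                    age=_opt_float(row["age"]),
                    sex=_opt_str(row["sex"]),
                    mechanism=_opt_str(row["mechanism"]) if "mechanism" in df.columns else None,
                    temperature=_opt_float(row["temperature_c"]),
                    potassium=_opt_float(row["potassium_mmol_l"]),
                    cpr_duration=_opt_float(row["cpr_min"]),
                    outcome=_opt_str(row["outcome"]) if "outcome" in df.columns else None,
                    cpc=int(cpc_raw) if cpc_raw is not None else None,
                    extra={c: row[c] for c in extra_cols},
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(RowError(line=line, record_id=rid, error=str(exc)))
    return CohortReadResult(records, errors)


def _records_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "age": r.age,
            "sex": r.sex.value if r.sex else "",
            "mechanism": r.mechanism.value if r.mechanism else "",
            "temperature_c": r.temperature,
            "potassium_mmol_l": r.potassium,
            "cpr_min": r.cpr_duration,
            "outcome": r.outcome.value if r.outcome else "",
            "cpc": r.cpc if r.cpc is not None else "",
        }
        row.update(r.extra)
        rows.append(row)
    return pd.DataFrame(rows, columns=None if not rows else list(rows[0]))


def write_cohort(records: Sequence[PatientRecord], path: str | Path, delimiter: str = ",") -> None:
    """Write records in the canonical delimited layout (lossless round trip)."""
    df = _records_frame(records)
    if df.empty:
        df = pd.DataFrame(columns=list(CANONICAL_COLUMNS))
    df.to_csv(path, sep=delimiter, index=False)


def write_scored_cohort(
    records: Sequence[PatientRecord],
    batch: BatchResult,
    path: str | Path,
    delimiter: str = ",",
    metadata: dict | None = None,
) -> None:
    """Write the cohort plus hope_score / hope_probability / warnings columns.

    Probabilities are serialised at full precision; display rounding is
    confined to human-facing report fields.  If ``metadata`` is given it
    is written next to the table as ``<path>.meta.json``.
    """
    if len(records) != len(batch.results):
        raise ValueError("records and batch results differ in length")
    df = _records_frame(records)
    if df.empty:
        df = pd.DataFrame(columns=list(CANONICAL_COLUMNS))
    df["hope_score"] = [r.score if r else "" for r in batch.results]
    df["hope_probability"] = [repr(r.probability) if r else "" for r in batch.results]
    df["warnings"] = ["; ".join(r.warnings) if r else "unscored" for r in batch.results]
    df.to_csv(path, sep=delimiter, index=False)
    if metadata is not None:
        Path(str(path) + ".meta.json").write_text(json.dumps(metadata, indent=2))


def run_metadata(
    coefficients: ScoreCoefficients,
    seed: int | None = None,
    threshold: float | None = None,
    **extra,
) -> dict:
    """Machine-readable provenance block emitted with every pipeline run."""
    from . import __version__

    meta = {
        "software": "hopescore",
        "version": __version__,
        "coefficients": coefficients.as_dict(),
    }
    if seed is not None:
        meta["seed"] = seed
    if threshold is not None:
        meta["threshold"] = threshold
    meta.update(extra)
    return meta


# ---------------------------------------------------------------------------
# Descriptive summaries


@dataclass(frozen=True)
class CohortSummary:
    """Characteristics-table-shaped summary of a cohort.

    Continuous covariates get median and range overall and per outcome
    group with a Mann-Whitney comparison; categorical covariates get
    counts and percentages with an exact (2x2 Fisher) or chi-squared
    (larger tables) comparison.  Comparison p-values are ``None`` when
    either outcome group is absent.
    """

    n: int
    n_survivors: int | None
    n_non_survivors: int | None
    continuous: pd.DataFrame
    categorical: pd.DataFrame


_CONTINUOUS = {
    "age": "age",
    "temperature": "temperature",
    "potassium": "potassium",
    "cpr_duration": "cpr_duration",
}
_CATEGORICAL = {
    "sex": lambda r: r.sex.value if r.sex else None,
    "mechanism": lambda r: r.mechanism.value if r.mechanism else None,
    "asphyxia": lambda r: {True: "yes", False: "no"}.get(r.asphyxia),
}


def summarize_cohort(records: Sequence[PatientRecord]) -> CohortSummary:
    """Build a descriptive summary with survivor/non-survivor comparisons."""
    if not records:
        raise ValueError("cannot summarise an empty cohort")

    outcome = np.array(
        [
            1 if r.outcome is Outcome.SURVIVED else (0 if r.outcome is Outcome.DIED else -1)
            for r in records
        ]
    )
    has_groups = bool(np.any(outcome == 1) and np.any(outcome == 0))

    cont_rows = []
    for label, attr in _CONTINUOUS.items():
        values = np.array([getattr(r, attr) if getattr(r, attr) is not None else np.nan for r in records])
        ok = ~np.isnan(values)
        row = {
            "variable": label,
            "median": float(np.median(values[ok])) if ok.any() else None,
            "min": float(np.min(values[ok])) if ok.any() else None,
            "max": float(np.max(values[ok])) if ok.any() else None,
        }
        for name, code in (("survivors", 1), ("non_survivors", 0)):
            sel = ok & (outcome == code)
            row[f"median_{name}"] = float(np.median(values[sel])) if sel.any() else None
        if has_groups and (ok & (outcome == 1)).any() and (ok & (outcome == 0)).any():
            row["p_value"] = float(
                mannwhitneyu(
                    values[ok & (outcome == 1)],
                    values[ok & (outcome == 0)],
                    alternative="two-sided",
                ).pvalue
            )
        else:
            row["p_value"] = None
        cont_rows.append(row)

    cat_rows = []
    for label, getter in _CATEGORICAL.items():
        levels_all = [getter(r) for r in records]
        levels = sorted({v for v in levels_all if v is not None})
        counts = {lv: levels_all.count(lv) for lv in levels}
        total = sum(counts.values())
        p_value = None
        if has_groups and len(levels) >= 2:
            table = np.array(
                [
                    [
                        sum(
                            1
                            for r, lv in zip(records, levels_all)
                            if lv == level and r.outcome is Outcome.SURVIVED
                        ),
                        sum(
                            1
                            for r, lv in zip(records, levels_all)
                            if lv == level and r.outcome is Outcome.DIED
                        ),
                    ]
                    for level in levels
                ]
            )
            if table.sum() > 0 and np.all(table.sum(axis=1) >= 0):
                if table.shape == (2, 2):
                    p_value = float(fisher_exact(table)[1])
                else:
                    # exact tests beyond 2x2 are not provided by the stack;
                    # chi-squared is the descriptive fallback
                    nonzero = table[table.sum(axis=1) > 0]
                    if nonzero.shape[0] >= 2 and np.all(nonzero.sum(axis=0) > 0):
                        p_value = float(chi2_contingency(nonzero)[1])
        for level in levels:
            cat_rows.append(
                {
                    "variable": label,
                    "level": level,
                    "count": counts[level],
                    "percent": 100.0 * counts[level] / total if total else None,
                    "count_survivors": sum(
                        1
                        for r, lv in zip(records, levels_all)
                        if lv == level and r.outcome is Outcome.SURVIVED
                    ),
                    "count_non_survivors": sum(
                        1
                        for r, lv in zip(records, levels_all)
                        if lv == level and r.outcome is Outcome.DIED
                    ),
                    "p_value": p_value,
                }
            )

    return CohortSummary(
        n=len(records),
        n_survivors=int(np.sum(outcome == 1)) if has_groups or np.any(outcome >= 0) else None,
        n_non_survivors=int(np.sum(outcome == 0)) if has_groups or np.any(outcome >= 0) else None,
        continuous=pd.DataFrame(cont_rows),
        categorical=pd.DataFrame(cat_rows),
    )
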