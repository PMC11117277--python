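"""Descriptive summaries and exploratory contingency tests.

Exploratory two-group comparisons use the Pearson chi-squared test with Yates
continuity correction on one degree of freedom (the correction term is
clamped so the statistic is never negative). Descriptive tables report
count (%) for categoricals and mean (SD) or median [IQR] for continuous
variables, by exposure arm and overall, with missing values as a category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UndefinedTestError

__all__ = [
    "TwoByTwo",
    "chi_squared_test",
    "describe_cohort",
    "antibiotic_frequency_table",
    "percentage",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwoByTwo:
    """Counts (exposed-event, exposed-no-event, unexposed-event,
    unexposed-no-event)."""
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def chi_squared_test(table: TwoByTwo, correction: bool = True) -> tuple[float, float]:
    """Pearson chi-squared on 1 df, Yates-corrected by default.

    Raises :class:`UndefinedTestError` on a zero margin (consider an exact
    test there instead).
    """
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise UndefinedTestError(
            "a table margin is zero; the chi-squared test is undefined -- "
            "consider Fisher's exact test")
    res = stats.chi2_contingency(obs, correction=correction)
    return float(res.statistic), float(res.pvalue)


def percentage(k: int, n: int) -> float:
    """Crude proportion as a percentage (1-decimal display convention is
    applied by the caller)."""
    return 100.0 * k / n


_CATEGORICAL = [
    "male", "adl_dependent", "low_exercise_tolerance", "immunodeficiency",
    "prior_antibiotics_90d", "source_hospital_nursing", "abnormal_mental_status",
    "low_albumin", "oxygen_use", "dialysis", "residence_healthcare_facility",
    "mdr_risk",
]


def _fmt_count(k, n):
    return f"{int(k)} ({percentage(k, n):.1f})"


def describe_cohort(rows: pd.DataFrame) -> pd.DataFrame:
    """Patient-characteristics table by exposure arm and overall.

    Continuous age as mean (SD) -- SD blank for a single observation;
    categoricals as count (%) with missing reported as its own category;
    90-day outcome status (alive / event / censored) per cause.
    """
    arms = {
        "anti_pseudomonal": rows[rows["exposure"] == 1],
        "non_anti_pseudomonal": rows[rows["exposure"] == 0],
        "overall": rows,
    }
    out = []

    def add(variable, level, fmt):
        out.append({"variable": variable, "level": level,
                    **{arm: fmt(df) for arm, df in arms.items()}})

    def mean_sd(df):
        x = df["age"].dropna()
        if len(x) == 0:
            return ""
        if len(x) == 1:
            return f"{x.mean():.1f} ()"
        return f"{x.mean():.1f} ({x.std(ddof=1):.1f})"

    add("age", "mean (SD)", mean_sd)
    for var in _CATEGORICAL:
        if var not in rows.columns:
            continue
        add(var, "yes", lambda df, v=var: _fmt_count((df[v] == 1).sum(), len(df)) if len(df) else "")
        n_missing = rows[var].isna().sum()
        if n_missing:
            add(var, "missing",
                lambda df, v=var: _fmt_count(df[v].isna().sum(), len(df)) if len(df) else "")
    if "bun_category" in rows.columns:
        for level in ["<14", "14-<22.4", ">=22.4"]:
            add("bun_category", level,
                lambda df, lv=level: _fmt_count((df["bun_category"] == lv).sum(), len(df)) if len(df) else "")
        if rows["bun_category"].isna().sum():
            add("bun_category", "missing",
                lambda df: _fmt_count(df["bun_category"].isna().sum(), len(df)) if len(df) else "")
    for cause, labels in (("death", ("alive", "death", "censored")),
                          ("surgery", ("no thoracic surgery", "thoracic surgery", "censored"))):
        tcol, ecol = f"time_{cause}", f"event_{cause}"
        horizon = 90

        def status(df, which, tcol=tcol, ecol=ecol):
            if not len(df):
                return ""
            event = df[ecol] == 1
            full = (df[ecol] == 0) & (df[tcol] >= horizon)
            cens = (df[ecol] == 0) & (df[tcol] < horizon)
            k = {0: full.sum(), 1: event.sum(), 2: cens.sum()}[which]
            return _fmt_count(k, len(df))

        for which, lab in enumerate(labels):
            add(f"{cause}_within_90d", lab, lambda df, w=which, s=status: s(df, w))
    return pd.DataFrame(out).set_index(["variable", "level"])


def antibiotic_frequency_table(records, drug_dict) -> pd.DataFrame:
    """Per-agent counts among day-0/1 intravenous antibiotics, by exposure
    class.

    A patient contributes to every agent received, so percentages within a
    class may exceed 100. Denominators are the classified arm sizes. Unknown
    drug codes are logged and bucketed as 'other_antibiotics'.
    """
    from .cohort import classify_exposure

    counts: dict[tuple[str, str], int] = {}
    arm_sizes = {"anti_pseudomonal": 0, "non_anti_pseudomonal": 0}
    for rec in records:
        arm = classify_exposure(rec, drug_dict)
        arm_sizes[arm] += 1
        seen = set()
        for code, day in rec.drug_events:
            if day not in (0, 1):
                continue
            klass = drug_dict.get(code)
            if klass in ("vasopressor", "other"):
                continue
            if klass is None:
                log.warning("unknown drug code %r bucketed as other_antibiotics", code)
                code = "other_antibiotics"
            if code in seen:
                continue
            seen.add(code)
            counts[(arm, code)] = counts.get((arm, code), 0) + 1
    out = []
    for (arm, code), k in sorted(counts.items(), key=lambda kv: (kv[0][0], -kv[1])):
        out.append({"class": arm, "agent": code, "count": k,
                    "pct": percentage(k, arm_sizes[arm]) if arm_sizes[arm] else np.nan})
    return pd.DataFrame(out, columns=["class", "agent", "count", "pct"])
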