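"""Descriptive group comparisons (case/control and tertile tables).

Test selection follows the classical epidemiology-table recipe:

* categorical variables — per-group counts and percentages on the group-size
  denominator (missing reported as its own row but excluded from the test),
  Pearson chi-square on the non-missing contingency table;
* continuous variables — Levene's test (mean-centred) for homogeneity of
  variance, then Student's t (pooled when Levene p >= 0.05, Welch otherwise)
  for two groups, or one-way ANOVA for three, followed post hoc by Fisher's
  LSD (homogeneous variances) or Dunnett's T3 (heterogeneous) only when the
  omnibus test rejects at 0.05.

Every percentage is count/denominator to two decimals with the denominator
recorded, so each printed row is arithmetically auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import TertileAssignment, assign_tertiles

__all__ = [
    "GroupComparisonResult",
    "summarize_categorical",
    "compare_continuous",
    "tertile_table",
    "percent",
    "format_p",
    "ALPHA",
]

ALPHA = 0.05


def percent(count: int, denominator: int, decimals: int = 2) -> float:
    """Percentage of ``count`` in ``denominator``, rounded half-away-from-zero."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    x = 100.0 * count / denominator
    scale = 10**decimals
    return float(np.floor(x * scale + 0.5) / scale)


def format_p(p: float) -> str:
    """Render a p-value to 3 decimals, with '<0.001' below that resolution."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


@dataclass
class GroupComparisonResult:
    """One table row: per-group summaries plus the between-group test."""

    variable: str
    groups: Mapping[str, Mapping]
    method: str  # 't_test' | 'welch_t_test' | 'anova' | 'chi_square'
    statistic: float
    p_value: float
    homogeneity: tuple[float, float] | None = None  # Levene (stat, p)
    posthoc: tuple[str, Mapping[tuple[str, str], float]] | None = None
    denominators: Mapping[str, int] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _group_frames(
    records: pd.DataFrame, variable: str, group_col: str, group_labels: Sequence[str] | None
) -> dict[str, pd.Series]:
    if variable not in records.columns:
        raise KeyError(f"variable {variable!r} not in records")
    labels = (
        list(group_labels)
        if group_labels is not None
        else sorted(records[group_col].dropna().unique().tolist())
    )
    if len(labels) < 2:
        raise ValueError(f"need >= 2 groups, got {labels}")
    return {g: records.loc[records[group_col] == g, variable] for g in labels}


def summarize_categorical(
    records: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    group_labels: Sequence[str] | None = None,
    levels: Sequence[str] | None = None,
) -> GroupComparisonResult:
    """Counts/percentages per group and a chi-square composition test.

    Percentages use the full group size (missing included) as denominator;
    the chi-square is computed on the non-missing levels only.
    """
    by_group = _group_frames(records, variable, group_col, group_labels)
    observed_levels = (
        list(levels)
        if levels is not None
        else sorted({v for s in by_group.values() for v in s.dropna().unique()})
    )
    if len(observed_levels) < 2:
        raise ValueError(f"{variable!r} has a single level; chi-square undefined")

    groups_out: dict[str, dict] = {}
    denominators: dict[str, int] = {}
    table = np.zeros((len(observed_levels), len(by_group)), dtype=float)
    for j, (g, series) in enumerate(by_group.items()):
        denom = len(series)
        denominators[g] = denom
        counts = {lev: int((series == lev).sum()) for lev in observed_levels}
        n_missing = denom - sum(counts.values())
        groups_out[g] = {
            "n": denom,
            "counts": counts,
            "percent": {lev: percent(c, denom) for lev, c in counts.items()},
            "missing": n_missing,
            "missing_percent": percent(n_missing, denom),
        }
        table[:, j] = [counts[lev] for lev in observed_levels]

    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise ValueError(f"{variable!r}: zero expected cell count; chi-square undefined")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return GroupComparisonResult(
        variable=variable,
        groups=groups_out,
        method="chi_square",
        statistic=float(chi2),
        p_value=float(p),
        denominators=denominators,
    )


def _lsd_pairwise(samples: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Fisher's LSD: pairwise t on the pooled ANOVA variance, df = N - k."""
    k = len(samples)
    ns = {g: len(x) for g, x in samples.items()}
    means = {g: x.mean() for g, x in samples.items()}
    n_total = sum(ns.values())
    df = n_total - k
    mse = sum(((x - x.mean()) ** 2).sum() for x in samples.values()) / df
    out = {}
    for g1, g2 in combinations(samples, 2):
        se = np.sqrt(mse * (1 / ns[g1] + 1 / ns[g2]))
        t = (means[g1] - means[g2]) / se
        out[(g1, g2)] = float(2 * stats.t.sf(abs(t), df))
    return out


def _dunnett_t3_pairwise(samples: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunnett's T3: Welch-type pairwise t with a Studentized-Maximum-Modulus
    adjustment, computed via the independence form (2F_t(|t|; df) - 1)^m."""
    m = len(samples) * (len(samples) - 1) // 2
    out = {}
    for g1, g2 in combinations(samples, 2):
        x, y = samples[g1], samples[g2]
        v1, v2 = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (len(x) - 1) + v2**2 / (len(y) - 1))
        p_single = 2 * stats.t.sf(abs(t), df)
        out[(g1, g2)] = float(min(1.0, 1.0 - (1.0 - p_single) ** m))
    return out


def compare_continuous(
    records: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    group_labels: Sequence[str] | None = None,
    welch_fallback: bool = True,
) -> GroupComparisonResult:
    """Two-group t-test or k-group ANOVA with Levene-driven variant selection.

    Missing values are dropped per variable with the analysed n reported.
    With ``welch_fallback`` (default) a Levene rejection switches the
    two-group test to Welch's t; post-hoc tests appear only after a
    significant ANOVA omnibus.
    """
    by_group = _group_frames(records, variable, group_col, group_labels)
    samples = {
        g: pd.to_numeric(s, errors="coerce").dropna().to_numpy(dtype=float)
        for g, s in by_group.items()
    }
    for g, x in samples.items():
        if len(x) < 2:
            raise ValueError(f"group {g!r} has {len(x)} non-missing values (< 2)")

    groups_out = {
        g: {"n": int(len(x)), "mean": float(x.mean()), "sd": float(x.std(ddof=1))}
        for g, x in samples.items()
    }
    denominators = {g: int(len(x)) for g, x in samples.items()}
    lev_stat, lev_p = stats.levene(*samples.values(), center="mean")
    homogeneous = lev_p >= ALPHA

    arrays = list(samples.values())
    posthoc = None
    if len(samples) == 2:
        equal_var = homogeneous or not welch_fallback
        t, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=equal_var)
        method = "t_test" if equal_var else "welch_t_test"
        statistic = float(t)
    else:
        f, p = stats.f_oneway(*arrays)
        method = "anova"
        statistic = float(f)
        if p < ALPHA:
            posthoc = (
                ("LSD", _lsd_pairwise(samples))
                if homogeneous
                else ("Dunnett_T3", _dunnett_t3_pairwise(samples))
            )
    return GroupComparisonResult(
        variable=variable,
        groups=groups_out,
        method=method,
        statistic=statistic,
        p_value=float(p),
        homogeneity=(float(lev_stat), float(lev_p)),
        posthoc=posthoc,
        denominators=denominators,
    )


def tertile_table(
    records: pd.DataFrame,
    scores: pd.Series,
    continuous: Sequence[str] | None = None,
    categorical: Sequence[str] | None = None,
    restrict_group: str | None = "HF",
    group_col: str = "group",
) -> tuple[TertileAssignment, dict[str, GroupComparisonResult]]:
    """Characteristics-by-DII-tertile table for (by default) the HF group.

    ``scores`` must be indexed like ``records``.  Variables default to every
    numeric column among age/BMI/waist/labs and every categorical column
    among demographics and condition flags that is present.
    """
    if restrict_group is not None and group_col in records.columns:
        records = records.loc[records[group_col] == restrict_group]
    scores = scores.reindex(records.index)
    if scores.isna().any():
        raise ValueError("a DII score is required for every participant in the table")

    tert = assign_tertiles(scores.to_numpy(dtype=float))
    tagged = records.copy()
    tagged["dii_tertile"] = tert.labels

    if continuous is None:
        candidates = ["age", "bmi", "waist_cm"] + [
            c for c in records.columns if c.startswith("lab_")
        ]
        continuous = [c for c in candidates if c in records.columns]
    if categorical is None:
        candidates = ["sex", "race", "education", "income_band", "smoking"] + [
            c for c in records.columns if c in
            ("hypertension", "diabetes", "prediabetes", "coronary_artery_disease",
             "angina", "heart_attack", "stroke")
        ]
        categorical = [c for c in candidates if c in records.columns]

    results: dict[str, GroupComparisonResult] = {}
    for var in continuous:
        results[var] = compare_continuous(tagged, var, group_col="dii_tertile",
                                          group_labels=["T1", "T2", "T3"])
    for var in categorical:
        results[var] = summarize_categorical(tagged, var, group_col="dii_tertile",
                                             group_labels=["T1", "T2", "T3"])
    return tert, results
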