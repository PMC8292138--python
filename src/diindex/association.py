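"""Logistic-regression association models for HF on the DII score.

Three nested models form the covariate ladder:

* model 1 — crude: HF ~ DII;
* model 2 — + age (years), sex, BMI (kg/m2);
* model 3 — + race, education, annual family income, current smoking status.

Fits are maximum-likelihood logistic regressions on complete cases for the
model's covariates; the DII enters as a continuous per-unit term.  Odds
ratios are exp(coefficient) with Wald 95% CIs exp(b +/- 1.96 SE).  Reference
levels: male sex, "Other race or multi-racial", ">High school" education,
"<20,000 USD" income, "Non-smoking".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ORRow",
    "ORTable",
    "LogisticORModel",
    "fit_logistic_model",
    "odds_ratio_from_counts",
    "MODEL_COVARIATES",
    "REFERENCE_LEVELS",
    "ConvergenceError",
    "SeparationError",
]

Z_95 = 1.959963984540054  # normal 97.5% quantile for Wald 95% CIs

MODEL_COVARIATES: Mapping[int, tuple[str, ...]] = {
    1: ("dii_total",),
    2: ("dii_total", "age", "sex", "bmi"),
    3: ("dii_total", "age", "sex", "bmi", "race", "education", "income_band", "smoking"),
}

REFERENCE_LEVELS: Mapping[str, str] = {
    "sex": "male",
    "race": "Other race or multi-racial",
    "education": ">High school",
    "income_band": "<20,000 USD",
    "smoking": "Non-smoking",
}

CATEGORICAL_TERMS = tuple(REFERENCE_LEVELS)


class ConvergenceError(RuntimeError):
    """The maximum-likelihood fit did not converge."""


class SeparationError(RuntimeError):
    """A term separates the outcome completely; the MLE does not exist."""


@dataclass(frozen=True)
class ORRow:
    term: str
    level: str | None  # categorical level, or None for continuous per-unit terms
    or_: float
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    is_reference: bool = False


@dataclass
class ORTable:
    """Fitted odds-ratio table for one model of the ladder."""

    model_id: int
    rows: list[ORRow]
    n_used: int
    covariate_spec: tuple[str, ...]
    llf: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": r.term,
                    "level": r.level,
                    "OR": r.or_,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p_value": r.p_value,
                    "is_reference": r.is_reference,
                }
                for r in self.rows
            ]
        )

    def lookup(self, term: str, level: str | None = None) -> ORRow:
        for r in self.rows:
            if r.term == term and (level is None or r.level == level):
                return r
        raise KeyError(f"no row for term {term!r} level {level!r}")


def _design_matrix(
    X: pd.DataFrame, covariates: Sequence[str], missing_as_level: bool
) -> tuple[pd.DataFrame, list[tuple[str, str | None]]]:
    """Complete-case design matrix with reference-coded categoricals.

    Returns the matrix and an ordered (term, level) descriptor per column.
    """
    cols = pd.DataFrame(index=X.index)
    descriptors: list[tuple[str, str | None]] = []
    for cov in covariates:
        if cov not in X.columns:
            raise KeyError(f"covariate {cov!r} not found")
        if cov in CATEGORICAL_TERMS:
            series = X[cov].astype(object)
            if missing_as_level:
                series = series.where(series.notna(), "Missing")
            ref = REFERENCE_LEVELS[cov]
            levels = [lv for lv in pd.unique(series.dropna()) if lv != ref]
            levels = sorted(levels, key=str)
            for lv in levels:
                cols[f"{cov}[{lv}]"] = (series == lv).astype(float)
                descriptors.append((cov, str(lv)))
            cols.loc[series.isna(), [f"{cov}[{lv}]" for lv in levels]] = np.nan
        else:
            cols[cov] = pd.to_numeric(X[cov], errors="coerce")
            descriptors.append((cov, None))
    return cols, descriptors


class LogisticORModel(BaseEstimator):
    """Sklearn-style estimator for one model of the HF ~ DII covariate ladder.

    Parameters
    ----------
    model_id : {1, 2, 3}
        Selects the nested covariate set.
    missing_as_level : bool, default False
        Keep missing categorical values as an explicit "Missing" level instead
        of dropping those records (complete-case is the default).
    lr_pvalues : bool, default False
        Report likelihood-ratio p-values instead of Wald p-values.

    Attributes
    ----------
    or_table_ : ORTable
        Odds ratios with 95% CIs for every fitted term.
    result_ : statsmodels result
        The underlying maximum-likelihood fit.
    n_used_ : int
        Complete-case sample size entering the fit.
    """

    def __init__(self, model_id: int = 1, missing_as_level: bool = False,
                 lr_pvalues: bool = False, maxiter: int = 100):
        self.model_id = model_id
        self.missing_as_level = missing_as_level
        self.lr_pvalues = lr_pvalues
        self.maxiter = maxiter

    def fit(self, X: pd.DataFrame, y):
        if self.model_id not in MODEL_COVARIATES:
            raise ValueError(f"model_id must be one of {sorted(MODEL_COVARIATES)}")
        covariates = MODEL_COVARIATES[self.model_id]
        y = pd.Series(np.asarray(y).astype(float), index=X.index)
        design, descriptors = _design_matrix(X, covariates, self.missing_as_level)
        mask = design.notna().all(axis=1) & y.notna()
        design, y_fit = design.loc[mask], y.loc[mask]
        exog = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.Logit(y_fit.to_numpy(), exog).fit(disp=0, maxiter=self.maxiter)
        except PerfectSeparationWarning as err:
            raise SeparationError(f"complete separation detected: {err}") from err
        except np.linalg.LinAlgError as err:  # singular design
            raise SeparationError(f"singular design matrix: {err}") from err
        if not res.mle_retvals.get("converged", False):
            raise ConvergenceError(
                f"logistic fit failed to converge after "
                f"{res.mle_retvals.get('iterations', '?')} iterations "
                f"(|grad| = {np.abs(res.model.score(res.params)).max():.3g})"
            )
        params, bse = res.params[1:], res.bse[1:]
        big = np.abs(params) > 15
        if np.any(big):
            bad = [descriptors[i] for i in np.where(big)[0]]
            raise SeparationError(f"complete separation suspected for terms: {bad}")

        pvals = res.pvalues[1:]
        if self.lr_pvalues:
            pvals = self._lr_pvalues(y_fit.to_numpy(), exog, res)

        rows: list[ORRow] = []
        seen_ref: set[str] = set()
        for i, (term, level) in enumerate(descriptors):
            if level is not None and term not in seen_ref:
                rows.append(ORRow(term, REFERENCE_LEVELS[term], 1.0, None, None,
                                  None, is_reference=True))
                seen_ref.add(term)
            rows.append(
                ORRow(
                    term,
                    level,
                    math.exp(params[i]),
                    math.exp(params[i] - Z_95 * bse[i]),
                    math.exp(params[i] + Z_95 * bse[i]),
                    float(pvals[i]),
                )
            )
        self.result_ = res
        self.n_used_ = int(mask.sum())
        self.or_table_ = ORTable(
            model_id=self.model_id,
            rows=rows,
            n_used=self.n_used_,
            covariate_spec=covariates,
            llf=float(res.llf),
        )
        return self

    @staticmethod
    def _lr_pvalues(y: np.ndarray, exog: np.ndarray, full) -> np.ndarray:
        from scipy.stats import chi2

        pvals = np.empty(exog.shape[1] - 1)
        for j in range(1, exog.shape[1]):
            reduced = sm.Logit(y, np.delete(exog, j, axis=1)).fit(disp=0)
            pvals[j - 1] = chi2.sf(2 * (full.llf - reduced.llf), df=1)
        return pvals

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "result_")
        design, _ = _design_matrix(
            X, MODEL_COVARIATES[self.model_id], self.missing_as_level
        )
        exog = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
        p1 = self.result_.predict(exog)
        return np.column_stack([1 - p1, p1])


def fit_logistic_model(
    cohort_records: pd.DataFrame,
    scores: pd.Series,
    model_id: int,
    missing_as_level: bool = False,
    lr_pvalues: bool = False,
) -> ORTable:
    """Fit one ladder model on a labelled cohort (``group`` in {HF, non-HF})."""
    X = cohort_records.copy()
    X["dii_total"] = scores.reindex(cohort_records.index)
    y = (cohort_records["group"] == "HF").astype(int)
    est = LogisticORModel(model_id=model_id, missing_as_level=missing_as_level,
                          lr_pvalues=lr_pvalues)
    est.fit(X, y)
    return est.or_table_


def odds_ratio_from_counts(a: float, b: float, c: float, d: float) -> dict:
    """Odds ratio for a 2x2 table [[a, b], [c, d]] with a Woolf 95% CI.

    ``a``/``b`` are exposed/unexposed cases, ``c``/``d`` exposed/unexposed
    controls.  When any single cell is zero the Haldane–Anscombe 0.5
    correction is applied (and flagged); a zero row or column leaves the OR
    undefined and raises ``ValueError``.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    aa, bb, cc, dd = cells
    for pair in ((aa, bb), (cc, dd), (aa, cc), (bb, dd)):
        if pair[0] == 0 and pair[1] == 0:
            raise ValueError("a zero row or column leaves the odds ratio undefined")
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    aa, bb, cc, dd = cells
    log_or = math.log(aa * dd / (bb * cc))
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return {
        "OR": math.exp(log_or),
        "ci_low": math.exp(log_or - Z_95 * se),
        "ci_high": math.exp(log_or + Z_95 * se),
        "corrected": corrected,
    }
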