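"""Random-forest discrimination of HF with cross-validated ROC/AUC.

A stratified 10-fold cross-validation trains one forest per fold on the
training folds only (with median imputation of missing features fitted on
the training folds, so no leakage), pools the out-of-fold predicted
probabilities into a single ROC curve, and averages impurity-based variable
importances across folds.  The analysis runs overall and within sex
subgroups; dietary features are flagged so the nutrient importance ranking
can be read off directly.

The AUC is computed by the trapezoidal rule over the empirical ROC and is
identical to the Mann–Whitney concordance probability
P(score_case > score_control) + 0.5 P(tie).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.model_selection import StratifiedKFold

from .cohort import DIET_PREFIX, LAB_PREFIX

__all__ = [
    "RFResult",
    "CrossValidatedForest",
    "fit_rf_cv",
    "compute_roc",
    "rank_dietary_features",
    "default_feature_frame",
]

DEFAULT_N_TREES = 500
DEFAULT_FOLDS = 10


@dataclass
class RFResult:
    """Cross-validated random-forest output for one subgroup."""

    subgroup: str
    feature_importances: pd.DataFrame  # columns: feature, importance, is_dietary
    cv_predictions: pd.Series  # out-of-fold P(HF), one per participant
    auc: float
    roc_points: np.ndarray  # (n_thresholds+1, 2) array of (FPR, TPR)
    per_fold_auc: list[float]
    seed: int
    n_trees: int
    folds: int


def compute_roc(predictions, labels) -> tuple[np.ndarray, float]:
    """Empirical ROC by threshold sweep over unique predicted values.

    Returns the (FPR, TPR) points from (0, 0) to (1, 1) and the trapezoidal
    AUC.  Probabilities must lie in [0, 1] and both classes must be present.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.shape != y.shape:
        raise ValueError("predictions and labels must have equal length")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("predictions must be probabilities in [0, 1]")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to form a ROC curve")

    order = np.argsort(-p, kind="stable")
    p_sorted, y_sorted = p[order], y[order]
    # cumulative counts at each distinct threshold (descending)
    boundary = np.r_[np.diff(p_sorted) != 0, True]
    tp = np.cumsum(y_sorted)[boundary]
    fp = np.cumsum(1 - y_sorted)[boundary]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def default_feature_frame(
    records: pd.DataFrame,
    include_dii: bool = False,
    scores: pd.Series | None = None,
) -> pd.DataFrame:
    """Default feature set: demographics + laboratory panel + dietary intakes.

    Sex is encoded as an indicator (female = 1); the DII total itself can be
    appended via ``include_dii``.
    """
    feats = pd.DataFrame(index=records.index)
    for col in ("age", "bmi", "waist_cm"):
        if col in records.columns:
            feats[col] = pd.to_numeric(records[col], errors="coerce")
    if "sex" in records.columns:
        feats["sex_female"] = (records["sex"] == "female").astype(float)
    for col in records.columns:
        if col.startswith(LAB_PREFIX) or col.startswith(DIET_PREFIX):
            feats[col] = pd.to_numeric(records[col], errors="coerce")
    if include_dii:
        if scores is None:
            raise ValueError("include_dii requires the scores series")
        feats["dii_total"] = scores.reindex(records.index)
    return feats


def fit_rf_cv(
    features: pd.DataFrame,
    labels,
    subgroup: str = "all",
    n_trees: int = DEFAULT_N_TREES,
    folds: int = DEFAULT_FOLDS,
    seed: int = 17,
    max_features: str | float = "sqrt",
    imputation: str = "median",
) -> RFResult:
    """Stratified k-fold random forest with pooled out-of-fold predictions.

    ``imputation`` is "median" (fitted on training folds only) or
    "complete_case" (rows with any missing feature are dropped first).
    Every retained participant receives exactly one out-of-fold prediction.
    """
    y = pd.Series(np.asarray(labels).astype(int), index=features.index)
    X = features.copy()
    if imputation == "complete_case":
        keep = X.notna().all(axis=1)
        X, y = X.loc[keep], y.loc[keep]
    elif imputation != "median":
        raise ValueError("imputation must be 'median' or 'complete_case'")
    if len(X) < folds:
        raise ValueError(f"{len(X)} participants < {folds} folds")
    class_counts = y.value_counts()
    if len(class_counts) < 2 or class_counts.min() < folds:
        raise ValueError(
            f"minority class has {class_counts.min() if len(class_counts) == 2 else 0} "
            f"members; use fewer than {folds} folds"
        )

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(len(X), np.nan)
    importances = np.zeros(X.shape[1])
    per_fold_auc: list[float] = []
    Xv, yv = X.to_numpy(dtype=float), y.to_numpy()
    for fold_idx, (tr, te) in enumerate(skf.split(Xv, yv)):
        X_tr, X_te = Xv[tr], Xv[te]
        if imputation == "median":
            imp = SimpleImputer(strategy="median").fit(X_tr)
            X_tr, X_te = imp.transform(X_tr), imp.transform(X_te)
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=seed + fold_idx,
            n_jobs=1,
        ).fit(X_tr, yv[tr])
        oof[te] = clf.predict_proba(X_te)[:, list(clf.classes_).index(1)]
        importances += clf.feature_importances_
        _, fold_auc = compute_roc(oof[te], yv[te])
        per_fold_auc.append(fold_auc)
    importances /= folds

    roc_points, auc = compute_roc(oof, yv)
    imp_frame = pd.DataFrame(
        {
            "feature": X.columns,
            "importance": importances,
            "is_dietary": [c.startswith(DIET_PREFIX) for c in X.columns],
        }
    )
    return RFResult(
        subgroup=subgroup,
        feature_importances=imp_frame,
        cv_predictions=pd.Series(oof, index=X.index, name="p_hf"),
        auc=auc,
        roc_points=roc_points,
        per_fold_auc=per_fold_auc,
        seed=seed,
        n_trees=n_trees,
        folds=folds,
    )


def rank_dietary_features(result: RFResult, top_k: int = 10) -> pd.DataFrame:
    """Dietary features ordered by importance (stable sort), truncated to top_k."""
    diet = result.feature_importances.loc[result.feature_importances["is_dietary"]]
    if diet.empty:
        raise ValueError("no dietary features in the fitted result")
    order = np.argsort(-diet["importance"].to_numpy(), kind="stable")
    ranked = diet.iloc[order].reset_index(drop=True)
    return ranked.head(max(0, int(top_k)))


class CrossValidatedForest:
    """Thin configuration wrapper around :func:`fit_rf_cv`.

    Holds the hyperparameters (trees, folds, seed, imputation policy) and
    exposes ``fit(features, labels)`` returning ``self`` with ``result_`` set,
    plus ``get_params``/``set_params`` so it slots into sklearn tooling.
    """

    def __init__(self, n_trees: int = DEFAULT_N_TREES, folds: int = DEFAULT_FOLDS,
                 seed: int = 17, max_features="sqrt", imputation: str = "median"):
        self.n_trees = n_trees
        self.folds = folds
        self.seed = seed
        self.max_features = max_features
        self.imputation = imputation

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_trees": self.n_trees,
            "folds": self.folds,
            "seed": self.seed,
            "max_features": self.max_features,
            "imputation": self.imputation,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, features: pd.DataFrame, labels, subgroup: str = "all"):
        self.result_ = fit_rf_cv(
            features,
            labels,
            subgroup=subgroup,
            n_trees=self.n_trees,
            folds=self.folds,
            seed=self.seed,
            max_features=self.max_features,
            imputation=self.imputation,
        )
        return self
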