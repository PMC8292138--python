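"""Dietary Inflammatory Index (DII) scoring engine.

The DII summarises the inflammatory potential of a 24-hour diet.  For each
food parameter with reference constants (global mean ``mu``, SD ``sigma``,
effect score ``w``) and an observed daily intake ``x``:

    z  = (x - mu) / sigma                      (standardised intake)
    cp = 2 * Phi(z) - 1                        (centered percentile, in (-1, 1))
    contribution = cp * w

and the overall DII score is the sum of contributions over the parameters
available for that participant.  ``Phi`` is the standard normal CDF by
default; it is the single pluggable point of the construction, so an
empirical-distribution percentile can be swapped in.

A positive DII indicates a pro-inflammatory diet, a negative DII an
anti-inflammatory diet.  With every intake at its global mean the score is
exactly zero, and ``|DII| <= sum(|w|)`` over the parameters used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .reference import ReferenceTable, load_reference_table

__all__ = [
    "z_score",
    "centered_percentile",
    "parameter_score",
    "dii_score",
    "score_frame",
    "assign_tertiles",
    "DIIResult",
    "TertileAssignment",
    "DIIScorer",
    "IntakeValidationError",
    "UnscorableRecordError",
    "DEFAULT_MIN_PARAMETERS",
]

#: Records with fewer scorable parameters than this are flagged, not scored.
DEFAULT_MIN_PARAMETERS = 20

CdfFunction = Callable[[np.ndarray], np.ndarray]


class IntakeValidationError(ValueError):
    """An intake amount is negative, non-finite, or names an unknown parameter."""


class UnscorableRecordError(ValueError):
    """A record has too few scorable parameters for a valid DII score."""


@dataclass(frozen=True)
class DIIResult:
    """Per-participant DII decomposition.

    ``per_parameter`` maps each scored parameter name to a dict with keys
    ``z``, ``centered_percentile`` and ``contribution``; ``total`` is the sum
    of contributions (the overall DII score).
    """

    participant_id: str
    per_parameter: Mapping[str, Mapping[str, float]]
    n_parameters_used: int
    total: float


@dataclass(frozen=True)
class TertileAssignment:
    """Tertile split of a set of DII scores.

    ``boundaries`` are the two cut values (scores at or below a cut fall in
    the lower tertile); ``labels`` holds a per-score label in {T1, T2, T3};
    ``ranges`` gives the observed (min, max) within each tertile.
    """

    boundaries: tuple[float, float]
    labels: np.ndarray
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def counts(self) -> Mapping[str, int]:
        lab, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(lab.tolist(), cnt.tolist()))


def _validate_intake(intake: float, name: str = "intake") -> float:
    intake = float(intake)
    if not math.isfinite(intake):
        raise IntakeValidationError(f"{name}: intake must be finite, got {intake}")
    if intake < 0:
        raise IntakeValidationError(f"{name}: intake must be >= 0, got {intake}")
    return intake


def z_score(intake: float, ref) -> float:
    """Standardise an intake against its global reference mean and SD."""
    intake = _validate_intake(intake, ref.name)
    return (intake - ref.global_mean) / ref.global_sd


def centered_percentile(z, cdf: CdfFunction = norm.cdf):
    """Map a z-score to a symmetric percentile score in (-1, 1).

    Computes ``2 * cdf(z) - 1``; an odd, strictly increasing function of ``z``
    under the default standard-normal CDF.
    """
    z_arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z_arr)):
        raise IntakeValidationError("z must be finite")
    out = 2.0 * np.asarray(cdf(z_arr), dtype=float) - 1.0
    # the CDF saturates to 0/1 in double precision for |z| beyond ~8.3; keep
    # the result strictly inside the open interval
    limit = 1.0 - np.finfo(float).eps / 2
    out = np.clip(out, -limit, limit)
    return float(out) if np.isscalar(z) or out.ndim == 0 else out


def parameter_score(intake: float, ref, cdf: CdfFunction = norm.cdf) -> float:
    """One parameter's DII contribution: centered percentile times effect score."""
    return centered_percentile(z_score(intake, ref), cdf=cdf) * ref.effect_score


def dii_score(
    record: Mapping[str, float],
    table: ReferenceTable,
    min_parameters: int = DEFAULT_MIN_PARAMETERS,
    participant_id: str = "",
    cdf: CdfFunction = norm.cdf,
    strict: bool = True,
) -> DIIResult:
    """Score a single dietary record (parameter name -> daily amount).

    Parameters present in the record but absent from the reference table raise
    :class:`IntakeValidationError` when ``strict`` (the ingestion contract);
    parameters in the table but absent from the record contribute nothing and
    are excluded from ``n_parameters_used``.  Records with fewer than
    ``min_parameters`` scorable parameters raise
    :class:`UnscorableRecordError` rather than returning a silently truncated
    score.
    """
    if strict:
        unknown = sorted(set(record) - set(table.names))
        if unknown:
            raise IntakeValidationError(f"unknown food parameters: {unknown}")
    scorable = [name for name in table.names if name in record and pd.notna(record[name])]
    if len(scorable) < min_parameters:
        raise UnscorableRecordError(
            f"record {participant_id!r}: only {len(scorable)} scorable parameters "
            f"(minimum {min_parameters})"
        )
    per_parameter: dict[str, dict[str, float]] = {}
    total = 0.0
    for name in scorable:
        ref = table[name]
        z = z_score(record[name], ref)
        cp = centered_percentile(z, cdf=cdf)
        contribution = cp * ref.effect_score
        per_parameter[name] = {
            "z": z,
            "centered_percentile": cp,
            "contribution": contribution,
        }
        total += contribution
    return DIIResult(
        participant_id=participant_id,
        per_parameter=per_parameter,
        n_parameters_used=len(scorable),
        total=total,
    )


def score_frame(
    intakes: pd.DataFrame,
    table: ReferenceTable,
    min_parameters: int = DEFAULT_MIN_PARAMETERS,
    cdf: CdfFunction = norm.cdf,
    contributions: bool = False,
) -> pd.DataFrame:
    """Vectorised DII scoring of an intake table (one row per participant).

    Columns of ``intakes`` must be food-parameter names from ``table``; NaN
    marks a missing intake.  Returns a frame indexed like ``intakes`` with
    ``dii_total``, ``n_parameters_used`` and ``scorable`` columns (unscorable
    rows get ``dii_total = NaN``), plus per-parameter ``contrib_<name>``
    columns when ``contributions`` is requested.
    """
    unknown = sorted(set(intakes.columns) - set(table.names))
    if unknown:
        raise IntakeValidationError(f"unknown food parameters: {unknown}")
    cols = [c for c in table.names if c in intakes.columns]
    values = intakes[cols].to_numpy(dtype=float)
    if np.any(values[np.isfinite(values)] < 0):
        bad_r, bad_c = np.where(values < 0)
        raise IntakeValidationError(
            f"negative intake for parameter {cols[bad_c[0]]!r} "
            f"(row {intakes.index[bad_r[0]]!r})"
        )
    means = np.array([table[c].global_mean for c in cols])
    sds = np.array([table[c].global_sd for c in cols])
    effects = np.array([table[c].effect_score for c in cols])

    limit = 1.0 - np.finfo(float).eps / 2
    with np.errstate(invalid="ignore"):
        z = (values - means) / sds
        cp = np.clip(2.0 * np.asarray(cdf(z), dtype=float) - 1.0, -limit, limit)
        contrib = cp * effects
    present = np.isfinite(values)
    contrib = np.where(present, contrib, 0.0)
    n_used = present.sum(axis=1)
    total = contrib.sum(axis=1)
    scorable = n_used >= min_parameters
    total = np.where(scorable, total, np.nan)

    out = pd.DataFrame(
        {
            "dii_total": total,
            "n_parameters_used": n_used,
            "scorable": scorable,
        },
        index=intakes.index,
    )
    if contributions:
        contrib_frame = pd.DataFrame(
            np.where(present, contrib, np.nan),
            index=intakes.index,
            columns=[f"contrib_{c}" for c in cols],
        )
        out = pd.concat([out, contrib_frame], axis=1)
    return out


def assign_tertiles(scores: Sequence[float]) -> TertileAssignment:
    """Split DII scores into rank-based tertiles T1 < T2 < T3.

    Group sizes differ by at most one, with the remainder allocated to the
    upper tertiles (n = 1,382 gives 460/461/461).  Rank ties are broken by
    stable input order; a score exactly at a cut value stays in the lower
    tertile.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.ndim != 1 or arr.size < 3:
        raise ValueError(f"need at least 3 scores, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("scores must be finite")
    if np.ptp(arr) == 0:
        raise ValueError("all scores identical; tertiles undefined")
    n = arr.size
    base, rem = divmod(n, 3)
    sizes = (base, base + (1 if rem >= 2 else 0), base + (1 if rem >= 1 else 0))
    order = np.argsort(arr, kind="stable")
    labels = np.empty(n, dtype=object)
    labels[order[: sizes[0]]] = "T1"
    labels[order[sizes[0] : sizes[0] + sizes[1]]] = "T2"
    labels[order[sizes[0] + sizes[1] :]] = "T3"
    ranges = {
        t: (float(arr[labels == t].min()), float(arr[labels == t].max()))
        for t in ("T1", "T2", "T3")
    }
    boundaries = (ranges["T1"][1], ranges["T2"][1])
    return TertileAssignment(boundaries=boundaries, labels=labels, ranges=ranges)


class DIIScorer(TransformerMixin, BaseEstimator):
    """Transformer computing the overall DII score from intake columns.

    Accepts a DataFrame whose columns include food-parameter names from the
    reference table; ``transform`` returns a single ``dii_total`` column so the
    scorer composes with sklearn pipelines.  Rows with fewer than
    ``min_parameters`` non-missing parameters transform to NaN.

    Parameters
    ----------
    reference : ReferenceTable or path-like, optional
        Scoring constants; default is the bundled 26-parameter table.
    min_parameters : int, default 20
        Minimum scorable parameters for a valid score.

    Attributes
    ----------
    reference_table_ : ReferenceTable
        Resolved constants used for scoring.
    feature_names_in_ : ndarray of str
        Intake columns seen in ``fit``.
    """

    def __init__(self, reference=None, min_parameters: int = DEFAULT_MIN_PARAMETERS):
        self.reference = reference
        self.min_parameters = min_parameters

    def _resolve_reference(self) -> ReferenceTable:
        if isinstance(self.reference, ReferenceTable):
            return self.reference
        return load_reference_table(self.reference)

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("DIIScorer requires a DataFrame with named intake columns")
        self.reference_table_ = self._resolve_reference()
        cols = [c for c in X.columns if c in set(self.reference_table_.names)]
        if not cols:
            raise IntakeValidationError("no reference food-parameter columns found")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.parameter_columns_ = cols
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "reference_table_")
        scored = score_frame(
            X[self.parameter_columns_],
            self.reference_table_,
            min_parameters=self.min_parameters,
        )
        return scored[["dii_total"]].to_numpy()

    def score_frame(self, X: pd.DataFrame, contributions: bool = True) -> pd.DataFrame:
        """Full decomposition (totals, parameter counts, contributions)."""
        check_is_fitted(self, "reference_table_")
        return score_frame(
            X[self.parameter_columns_],
            self.reference_table_,
            min_parameters=self.min_parameters,
            contributions=contributions,
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["dii_total"], dtype=object)
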