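"""Heart-failure case/control cohort construction.

Participants flow through three ordered exclusion gates before grouping:

1. missing HF diagnosis (the congestive-heart-failure questionnaire item is
   unanswered);
2. no qualifying basic disease — none of hypertension, diabetes, prediabetes,
   coronary artery disease, angina, heart attack or stroke is reported "yes"
   (a missing flag never qualifies);
3. missing essential dietary data — the 24-h intake record has too few
   parameters for a valid DII score.

Survivors are labelled HF (diagnosis "yes") or non-HF ("no").  The flow
accounting partitions the input exactly: every record lands in precisely one
of the five boxes, and missing covariates (BMI, education, smoking ...) never
exclude anyone at this stage — each downstream analysis decides its own
missing-data handling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .reference import ReferenceTable
from .scoring import DEFAULT_MIN_PARAMETERS, score_frame

__all__ = [
    "QUALIFYING_CONDITIONS",
    "SEX_LEVELS",
    "RACE_LEVELS",
    "EDUCATION_LEVELS",
    "INCOME_LEVELS",
    "SMOKING_LEVELS",
    "DIET_PREFIX",
    "LAB_PREFIX",
    "intake_frame",
    "classify_participant",
    "build_cohort",
    "CohortFlow",
    "CohortDataset",
    "HF",
    "NON_HF",
]

#: Diagnostic histories that qualify a participant for the analysis base.
QUALIFYING_CONDITIONS = (
    "hypertension",
    "diabetes",
    "prediabetes",
    "coronary_artery_disease",
    "angina",
    "heart_attack",
    "stroke",
)

SEX_LEVELS = ("male", "female")
RACE_LEVELS = (
    "Mexican American",
    "Other Hispanic",
    "Non-Hispanic white",
    "Non-Hispanic black",
    "Other race or multi-racial",
)
EDUCATION_LEVELS = ("<High school", "High school", ">High school")
INCOME_LEVELS = ("<20,000 USD", ">=20,000 USD")
SMOKING_LEVELS = ("Smoking", "Non-smoking")

#: Column-name prefixes for 24-h dietary intakes and laboratory measurements.
DIET_PREFIX = "diet_"
LAB_PREFIX = "lab_"

HF = "HF"
NON_HF = "non-HF"
EXCL_MISSING_HF = "excluded:missing_hf"
EXCL_NO_BASIC = "excluded:no_basic_disease"
EXCL_MISSING_DIET = "excluded:missing_diet"


def intake_frame(participants: pd.DataFrame) -> pd.DataFrame:
    """Extract the dietary intake columns (``diet_*``), prefix stripped."""
    cols = [c for c in participants.columns if c.startswith(DIET_PREFIX)]
    out = participants[cols].copy()
    out.columns = [c[len(DIET_PREFIX) :] for c in cols]
    return out


def _as_flag(value) -> str | None:
    """Normalise a condition flag to 'yes' / 'no' / None (missing)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("yes", "no"):
            return v
        if v in ("", "missing", "nan"):
            return None
        raise ValueError(f"invalid condition flag {value!r}")
    if value in (0, 1):
        return "yes" if value else "no"
    raise ValueError(f"invalid condition flag {value!r}")


def classify_participant(rec: Mapping, diet_scorable: bool | None = None) -> str:
    """Label one participant: HF, non-HF, or an exclusion reason.

    ``diet_scorable`` may be passed explicitly; otherwise it is read from the
    record's ``diet_scorable`` field.  The function is pure — the label
    depends only on the record's own fields.
    """
    hf = _as_flag(rec.get("heart_failure"))
    if hf is None:
        return EXCL_MISSING_HF
    if not any(_as_flag(rec.get(c)) == "yes" for c in QUALIFYING_CONDITIONS):
        return EXCL_NO_BASIC
    if diet_scorable is None:
        diet_scorable = bool(rec.get("diet_scorable", False))
    if not diet_scorable:
        return EXCL_MISSING_DIET
    return HF if hf == "yes" else NON_HF


@dataclass(frozen=True)
class CohortFlow:
    """Exclusion-flow accounting; the counts partition the input exactly."""

    n_input: int
    excluded_missing_hf: int
    excluded_no_basic_disease: int
    excluded_missing_diet: int
    n_hf: int
    n_non_hf: int

    @property
    def n_excluded(self) -> int:
        return (
            self.excluded_missing_hf
            + self.excluded_no_basic_disease
            + self.excluded_missing_diet
        )

    @property
    def n_retained(self) -> int:
        return self.n_hf + self.n_non_hf

    def __post_init__(self) -> None:
        if self.n_input != self.n_excluded + self.n_retained:
            raise ValueError("flow counts do not partition the input")

    def to_dict(self) -> dict:
        return {
            "input": self.n_input,
            "excluded_missing_hf": self.excluded_missing_hf,
            "excluded_no_basic_disease": self.excluded_no_basic_disease,
            "excluded_missing_diet": self.excluded_missing_diet,
            "excluded_total": self.n_excluded,
            "hf": self.n_hf,
            "non_hf": self.n_non_hf,
            "retained": self.n_retained,
        }


@dataclass(frozen=True)
class CohortDataset:
    """Labelled cohort: retained records with a ``group`` column, plus flow."""

    records: pd.DataFrame
    flow: CohortFlow
    labels: pd.Series  # per-input label including exclusion reasons

    @property
    def hf_prevalence(self) -> float:
        return self.flow.n_hf / self.flow.n_retained


def build_cohort(
    participants: pd.DataFrame,
    reference: ReferenceTable | None = None,
    min_parameters: int = DEFAULT_MIN_PARAMETERS,
    scorable: pd.Series | None = None,
) -> CohortDataset:
    """Apply the exclusion flow to a participant table.

    ``participants`` must carry a unique ``participant_id`` column, the
    condition-flag columns, and (unless ``scorable`` is supplied) ``diet_*``
    intake columns scored against ``reference`` to decide dietary
    completeness.
    """
    if "participant_id" not in participants.columns:
        raise ValueError("participants table needs a 'participant_id' column")
    ids = participants["participant_id"]
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate participant ids: {dupes[:10]}")
    if len(participants) == 0:
        raise ValueError("participants table is empty")

    if scorable is None:
        if reference is None:
            raise ValueError("either a reference table or a scorable series is required")
        diet = intake_frame(participants)
        if diet.shape[1] == 0:
            scorable = pd.Series(False, index=participants.index)
        else:
            scored = score_frame(diet, reference, min_parameters=min_parameters)
            scorable = scored["scorable"]
    scorable = scorable.reindex(participants.index).fillna(False).astype(bool)

    hf_flag = participants["heart_failure"].map(_as_flag)
    any_basic = pd.Series(False, index=participants.index)
    for cond in QUALIFYING_CONDITIONS:
        if cond in participants.columns:
            any_basic |= participants[cond].map(_as_flag) == "yes"

    labels = pd.Series(EXCL_MISSING_HF, index=participants.index, dtype=object)
    has_hf_info = hf_flag.notna()
    labels[has_hf_info & ~any_basic] = EXCL_NO_BASIC
    eligible = has_hf_info & any_basic
    labels[eligible & ~scorable] = EXCL_MISSING_DIET
    kept = eligible & scorable
    labels[kept & (hf_flag == "yes")] = HF
    labels[kept & (hf_flag == "no")] = NON_HF

    flow = CohortFlow(
        n_input=len(participants),
        excluded_missing_hf=int((labels == EXCL_MISSING_HF).sum()),
        excluded_no_basic_disease=int((labels == EXCL_NO_BASIC).sum()),
        excluded_missing_diet=int((labels == EXCL_MISSING_DIET).sum()),
        n_hf=int((labels == HF).sum()),
        n_non_hf=int((labels == NON_HF).sum()),
    )
    records = participants.loc[kept].copy()
    records["group"] = labels.loc[kept]
    return CohortDataset(records=records, flow=flow, labels=labels)
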