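"""Participant-table ingestion: CSV (canonical) and SAS transport (XPT) adapter.

The canonical interchange format is UTF-8 CSV with the pipeline's column
names (``participant_id``, demographics, condition flags, ``lab_*``
measurements and ``diet_*`` intakes).  Survey-style files with their own
variable names (e.g. SEQN, RIDAGEYR) are ingested through a
:class:`ColumnMapping` — a rename table plus optional per-column value
recodes and explicit unit declarations for dietary columns.  Units are only
ever rescaled through the declared-unit table; silent unit guessing is
forbidden, so a declared unit that cannot be converted to the reference
table's unit is an error.

Validation collects every coercion problem (with row and column named) and
reports them together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import DIET_PREFIX
from .reference import ReferenceTable, load_reference_table

__all__ = ["ColumnMapping", "read_participant_table", "ValidationReportError",
           "UNIT_FACTORS"]

#: Explicit mass/energy unit conversion factors (from-unit, to-unit) -> scale.
UNIT_FACTORS: Mapping[tuple[str, str], float] = {
    ("g", "g"): 1.0, ("mg", "mg"): 1.0, ("ug", "ug"): 1.0, ("kcal", "kcal"): 1.0,
    ("RE", "RE"): 1.0,
    ("mg", "g"): 1e-3, ("g", "mg"): 1e3,
    ("ug", "mg"): 1e-3, ("mg", "ug"): 1e3,
    ("ug", "g"): 1e-6, ("g", "ug"): 1e6,
}


class ValidationReportError(ValueError):
    """Aggregated ingestion failures; ``errors`` lists every problem found."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        preview = "\n  ".join(errors[:20])
        more = f"\n  ... and {len(errors) - 20} more" if len(errors) > 20 else ""
        super().__init__(f"{len(errors)} validation error(s):\n  {preview}{more}")


@dataclass
class ColumnMapping:
    """External-file → canonical-schema mapping.

    ``columns`` renames external variables to canonical fields; ``values``
    recodes raw codes per canonical column (e.g. survey codes 1/2 → yes/no);
    ``units`` declares the unit each dietary column is expressed in, so
    ingestion can rescale to the reference table's unit explicitly.
    """

    columns: dict = field(default_factory=dict)
    values: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnMapping":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            columns=data.get("columns", {}),
            values=data.get("values", {}),
            units=data.get("units", {}),
        )


def _read_raw(path: Path) -> pd.DataFrame:
    if path.suffix.lower() == ".xpt":
        frame = pd.read_sas(path, format="xport")
        for col in frame.columns:  # XPT character fields arrive as bytes
            if frame[col].dtype == object:
                frame[col] = frame[col].map(
                    lambda v: v.decode("ascii").strip() if isinstance(v, bytes) else v
                )
        return frame
    return pd.read_csv(path)


def read_participant_table(
    path: str | Path,
    mapping: ColumnMapping | str | Path | None = None,
    reference: ReferenceTable | None = None,
) -> pd.DataFrame:
    """Read and validate a participant table (CSV or SAS XPT).

    With a mapping, external columns are renamed, values recoded and dietary
    units rescaled to the reference table's units.  Raises
    :class:`ValidationReportError` listing every problem (unknown mapped
    columns, duplicate ids, negative or non-numeric intakes with their rows).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if mapping is not None and not isinstance(mapping, ColumnMapping):
        mapping = ColumnMapping.from_yaml(mapping)
    frame = _read_raw(path)
    errors: list[str] = []

    if mapping is not None:
        unknown = sorted(set(mapping.columns) - set(frame.columns))
        if unknown:
            errors.append(f"mapping references unknown columns: {unknown}")
        frame = frame.rename(columns={k: v for k, v in mapping.columns.items()
                                      if k in frame.columns})
        for col, recode in mapping.values.items():
            if col in frame.columns:
                frame[col] = frame[col].map(
                    lambda v, rc=recode: rc.get(v, rc.get(str(v), v))
                    if pd.notna(v) else v
                )
        if mapping.units:
            ref = reference if reference is not None else load_reference_table()
            for col, declared in mapping.units.items():
                if col not in frame.columns:
                    errors.append(f"unit declared for absent column {col!r}")
                    continue
                name = col[len(DIET_PREFIX):] if col.startswith(DIET_PREFIX) else col
                if name not in ref.names:
                    errors.append(f"unit declared for non-reference parameter {col!r}")
                    continue
                target = ref[name].unit
                factor = UNIT_FACTORS.get((str(declared), target))
                if factor is None:
                    errors.append(
                        f"{col!r}: no declared conversion {declared!r} -> {target!r}"
                    )
                    continue
                frame[col] = pd.to_numeric(frame[col], errors="coerce") * factor

    if "participant_id" not in frame.columns:
        errors.append("no 'participant_id' column after mapping")
    else:
        frame["participant_id"] = frame["participant_id"].astype(str)
        dupes = frame["participant_id"][frame["participant_id"].duplicated()]
        if len(dupes):
            errors.append(f"duplicate participant ids: {dupes.unique().tolist()[:10]}")

    diet_cols = [c for c in frame.columns if c.startswith(DIET_PREFIX)]
    for col in diet_cols:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad_text = frame[col].notna() & numeric.isna()
        for row in frame.index[bad_text][:5]:
            errors.append(f"row {row}, column {col!r}: non-numeric intake "
                          f"{frame.loc[row, col]!r}")
        negative = numeric < 0
        for row in frame.index[negative][:5]:
            errors.append(f"row {row}, column {col!r}: negative intake "
                          f"{numeric.loc[row]!r}")
        frame[col] = numeric

    for col in ("age", "bmi", "waist_cm"):
        if col in frame.columns:
            numeric = pd.to_numeric(frame[col], errors="coerce")
            bad = frame[col].notna() & numeric.isna()
            for row in frame.index[bad][:5]:
                errors.append(f"row {row}, column {col!r}: non-numeric value "
                              f"{frame.loc[row, col]!r}")
            frame[col] = numeric

    if errors:
        raise ValidationReportError(errors)
    return frame
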