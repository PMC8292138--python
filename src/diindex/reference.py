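"""Reference constants for Dietary Inflammatory Index scoring.

Each food parameter (a nutrient or dietary component) carries three
literature-derived constants: the global daily mean intake, its standard
deviation, and an overall inflammatory effect score in [-1, 1] (negative =
anti-inflammatory, positive = pro-inflammatory).  A default table covering
26 nutrient parameters ships with the package; any user-supplied table with
the same columns can be substituted, so no constant is hard-coded in logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "FoodParameterReference",
    "ReferenceTable",
    "load_reference_table",
    "default_reference_path",
    "REFERENCE_COLUMNS",
]

REFERENCE_COLUMNS = ("name", "unit", "global_mean", "global_sd", "effect_score")


class ReferenceTableError(ValueError):
    """Raised when a reference table violates its invariants."""


@dataclass(frozen=True)
class FoodParameterReference:
    """Scoring constants for a single food parameter.

    Parameters
    ----------
    name : str
        Canonical food-parameter identifier (e.g. ``"fiber"``).
    unit : str
        Per-day intake unit the constants are expressed in (g, mg, ug, kcal, RE).
    global_mean : float
        Global daily mean intake in ``unit``.
    global_sd : float
        Standard deviation of the global daily intake; must be positive.
    effect_score : float
        Dimensionless overall inflammatory effect score in [-1, 1].
    """

    name: str
    unit: str
    global_mean: float
    global_sd: float
    effect_score: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ReferenceTableError("food parameter name must be non-empty")
        if not (self.global_sd > 0):
            raise ReferenceTableError(
                f"{self.name!r}: global_sd must be > 0, got {self.global_sd}"
            )
        if abs(self.effect_score) > 1:
            raise ReferenceTableError(
                f"{self.name!r}: |effect_score| must be <= 1, got {self.effect_score}"
            )


class ReferenceTable(Mapping[str, FoodParameterReference]):
    """Immutable mapping of food-parameter name -> :class:`FoodParameterReference`."""

    def __init__(self, parameters: Iterable[FoodParameterReference]):
        params = list(parameters)
        names = [p.name for p in params]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ReferenceTableError(f"duplicate parameter names: {sorted(dupes)}")
        if not params:
            raise ReferenceTableError("reference table is empty")
        self._params = {p.name: p for p in params}

    def __getitem__(self, name: str) -> FoodParameterReference:
        return self._params[name]

    def __iter__(self):
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    @property
    def names(self) -> list[str]:
        return list(self._params)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (p.name, p.unit, p.global_mean, p.global_sd, p.effect_score)
                for p in self._params.values()
            ],
            columns=list(REFERENCE_COLUMNS),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReferenceTable":
        missing = set(REFERENCE_COLUMNS) - set(frame.columns)
        if missing:
            raise ReferenceTableError(f"reference table missing columns: {sorted(missing)}")
        params = [
            FoodParameterReference(
                name=str(row["name"]),
                unit=str(row["unit"]),
                global_mean=float(row["global_mean"]),
                global_sd=float(row["global_sd"]),
                effect_score=float(row["effect_score"]),
            )
            for _, row in frame.iterrows()
        ]
        return cls(params)


def default_reference_path() -> Path:
    """Path to the bundled 26-parameter reference table."""
    return Path(resources.files("diindex") / "data" / "dii_reference_26.csv")


def load_reference_table(path: str | Path | None = None) -> ReferenceTable:
    """Load a reference table from ``path`` (default: the bundled 26-parameter table)."""
    src = Path(path) if path is not None else default_reference_path()
    frame = pd.read_csv(src)
    return ReferenceTable.from_frame(frame)
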