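"""Synthetic person generation: female sex, birthdate, DIVIPOLA location.

Municipalities are drawn proportional to population weights keyed by
DIVIPOLA codes (Colombia's political-administrative division: 2-digit
department, 5-digit municipality whose first two digits are the
department).  A 30-municipality fixture with plausible relative weights
ships in-repo as a synthetic stand-in for the national census; real
census data can be supplied as a CSV with the same three columns.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .engine import REFERENCE_DATE, Event

__all__ = [
    "PersonRecord",
    "LocationWeights",
    "load_weights",
    "default_weights",
    "sample_person",
    "filter_department",
]

DEFAULT_AGE_RANGE = (15, 49)


@dataclass
class PersonRecord:
    """One synthetic woman: demographics, location and her event log."""

    person_id: int
    sex: str
    birthdate: datetime.date
    municipality: str
    department: str
    events: list[Event] = field(default_factory=list)


class LocationWeights:
    """Normalized municipality sampling weights keyed by DIVIPOLA codes."""

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        table["municipality"] = table["municipality"].astype(str).str.zfill(5)
        table["department"] = table["department"].astype(str).str.zfill(2)
        table["weight"] = table["weight"].astype(float)
        if len(table) == 0:
            raise ValueError("weight table is empty")
        if (table["weight"] < 0).any():
            bad = table.loc[table["weight"] < 0, "municipality"].tolist()
            raise ValueError(f"negative weights for municipalities {bad}")
        total = table["weight"].sum()
        if total <= 0:
            raise ValueError("weights sum to zero")
        if table["municipality"].duplicated().any():
            dup = table.loc[table["municipality"].duplicated(), "municipality"].tolist()
            raise ValueError(f"duplicate municipality codes {dup}")
        mismatch = table["municipality"].str[:2] != table["department"]
        if mismatch.any():
            bad = table.loc[mismatch, "municipality"].tolist()
            raise ValueError(
                f"municipality codes {bad} do not start with their department code"
            )
        table["weight"] = table["weight"] / total
        self.table = table.reset_index(drop=True)
        self._codes = self.table["municipality"].to_numpy()
        self._departments = self.table["department"].to_numpy()
        self._weights = self.table["weight"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    @property
    def departments(self) -> list[str]:
        return sorted(self.table["department"].unique())

    def department_weights(self) -> pd.Series:
        """Total normalized weight per department, indexed by code."""
        return self.table.groupby("department")["weight"].sum().sort_index()

    def sample_municipality(self, rng: np.random.Generator) -> tuple[str, str]:
        idx = int(rng.choice(len(self._codes), p=self._weights))
        return str(self._codes[idx]), str(self._departments[idx])


def load_weights(path: Union[str, Path]) -> LocationWeights:
    """Read a ``municipality,department,weight`` CSV into normalized weights."""
    frame = pd.read_csv(path, dtype={"municipality": str, "department": str})
    expected = {"municipality", "department", "weight"}
    if not expected.issubset(frame.columns):
        raise ValueError(
            f"weights CSV must have columns {sorted(expected)}, got {list(frame.columns)}"
        )
    return LocationWeights(frame)


def default_weights() -> LocationWeights:
    """The bundled 30-municipality synthetic census stand-in."""
    with resources.as_file(
        resources.files("gestasynth.data").joinpath("synthetic_municipality_weights.csv")
    ) as path:
        return load_weights(path)


def filter_department(weights: LocationWeights, department: str) -> LocationWeights:
    """Restrict to one department and renormalize."""
    department = str(department).zfill(2)
    subset = weights.table[weights.table["department"] == department]
    if len(subset) == 0:
        raise ValueError(
            f"department {department!r} not present; known: {weights.departments}"
        )
    return LocationWeights(subset)


def sample_person(
    weights: LocationWeights,
    rng: np.random.Generator,
    person_id: int = 0,
    *,
    age_range: tuple[int, int] = DEFAULT_AGE_RANGE,
    reference_date: datetime.date = REFERENCE_DATE,
) -> PersonRecord:
    """Draw one woman: municipality proportional to weight, age uniform on
    ``age_range`` (whole years, plus a uniform day-of-year offset)."""
    municipality, department = weights.sample_municipality(rng)
    lo, hi = age_range
    age_years = int(rng.integers(lo, hi + 1))
    extra_days = int(rng.integers(0, 365))
    birthdate = reference_date - datetime.timedelta(days=age_years * 365 + extra_days)
    return PersonRecord(
        person_id=person_id,
        sex="F",
        birthdate=birthdate,
        municipality=municipality,
        department=department,
    )
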