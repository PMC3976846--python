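"""Hierarchical feature representation of clinical symptom data.

A clinical observation table (samples x symptoms, non-negative integer
positivity levels, plus one real "positive score" per sample) is aggregated
into a three-layer tree:

* leaves   — the raw symptom columns;
* middle   — one *syndrome* feature per symptom group;
* root     — the per-patient positive score (the regression target).

Two aggregation rules exist, depending on whether the symptoms in a group can
co-occur on one patient:

* **mutually-exclusive** groups (e.g. the four possible lip colors) collapse
  to a single categorical code 0..m, where 0 means "no member positive" and
  the codes 1..m are assigned by positivity frequency — the symptom positive
  in more patients receives the larger code;
* **concurrent** groups (e.g. the emotional symptoms irritability,
  depression, sigh) collapse to the row sum of their members, a cumulative
  positive strength.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SymptomTable",
    "GroupSpec",
    "FeatureHierarchy",
    "ExclusivityViolation",
    "PartitionError",
    "extract_exclusive_syndrome",
    "extract_concurrent_syndrome",
    "build_hierarchy",
    "read_symptom_table",
    "write_symptom_table",
    "read_group_specs",
    "write_group_specs",
]

POSITIVE_SCORE_COLUMN = "positive_score"


class ExclusivityViolation(ValueError):
    """Two members of a mutually-exclusive group are positive in one row."""


class PartitionError(ValueError):
    """Group membership does not partition the symptom columns."""


@dataclass
class SymptomTable:
    """Samples x symptoms matrix of non-negative integers plus target score.

    Parameters
    ----------
    values
        (n_samples, n_symptoms) array of non-negative integer positivity
        levels (0 = not positive; larger = stronger).
    positive_score
        (n_samples,) non-negative reals: the total positivity evaluation of
        each patient, used as the regression target.
    column_names
        Unique symptom identifiers, one per column of ``values``.
    """

    values: np.ndarray
    positive_score: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.positive_score = np.asarray(self.positive_score, dtype=float)
        self.column_names = list(self.column_names)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if np.any(self.values < 0):
            raise ValueError("symptom values must be non-negative")
        if np.any(self.positive_score < 0):
            raise ValueError("positive scores must be non-negative")
        if len(self.positive_score) != self.values.shape[0]:
            raise ValueError("positive_score length must equal sample count")
        if len(self.column_names) != self.values.shape[1]:
            raise ValueError("one column name per symptom column required")
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("symptom column names must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_symptoms(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df[POSITIVE_SCORE_COLUMN] = self.positive_score
        return df


@dataclass
class GroupSpec:
    """One named symptom group of the middle layer.

    ``exclusive`` marks mutually-exclusive groups; for those, ``code_map``
    (symptom name -> positive integer code) is learned from data by
    :func:`extract_exclusive_syndrome` and persisted alongside the grouping.
    """

    group_name: str
    member_columns: list[str]
    exclusive: bool = False
    code_map: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.member_columns = list(self.member_columns)
        if not self.member_columns:
            raise ValueError(f"group {self.group_name!r} has no members")
        if self.code_map is not None:
            self._check_code_map()

    def _check_code_map(self) -> None:
        assert self.code_map is not None
        if set(self.code_map) != set(self.member_columns):
            raise ValueError("code_map keys must equal the member set")
        codes = sorted(self.code_map.values())
        if codes != list(range(1, len(self.member_columns) + 1)):
            raise ValueError("codes must be a permutation of 1..|members|")


@dataclass
class FeatureHierarchy:
    """Three-layer tree: positive score / syndromes / symptoms."""

    table: SymptomTable
    groups: list[GroupSpec]
    syndrome_values: np.ndarray = field(repr=False)

    @property
    def syndrome_names(self) -> list[str]:
        return [g.group_name for g in self.groups]

    @property
    def n_syndromes(self) -> int:
        return len(self.groups)

    def syndrome_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.syndrome_values, columns=self.syndrome_names)
        df[POSITIVE_SCORE_COLUMN] = self.table.positive_score
        return df


def extract_exclusive_syndrome(
    columns: np.ndarray,
    positive_score: np.ndarray,
    member_names: Sequence[str],
) -> tuple[np.ndarray, dict[str, int]]:
    """Collapse a mutually-exclusive group to one categorical code column.

    A row with no positive member maps to 0; a row whose (single) positive
    member is symptom ``s`` maps to ``code_map[s]``.  Codes 1..m are assigned
    by positivity frequency: the symptom positive in more patients gets the
    larger code.  Frequency ties are broken by the larger mean positive score
    over that symptom's positive patients, and remaining ties by column
    order (earlier column ranks higher).

    Raises
    ------
    ExclusivityViolation
        If any row has two or more positive members (the first offending row
        index is named in the message).
    ValueError
        If a member column is non-binary: the exclusive coding is only
        defined for occurrence/non-occurrence indicators.
    """
    columns = np.asarray(columns)
    positive_score = np.asarray(positive_score, dtype=float)
    m = columns.shape[1]
    if len(member_names) != m:
        raise ValueError("one name per member column required")
    if np.any((columns != 0) & (columns != 1)):
        raise ValueError(
            "exclusive-group members must be binary occurrence indicators"
        )
    positive = columns > 0
    per_row = positive.sum(axis=1)
    bad = np.nonzero(per_row > 1)[0]
    if bad.size:
        raise ExclusivityViolation(
            f"row {bad[0]}: {per_row[bad[0]]} members of an exclusive group "
            "are simultaneously positive"
        )

    counts = positive.sum(axis=0)
    mean_ps = np.array(
        [positive_score[positive[:, j]].mean() if counts[j] else 0.0
         for j in range(m)]
    )
    # ascending sort; code 1 goes to the least frequent member, code m to the
    # most frequent; -j makes the earlier column win full ties (larger code)
    order = sorted(range(m), key=lambda j: (counts[j], mean_ps[j], -j))
    code_map = {member_names[j]: rank + 1 for rank, j in enumerate(order)}

    codes = np.array([code_map[name] for name in member_names])
    syndrome = np.where(per_row == 0, 0, positive @ codes)
    return syndrome.astype(int), code_map


def extract_concurrent_syndrome(columns: np.ndarray) -> np.ndarray:
    """Collapse a concurrent group to the cumulative row sum of its members."""
    columns = np.asarray(columns)
    if np.any(columns < 0):
        raise ValueError("symptom values must be non-negative")
    return columns.sum(axis=1).astype(int)


def build_hierarchy(
    table: SymptomTable, groups: Sequence[GroupSpec]
) -> FeatureHierarchy:
    """Compute every syndrome column and assemble the three-layer hierarchy.

    The groups' member lists must partition the table's symptom columns
    exactly.  Learned exclusive code maps are written back onto the returned
    hierarchy's group specs; the input table is left untouched.
    """
    assigned: dict[str, str] = {}
    for g in groups:
        for col in g.member_columns:
            if col in assigned:
                raise PartitionError(
                    f"symptom {col!r} assigned to both {assigned[col]!r} "
                    f"and {g.group_name!r}"
                )
            if col not in table.column_names:
                raise PartitionError(f"symptom {col!r} not in the table")
            assigned[col] = g.group_name
    missing = set(table.column_names) - set(assigned)
    if missing:
        raise PartitionError(f"symptoms not assigned to any group: {sorted(missing)}")

    out_groups: list[GroupSpec] = []
    syndrome_cols: list[np.ndarray] = []
    for g in groups:
        idx = [table.column_names.index(c) for c in g.member_columns]
        sub = table.values[:, idx]
        if g.exclusive:
            col, code_map = extract_exclusive_syndrome(
                sub, table.positive_score, g.member_columns
            )
            out_groups.append(
                GroupSpec(g.group_name, g.member_columns, True, code_map)
            )
        else:
            col = extract_concurrent_syndrome(sub)
            out_groups.append(GroupSpec(g.group_name, g.member_columns, False))
        syndrome_cols.append(col)
    return FeatureHierarchy(table, out_groups, np.column_stack(syndrome_cols))


# ---------------------------------------------------------------------------
# serialization


def read_symptom_table(path: str | Path) -> SymptomTable:
    """Read a CSV whose last column is ``positive_score``."""
    df = pd.read_csv(path)
    if POSITIVE_SCORE_COLUMN not in df.columns:
        raise ValueError(f"CSV must contain a {POSITIVE_SCORE_COLUMN!r} column")
    score = df.pop(POSITIVE_SCORE_COLUMN).to_numpy(dtype=float)
    return SymptomTable(df.to_numpy(dtype=int), score, list(df.columns))


def write_symptom_table(table: SymptomTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def _spec_to_dict(g: GroupSpec) -> dict:
    d: dict = {
        "group_name": g.group_name,
        "members": g.member_columns,
        "exclusive": g.exclusive,
    }
    if g.code_map is not None:
        d["code_map"] = g.code_map
    return d


def read_group_specs(path: str | Path) -> list[GroupSpec]:
    """Read a grouping JSON: a list of group objects, or {"groups": [...]}."""
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, Mapping):
        payload = payload["groups"]
    return [
        GroupSpec(
            d["group_name"],
            d["members"],
            bool(d.get("exclusive", False)),
            d.get("code_map"),
        )
        for d in payload
    ]


def write_group_specs(groups: Sequence[GroupSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"groups": [_spec_to_dict(g) for g in groups]}, fh, indent=1)
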