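"""Mixed-type cohort container: a subject x variable table plus a roster.

The roster declares, for every column, its role in the analysis
(``symptom``, ``metabolite``, ``risk_factor`` or ``covariate``) and its
statistical type (``gaussian``, ``ordinal`` or ``categorical``).  All
downstream stages (imputation, covariate adjustment, network estimation,
bridge scoring) consume this container rather than a bare DataFrame so that
role/type information travels with the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ROLES = ("symptom", "metabolite", "risk_factor", "covariate")
TYPES = ("gaussian", "ordinal", "categorical")


@dataclass(frozen=True)
class Roster:
    """Per-variable metadata: role, statistical type and level count.

    ``levels`` is the number of categories for ordinal/categorical
    variables and 0 for gaussian ones.
    """

    table: pd.DataFrame  # columns: variable, role, type, levels

    def __post_init__(self) -> None:
        required = {"variable", "role", "type", "levels"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"roster missing columns: {sorted(missing)}")
        bad_roles = set(self.table["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles in roster: {sorted(bad_roles)}")
        bad_types = set(self.table["type"]) - set(TYPES)
        if bad_types:
            raise ValueError(f"unknown types in roster: {sorted(bad_types)}")
        if self.table["variable"].duplicated().any():
            raise ValueError("duplicate variable names in roster")

    @property
    def variables(self) -> list[str]:
        return list(self.table["variable"])

    def role_of(self, variable: str) -> str:
        return self._lookup(variable, "role")

    def type_of(self, variable: str) -> str:
        return self._lookup(variable, "type")

    def levels_of(self, variable: str) -> int:
        return int(self._lookup(variable, "levels"))

    def _lookup(self, variable: str, col: str):
        rows = self.table.loc[self.table["variable"] == variable, col]
        if rows.empty:
            raise KeyError(f"variable {variable!r} not in roster")
        return rows.iloc[0]

    def by_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return list(self.table.loc[self.table["role"] == role, "variable"])

    @classmethod
    def from_records(cls, records: list[tuple[str, str, str, int]]) -> "Roster":
        return cls(pd.DataFrame(records, columns=["variable", "role", "type", "levels"]))


@dataclass
class MixedDataset:
    """Subject x variable table with roster and missingness mask."""

    frame: pd.DataFrame
    roster: Roster
    _mask: pd.DataFrame = field(default=None, repr=False)  # True = missing

    def __post_init__(self) -> None:
        roster_vars = set(self.roster.variables)
        frame_vars = set(self.frame.columns)
        if roster_vars != frame_vars:
            extra = sorted(frame_vars - roster_vars)
            lacking = sorted(roster_vars - frame_vars)
            raise ValueError(
                f"frame/roster mismatch: columns not in roster {extra}, "
                f"roster variables not in frame {lacking}"
            )
        if self._mask is None:
            self._mask = self.frame.isna()

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self._mask

    @property
    def n_missing(self) -> int:
        return int(self.frame.isna().sum().sum())

    def variables(self, role: str | None = None) -> list[str]:
        if role is None:
            return self.roster.variables
        return self.roster.by_role(role)

    def copy_with(self, frame: pd.DataFrame) -> "MixedDataset":
        return MixedDataset(frame=frame, roster=self.roster)

    # ------------------------------------------------------------------ I/O

    def write(self, cohort_path: str | Path, roster_path: str | Path) -> None:
        """Write cohort as CSV and roster as TSV."""
        self.frame.to_csv(cohort_path, index=False)
        self.roster.table.to_csv(roster_path, sep="\t", index=False)

    @classmethod
    def read(cls, cohort_path: str | Path, roster_path: str | Path) -> "MixedDataset":
        frame = pd.read_csv(cohort_path)
        roster = Roster(pd.read_csv(roster_path, sep="\t"))
        return cls(frame=frame, roster=roster)


def check_complete(data: MixedDataset, stage: str) -> None:
    """Raise if the dataset still has missing entries (upstream contract)."""
    missing = data.frame.columns[data.frame.isna().any()].tolist()
    if missing:
        raise ValueError(f"{stage} requires complete data; missing values in {missing}")


def numeric_matrix(data: MixedDataset, columns: list[str] | None = None) -> np.ndarray:
    cols = columns if columns is not None else data.roster.variables
    return data.frame[cols].to_numpy(dtype=float)
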