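"""Loading and preparation of interbeat-interval (IBI) tables.

Input is a long-format table (``ibi.csv``) with one beat per row:
``group_id, member_id, study, condition, phase, beat_index, ibi_s``.
Groups are triads; a group is analysed only when all 3 members have both
a baseline and a task segment, otherwise it is excluded with a warning.

Series within a dyad or triad are equalized in length by trimming the
longer series to the shortest one, removing excess points at the end.
Trimming happens per analysis unit: a dyad is trimmed to its own pair
minimum, not to the triad-wide minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "IBISeries",
    "GroupRecord",
    "PHASES",
    "load_ibi_table",
    "trim_to_shortest",
    "assemble_level_inputs",
]

PHASES = ("baseline", "task")
IBI_COLUMNS = ["group_id", "member_id", "study", "condition", "phase", "beat_index", "ibi_s"]


@dataclass(frozen=True)
class IBISeries:
    """One participant-phase sequence of interbeat intervals (seconds)."""

    values: np.ndarray
    group_id: str
    member_id: int
    phase: str
    study: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("IBI series must be a non-empty 1-d array")
        if np.any(vals <= 0):
            raise ValueError(
                f"non-positive IBI in group={self.group_id} member={self.member_id} "
                f"phase={self.phase}"
            )

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class GroupRecord:
    """A triad: three members, each with baseline and task IBI series."""

    group_id: str
    study: str
    condition: str
    series: dict[tuple[int, str], IBISeries] = field(repr=False)
    is_surrogate: bool = False

    def __post_init__(self) -> None:
        members = self.member_ids
        if len(members) != 3:
            raise ValueError(f"group {self.group_id} has {len(members)} members, expected 3")
        for mid in members:
            for phase in PHASES:
                if (mid, phase) not in self.series:
                    raise ValueError(
                        f"group {self.group_id} member {mid} is missing phase {phase!r}"
                    )

    @property
    def member_ids(self) -> tuple[int, ...]:
        return tuple(sorted({mid for mid, _ in self.series}))

    def member_phase(self, member_id: int, phase: str) -> IBISeries:
        return self.series[(member_id, phase)]


def load_ibi_table(path: str | Path) -> list[GroupRecord]:
    """Read an ``ibi.csv`` long table into GroupRecords.

    Groups without exactly 3 members or with a missing phase are excluded
    with a warning; an empty file yields an empty list and a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in IBI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: empty IBI table", stacklevel=2)
        return []

    bad_phase = ~df["phase"].isin(PHASES)
    if bad_phase.any():
        line = int(df.index[bad_phase][0]) + 2  # +1 header, +1 zero-based
        raise ValueError(f"{path}: invalid phase {df.loc[bad_phase, 'phase'].iloc[0]!r} at line {line}")
    if df["ibi_s"].isna().any():
        line = int(df.index[df["ibi_s"].isna()][0]) + 2
        raise ValueError(f"{path}: missing ibi_s value at line {line}")

    records: list[GroupRecord] = []
    for gid, gdf in df.groupby("group_id", sort=True):
        members = sorted(gdf["member_id"].unique())
        have = {
            (int(mid), phase)
            for (mid, phase), _ in gdf.groupby(["member_id", "phase"], sort=False)
        }
        complete = len(members) == 3 and all(
            (int(mid), phase) in have for mid in members for phase in PHASES
        )
        if not complete:
            warnings.warn(
                f"excluding group {gid!r}: incomplete data "
                f"(members={members}, segments={len(have)})",
                stacklevel=2,
            )
            continue
        series: dict[tuple[int, str], IBISeries] = {}
        for (mid, phase), sdf in gdf.groupby(["member_id", "phase"], sort=False):
            sdf = sdf.sort_values("beat_index")
            idx = sdf["beat_index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                raise ValueError(
                    f"{path}: beat_index not contiguous from 0 for group {gid!r} "
                    f"member {mid} phase {phase}"
                )
            series[(int(mid), str(phase))] = IBISeries(
                values=sdf["ibi_s"].to_numpy(),
                group_id=str(gid),
                member_id=int(mid),
                phase=str(phase),
                study=str(sdf["study"].iloc[0]),
                condition=str(sdf["condition"].iloc[0]),
            )
        records.append(
            GroupRecord(
                group_id=str(gid),
                study=str(gdf["study"].iloc[0]),
                condition=str(gdf["condition"].iloc[0]),
                series=series,
            )
        )
    return records


def trim_to_shortest(series: list[IBISeries]) -> list[IBISeries]:
    """Trim all series to the shortest length by dropping trailing points."""
    if len(series) < 2:
        raise ValueError("need at least 2 series to trim")
    n_min = min(len(s) for s in series)
    if n_min == 0:
        raise ValueError("cannot trim empty series")
    return [
        s if len(s) == n_min else replace(s, values=s.values[:n_min]) for s in series
    ]


def assemble_level_inputs(
    group: GroupRecord, level: str, phase: str
) -> list[tuple[tuple[int, ...], np.ndarray]]:
    """Build the multivariate arrays analysed at a given level.

    ``level='triad'``: one ``(n, 3)`` array, trimmed to the triad minimum.
    ``level='dyad'``: three ``(n_pair, 2)`` arrays for member pairs
    (A,B), (A,C), (B,C), each trimmed within its own pair.
    Returns ``(member_ids, array)`` tuples.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    members = group.member_ids
    if level == "triad":
        trimmed = trim_to_shortest([group.member_phase(m, phase) for m in members])
        return [(members, np.column_stack([s.values for s in trimmed]))]
    if level == "dyad":
        out = []
        for a, b in combinations(members, 2):
            trimmed = trim_to_shortest(
                [group.member_phase(a, phase), group.member_phase(b, phase)]
            )
            out.append(((a, b), np.column_stack([s.values for s in trimmed])))
        return out
    raise ValueError(f"unknown level {level!r}; expected 'dyad' or 'triad'")
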