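"""Deletion records and per-end breakpoint sets.

A deletion is a pair of 1-based genomic coordinates: the 5' breakpoint
(``bp5``) and the 3' breakpoint (``bp3``), where the DNA rejoins after loss
of the intervening segment.  Statistics operate on the deduplicated set of
breakpoints at each end separately, with optional subgrouping by clinical or
other labels carried as extra table columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class DeletionTableError(ValueError):
    """Raised for malformed deletion tables."""


@dataclass(frozen=True)
class DeletionRecord:
    id: str
    bp5: int
    bp3: int
    groups: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class BreakpointSet:
    """Deduplicated breakpoint positions for one deletion end."""

    end: str  # "five_prime" | "three_prime"
    positions: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.positions)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.positions, dtype=float)


_END_ALIASES = {
    "5p": "five_prime", "five_prime": "five_prime", "5": "five_prime",
    "3p": "three_prime", "three_prime": "three_prime", "3": "three_prime",
}


def _normalize_end(end: str) -> str:
    try:
        return _END_ALIASES[str(end)]
    except KeyError:
        raise ValueError(f"unknown breakpoint end {end!r}; use '5p' or '3p'")


def read_deletions(path: str | Path, L: int | None = None) -> list[DeletionRecord]:
    """Read a TSV/CSV deletion table with columns id, bp5, bp3.

    Extra columns become group labels.  Coordinates are validated against the
    genome length when ``L`` is given; bad rows are reported together.
    """
    df = pd.read_csv(path, sep=r"[\t,]", engine="python", dtype=str)
    required = {"id", "bp5", "bp3"}
    missing = required - set(df.columns)
    if missing:
        raise DeletionTableError(f"{path}: missing columns {sorted(missing)}")
    extra = [c for c in df.columns if c not in required]
    bad_rows: list[str] = []
    records: list[DeletionRecord] = []
    seen_ids: set[str] = set()
    for i, row in df.iterrows():
        rid = str(row["id"])
        try:
            bp5, bp3 = int(row["bp5"]), int(row["bp3"])
        except (TypeError, ValueError):
            bad_rows.append(f"row {i}: non-integer coordinates "
                            f"({row['bp5']!r}, {row['bp3']!r})")
            continue
        if rid in seen_ids:
            bad_rows.append(f"row {i}: duplicate id {rid!r}")
            continue
        lo, hi = 1, (L if L is not None else max(bp5, bp3))
        if not (lo <= bp5 <= hi and lo <= bp3 <= hi):
            bad_rows.append(f"row {i}: coordinates out of range [1, {hi}] "
                            f"({bp5}, {bp3})")
            continue
        if bp5 == bp3:
            bad_rows.append(f"row {i}: bp5 == bp3 ({bp5})")
            continue
        seen_ids.add(rid)
        groups = {c: row[c] for c in extra if pd.notna(row[c])}
        records.append(DeletionRecord(id=rid, bp5=bp5, bp3=bp3, groups=groups))
    if bad_rows:
        raise DeletionTableError(f"{path}: invalid rows:\n  " + "\n  ".join(bad_rows))
    for rec in records:
        if rec.bp5 > rec.bp3:
            warnings.warn(
                f"deletion {rec.id}: bp5 ({rec.bp5}) > bp3 ({rec.bp3}); "
                "accepted as given (no origin normalization is attempted)"
            )
    return records


def write_deletions(records: Sequence[DeletionRecord], path: str | Path) -> None:
    labels = sorted({k for r in records for k in r.groups})
    rows = [dict(id=r.id, bp5=r.bp5, bp3=r.bp3,
                 **{k: r.groups.get(k, "") for k in labels})
            for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def unique_breakpoints(deletions: Sequence[DeletionRecord], end: str) -> BreakpointSet:
    """Deduplicated positions of one deletion end across a record list."""
    if not deletions:
        raise ValueError("deletion list is empty")
    end = _normalize_end(end)
    attr = "bp5" if end == "five_prime" else "bp3"
    positions = tuple(sorted({getattr(d, attr) for d in deletions}))
    return BreakpointSet(end=end, positions=positions)


def filter_by_group(deletions: Sequence[DeletionRecord], label: str,
                    value: str) -> list[DeletionRecord]:
    """Records whose group ``label`` equals ``value``; order preserved."""
    known = {k for d in deletions for k in d.groups}
    if label not in known:
        raise KeyError(f"unknown group label {label!r}; known: {sorted(known)}")
    return [d for d in deletions if str(d.groups.get(label)) == str(value)]


def breakpoint_arrays(deletions: Sequence[DeletionRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(bp5, bp3) as integer arrays, one entry per record (no deduplication)."""
    bp5 = np.asarray([d.bp5 for d in deletions], dtype=np.int64)
    bp3 = np.asarray([d.bp3 for d in deletions], dtype=np.int64)
    return bp5, bp3


def write_breakpoint_set(bset: BreakpointSet, path: str | Path) -> None:
    pd.DataFrame({"end": bset.end, "position": list(bset.positions)}).to_csv(
        path, sep="\t", index=False
    )
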