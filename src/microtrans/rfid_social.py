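"""Nest-box visit reconstruction and social-contact matrices.

Each nest-box entrance carries two transponder readers.  A mouse entering
triggers the outer reader first, then the inner one; on leaving the order is
reversed (inner, then outer).  A *visit* is the interval between a completed
entry pair and the next completed exit pair for the same mouse at the same
box.  Social contact between two mice is the total time they were
simultaneously inside any nest box, regardless of who else was present.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventRecord",
    "Visit",
    "ContactMatrix",
    "ParseReport",
    "parse_visits",
    "contact_matrix",
    "read_events_csv",
    "write_events_csv",
]

OUTER = "outer"
INNER = "inner"


@dataclass(frozen=True)
class EventRecord:
    """One antenna detection: which mouse, which box, which reader, when."""

    timestamp: float
    mouse_id: str
    nestbox_id: str
    reader: str

    def __post_init__(self) -> None:
        if self.reader not in (OUTER, INNER):
            raise ValueError(f"reader must be 'outer' or 'inner', got {self.reader!r}")
        if self.timestamp < 0:
            raise ValueError("timestamp must be >= 0")


@dataclass(frozen=True)
class Visit:
    """A reconstructed stay of one mouse in one nest box.

    Start and end are anchored at the inner-reader timestamps: the moment the
    mouse is fully inside, and the last moment it is still inside.
    """

    mouse_id: str
    nestbox_id: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("visit end must be after start")


@dataclass
class ParseReport:
    records_total: int = 0
    records_discarded: int = 0
    duplicates_removed: int = 0
    visits_emitted: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


@dataclass
class ContactMatrix:
    """Symmetric individual × individual co-occupancy time in seconds."""

    individuals: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individuals)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match individual list")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("contact matrix must be symmetric")
        if (self.values < 0).any():
            raise ValueError("contact times must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individuals, columns=self.individuals)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ContactMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def _dedup(events: Sequence[EventRecord]) -> tuple[list[EventRecord], int]:
    seen: set[tuple] = set()
    out: list[EventRecord] = []
    dups = 0
    for e in events:
        key = (e.timestamp, e.mouse_id, e.nestbox_id, e.reader)
        if key in seen:
            dups += 1
            continue
        seen.add(key)
        out.append(e)
    return out, dups


def _merge_intervals(iv: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not iv:
        return []
    iv = sorted(iv)
    merged = [iv[0]]
    for s, e in iv[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def parse_visits(events: Iterable[EventRecord]) -> tuple[list[Visit], ParseReport]:
    """Reconstruct visits from a dual-reader event stream.

    Per (mouse, box) the time-ordered reader sequence is scanned with a small
    state machine: outer→inner opens a visit, the next inner→outer closes it.
    Out-of-pattern reads are skipped forward (greedy resynchronisation) and
    counted in the report rather than aborting the stream — real RFID logs
    drop reads.  Exact duplicate records are removed silently and counted.
    """
    events = list(events)
    report = ParseReport(records_total=len(events))
    events, dups = _dedup(events)
    report.duplicates_removed = dups

    by_key: dict[tuple[str, str], list[EventRecord]] = {}
    for e in events:
        by_key.setdefault((e.mouse_id, e.nestbox_id), []).append(e)

    visits: list[Visit] = []
    discarded = 0
    for (mouse, box), evs in sorted(by_key.items()):
        evs.sort(key=lambda e: e.timestamp)
        state = "outside"
        start = None  # inner timestamp of the entry
        pending_end = None  # inner timestamp of a candidate exit
        entry_outer_seen = False
        raw: list[tuple[float, float]] = []
        for e in evs:
            if state == "outside":
                if e.reader == OUTER:
                    state = "entering"
                    entry_outer_seen = True
                else:
                    discarded += 1
            elif state == "entering":
                if e.reader == INNER:
                    start = e.timestamp
                    state = "inside"
                else:
                    # another outer read: drop the earlier one, stay waiting
                    discarded += 1
            elif state == "inside":
                if e.reader == INNER:
                    pending_end = e.timestamp
                    state = "exiting"
                else:
                    # an outer read cannot occur mid-visit: the exit pair was
                    # lost, so drop the open visit and treat this read as a
                    # candidate entry outer
                    discarded += 2
                    start = None
                    state = "entering"
            elif state == "exiting":
                if e.reader == OUTER:
                    if pending_end is not None and pending_end > start:
                        raw.append((start, pending_end))
                    else:
                        discarded += 2  # degenerate zero-length visit
                    state = "outside"
                    start = pending_end = None
                else:
                    # repeated inner read: keep the latest as candidate exit
                    discarded += 1
                    pending_end = e.timestamp
        if state != "outside":
            # truncated trailing pattern
            discarded += {"entering": 1, "inside": 2, "exiting": 3}[state]
        # overlap can only arise after resynchronisation; union to avoid
        # double counting in co-occupancy
        for s, t in _merge_intervals(raw):
            visits.append(Visit(mouse, box, s, t))

    visits.sort(key=lambda v: (v.start, v.mouse_id, v.nestbox_id))
    report.records_discarded = discarded
    report.visits_emitted = len(visits)
    return visits, report


def _intersect_length(a: list[tuple[float, float]], b: list[tuple[float, float]]) -> float:
    i = j = 0
    total = 0.0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            total += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def contact_matrix(visits: Iterable[Visit], individuals: Sequence[str]) -> ContactMatrix:
    """Total pairwise co-occupancy time, summed over nest boxes.

    Entry (i, j) is the length of the intersection of i's and j's visit
    interval unions within each box, summed over boxes.  Purely pairwise: no
    adjustment for additional animals present.
    """
    individuals = [str(i) for i in individuals]
    index = {m: k for k, m in enumerate(individuals)}
    per_box: dict[str, dict[str, list[tuple[float, float]]]] = {}
    for v in visits:
        if v.mouse_id not in index:
            raise ValueError(f"individual {v.mouse_id!r} in visits but not in id list")
        per_box.setdefault(v.nestbox_id, {}).setdefault(v.mouse_id, []).append((v.start, v.end))

    n = len(individuals)
    mat = np.zeros((n, n))
    for box_map in per_box.values():
        mice = sorted(box_map)
        merged = {m: _merge_intervals(box_map[m]) for m in mice}
        for a_i in range(len(mice)):
            for b_i in range(a_i + 1, len(mice)):
                t = _intersect_length(merged[mice[a_i]], merged[mice[b_i]])
                if t > 0:
                    ia, ib = index[mice[a_i]], index[mice[b_i]]
                    mat[ia, ib] += t
                    mat[ib, ia] += t
    return ContactMatrix(individuals, mat)


def read_events_csv(path: str | Path) -> list[EventRecord]:
    df = pd.read_csv(path)
    return [
        EventRecord(float(r.timestamp_s), str(r.mouse_id), str(r.nestbox_id), str(r.reader))
        for r in df.itertuples(index=False)
    ]


def write_events_csv(events: Sequence[EventRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "timestamp_s": [e.timestamp for e in events],
            "mouse_id": [e.mouse_id for e in events],
            "nestbox_id": [e.nestbox_id for e in events],
            "reader": [e.reader for e in events],
        }
    ).to_csv(path, index=False)
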