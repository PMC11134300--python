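"""Pedigree-based additive relatedness and dyad classification.

The relatedness between two individuals is the entry of the numerator
relationship matrix A, built from the parentage table by the recursive
tabular method.  Diagonal entries are 1 + F (inbreeding coefficient), so
relatedness can exceed 1 under inbreeding; parent–offspring and full-sib
pairs in a non-inbred pedigree have r = 0.5.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeTable",
    "RelatednessMatrix",
    "additive_relationship",
    "classify_dyads",
    "UNRELATED_THRESHOLD",
]

#: default relatedness cut-off below which a pair counts as unrelated
UNRELATED_THRESHOLD = 0.25

_UNKNOWN = {"", "NA", "nan", "None", "0", "unknown"}


def _is_unknown(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or str(v) in _UNKNOWN


@dataclass
class PedigreeTable:
    """Parentage table: one row per individual with dam/sire (or unknown)."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("id", "dam", "sire", "sex", "subspecies", "birth_day")

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in ("id", "dam", "sire") if c not in df.columns]
        if missing:
            raise ValueError(f"pedigree table missing columns {missing}")
        for c in ("sex", "subspecies", "deme"):
            if c not in df.columns:
                df[c] = ""
        if "birth_day" not in df.columns:
            df["birth_day"] = 0.0
        df["id"] = df["id"].astype(str)
        for c in ("dam", "sire"):
            df[c] = df[c].map(lambda v: None if _is_unknown(v) else str(v))
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate individual ids: {dupes}")
        ids = set(df["id"])
        for c in ("dam", "sire"):
            bad = [p for p in df[c] if p is not None and p not in ids]
            if bad:
                raise ValueError(f"{c} ids not present in pedigree: {sorted(set(bad))}")
        self.table = df.reset_index(drop=True)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {r.id: (r.dam, r.sire) for r in self.table.itertuples(index=False)}
        state: dict[str, int] = {}

        def visit(node: str, chain: list[str]) -> None:
            st = state.get(node, 0)
            if st == 1:
                cycle = chain[chain.index(node):] + [node]
                raise ValueError(f"pedigree cycle detected: {' -> '.join(cycle)}")
            if st == 2:
                return
            state[node] = 1
            for p in parents[node]:
                if p is not None:
                    visit(p, chain + [node])
            state[node] = 2

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, len(parents) * 4 + 100))
        try:
            for i in parents:
                visit(i, [])
        finally:
            sys.setrecursionlimit(old)

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def founders(self) -> list[str]:
        t = self.table
        mask = [d is None and s is None for d, s in zip(t["dam"], t["sire"])]
        return list(t.loc[mask, "id"])

    def topological_order(self) -> list[str]:
        """Ids with every parent preceding its offspring (birth-day tie-break)."""
        t = self.table
        parents = {r.id: [p for p in (r.dam, r.sire) if p is not None]
                   for r in t.itertuples(index=False)}
        birth = dict(zip(t["id"], pd.to_numeric(t["birth_day"], errors="coerce").fillna(0)))
        order: list[str] = []
        placed: set[str] = set()
        remaining = sorted(parents, key=lambda i: (birth[i], i))
        while remaining:
            progress = [i for i in remaining if all(p in placed for p in parents[i])]
            if not progress:  # unreachable given the acyclicity check
                raise ValueError("pedigree is not orderable")
            order.extend(progress)
            placed.update(progress)
            remaining = [i for i in remaining if i not in placed]
        return order

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        for c in ("dam", "sire"):
            out[c] = out[c].map(lambda v: "" if v is None else v)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PedigreeTable":
        return cls(pd.read_csv(path, dtype=str).assign(
            birth_day=lambda d: pd.to_numeric(d.get("birth_day", 0))))


@dataclass
class RelatednessMatrix:
    individuals: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individuals)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match individual list")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("relatedness matrix must be symmetric")

    def loc(self, i: str, j: str) -> float:
        a, b = self.individuals.index(i), self.individuals.index(j)
        return float(self.values[a, b])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individuals, columns=self.individuals)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.8f")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RelatednessMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def additive_relationship(pedigree: PedigreeTable) -> RelatednessMatrix:
    """Numerator relationship matrix A by the recursive tabular method.

    In an order where parents precede offspring:
    a_ii = 1 + a(dam_i, sire_i)/2 and, for j earlier than i,
    a_ij = (a(j, dam_i) + a(j, sire_i))/2; an unknown parent contributes 0.
    """
    order = pedigree.topological_order()
    idx = {m: k for k, m in enumerate(order)}
    t = pedigree.table.set_index("id")
    n = len(order)
    A = np.zeros((n, n))
    for i, ind in enumerate(order):
        dam, sire = t.at[ind, "dam"], t.at[ind, "sire"]
        di = idx[dam] if dam is not None else None
        si = idx[sire] if sire is not None else None
        for j in range(i):
            a = 0.0
            if di is not None:
                a += A[j, di]
            if si is not None:
                a += A[j, si]
            A[j, i] = A[i, j] = 0.5 * a
        A[i, i] = 1.0 + (0.5 * A[di, si] if di is not None and si is not None else 0.0)
    # restore the pedigree's own row order
    perm = [idx[m] for m in pedigree.ids]
    return RelatednessMatrix(pedigree.ids, A[np.ix_(perm, perm)])


def classify_dyads(
    relatedness: RelatednessMatrix,
    pedigree: PedigreeTable,
    unrelated_threshold: float = UNRELATED_THRESHOLD,
) -> pd.DataFrame:
    """Label every unordered pair of individuals by its pedigree relation.

    Classes (first match wins): mother_offspring, father_offspring, full_sib,
    and within full sibs additionally same-litter (same dam, sire and
    birth day — flagged in the ``same_litter`` column); otherwise unrelated
    (r strictly below the threshold) or other.
    """
    t = pedigree.table.set_index("id")
    ids = relatedness.individuals
    rows = []
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            i, j = ids[a_i], ids[b_i]
            r = relatedness.values[a_i, b_i]
            di, si_ = t.at[i, "dam"], t.at[i, "sire"]
            dj, sj = t.at[j, "dam"], t.at[j, "sire"]
            same_litter = False
            if dj == i or sj == i or di == j or si_ == j:
                parent, child = (i, j) if (dj == i or sj == i) else (j, i)
                cls_ = ("mother_offspring"
                        if t.at[child, "dam"] == parent else "father_offspring")
            elif di is not None and si_ is not None and di == dj and si_ == sj:
                cls_ = "full_sib"
                same_litter = t.at[i, "birth_day"] == t.at[j, "birth_day"]
            elif r < unrelated_threshold:
                cls_ = "unrelated"
            else:
                cls_ = "other"
            rows.append((i, j, r, cls_, same_litter))
    return pd.DataFrame(
        rows, columns=["individual_i", "individual_j", "relatedness", "dyad_class", "same_litter"]
    )
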