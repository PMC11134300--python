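"""ASV count-table handling: duplicate merging, rarefaction, similarity.

Counts are samples × ASVs.  Technical PCR duplicates are merged by zeroing
any ASV not detected in both members of a pair and summing the rest.
Community similarity is S = 1 − D for Bray–Curtis (relative abundances) or
Jaccard (presence/absence) dissimilarity; phylogenetically weighted metrics
are deliberately not offered, since shared dispersal traits of related
bacteria are part of the signal of interest here.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import logit as _logit

from ._rng import substream

__all__ = [
    "CountTable",
    "SampleMeta",
    "SimilarityMatrix",
    "merge_duplicates",
    "rarefy",
    "dissimilarity",
    "logit_similarity",
]


@dataclass
class CountTable:
    """Integer read counts, samples in rows, ASVs in columns.

    ``duplicate_pairs`` optionally maps each technical-duplicate sample id to
    the merged sample id it belongs to.
    """

    counts: pd.DataFrame = field(repr=False)
    duplicate_pairs: dict[str, str] | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        arr = c.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        self.counts = c.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index.astype(str))

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns.astype(str))

    def depths(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, **kw) -> "CountTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0), **kw)


@dataclass
class SampleMeta:
    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "individual", "gut_section", "subspecies", "sex", "age_days")

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            raise ValueError("each sample must map to exactly one individual/section row")
        self.table = df.set_index("sample_id", drop=False)

    def for_samples(self, sample_ids) -> pd.DataFrame:
        return self.table.loc[list(sample_ids)]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleMeta":
        return cls(pd.read_csv(path))


@dataclass
class SimilarityMatrix:
    """Pairwise sample similarity with metric and transform tags."""

    sample_ids: list[str]
    values: np.ndarray = field(repr=False)
    metric: str = "bray_curtis"
    transform: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if self.transform == "raw" and ((self.values < -1e-12).any() or (self.values > 1 + 1e-12).any()):
            raise ValueError("raw similarities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.10f")


def merge_duplicates(table: CountTable) -> CountTable:
    """Merge technical duplicates, dropping ASVs absent from either member.

    Per pair, an ASV with zero count in either duplicate is zeroed in both
    (it failed the two-independent-detections check); surviving counts are
    summed into one sample named by the pair's merged id.  Without a
    duplicate mapping this is a no-op.
    """
    if not table.duplicate_pairs:
        return table
    mapping = {str(k): str(v) for k, v in table.duplicate_pairs.items()}
    groups: dict[str, list[str]] = {}
    for s, m in mapping.items():
        groups.setdefault(m, []).append(s)
    bad = {m: g for m, g in groups.items() if len(g) != 2}
    if bad:
        raise ValueError(f"unpaired duplicate ids: {bad}")
    unknown = set(mapping) - set(table.sample_ids)
    if unknown:
        raise ValueError(f"duplicate mapping refers to unknown samples: {sorted(unknown)}")
    rows = {}
    for merged_id in sorted(groups):
        a, b = groups[merged_id]
        ca = table.counts.loc[a]
        cb = table.counts.loc[b]
        both = (ca > 0) & (cb > 0)
        rows[merged_id] = (ca + cb).where(both, 0)
    merged = pd.DataFrame(rows).T
    merged.index.name = table.counts.index.name
    return CountTable(merged)


def rarefy(
    table: CountTable,
    depth: int,
    seed: int,
    on_shallow: str = "error",
) -> CountTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Equivalent to a multivariate hypergeometric draw per sample, so repeated
    rarefaction of a two-ASV sample has the hypergeometric mean/variance.
    ``on_shallow`` controls samples below the threshold: "error" (default)
    or "drop" (with a warning).
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    totals = table.depths()
    shallow = totals[totals < depth]
    counts = table.counts
    if len(shallow):
        if on_shallow == "drop":
            warnings.warn(
                f"dropping {len(shallow)} sample(s) below rarefaction depth {depth}: "
                f"{list(shallow.index)}",
                stacklevel=2,
            )
            counts = counts.drop(index=shallow.index)
        else:
            raise ValueError(
                f"samples below rarefaction depth {depth}: {list(shallow.index)}"
            )
    rng = substream(seed, "rarefaction")
    out = np.empty_like(counts.to_numpy())
    for k, (_, row) in enumerate(counts.iterrows()):
        out[k] = rng.multivariate_hypergeometric(row.to_numpy(), depth)
    return CountTable(pd.DataFrame(out, index=counts.index, columns=counts.columns))


def dissimilarity(table: CountTable, metric: str = "bray_curtis") -> SimilarityMatrix:
    """Pairwise similarity S = 1 − D between all samples.

    Bray–Curtis is computed on relative abundances; Jaccard on the
    presence/absence pattern (unweighted, |shared| / |union|).
    """
    X = table.counts.to_numpy(dtype=float)
    totals = X.sum(axis=1)
    zero = np.asarray(table.sample_ids)[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero)}")
    if metric == "bray_curtis":
        D = pdist(X / totals[:, None], metric="braycurtis")
    elif metric == "jaccard":
        D = pdist(X > 0, metric="jaccard")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    S = 1.0 - squareform(D)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(table.sample_ids, S, metric=metric, transform="raw")


def logit_similarity(S: SimilarityMatrix, eps: float = 1e-3) -> SimilarityMatrix:
    """Logit-transform raw similarities, squeezing into [eps, 1−eps].

    The symmetric squeeze keeps boundary values (identical or disjoint
    communities) finite; the response scale is similarity, so positive
    coefficients mean more similar microbiota.
    """
    if S.transform != "raw":
        raise ValueError("expected a raw similarity matrix")
    v = np.clip(S.values, eps, 1.0 - eps)
    return SimilarityMatrix(S.sample_ids, _logit(v), metric=S.metric, transform="logit")
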