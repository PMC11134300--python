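"""Per-ASV association with relatedness and social contact.

For each sufficiently prevalent ASV, between-sample variation is summarised
as pairwise absolute differences of centred log-ratio (clr) values, embedded
by principal coordinate analysis (with the Cailliez additive correction when
the dissimilarity is non-Euclidean), and compared to the PCoA embedding of
the inverted (1 − value) relatedness or contact matrix by a symmetric
Procrustes permutation test.  Small Procrustes sums of squares m² mean
strong concordance.  Benjamini–Hochberg FDR is applied within each
(section, subspecies, predictor) family.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, spearmanr, wilcoxon
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .community_matrix import CountTable, SampleMeta
from .pedigree_kinship import RelatednessMatrix
from .rfid_social import ContactMatrix

__all__ = [
    "ClrTable",
    "PcoaResult",
    "clr_transform",
    "asv_dissimilarity",
    "pcoa_cailliez",
    "predictor_configuration",
    "procrustes_test",
    "asv_screen",
    "subspecies_congruence",
]


@dataclass
class ClrTable:
    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        rowsums = self.values.sum(axis=1).to_numpy()
        if not np.allclose(rowsums, 0.0, atol=1e-8):
            raise ValueError("clr rows must sum to zero")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index.astype(str))


@dataclass
class PcoaResult:
    """PCoA scores (samples × retained axes) with eigenvalues and Cailliez c."""

    sample_ids: list[str]
    scores: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray = field(repr=False)
    cailliez_c: float = 0.0


def clr_transform(table: CountTable, pseudocount: float = 0.5) -> ClrTable:
    """Centred log-ratio transform after adding a global pseudocount.

    The pseudocount (default 0.5) replaces zeros so logs are defined; each
    sample's clr values are its log counts centred by their mean (the log of
    the geometric mean), making rows sum to zero.
    """
    X = table.counts.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    logs = np.log(X + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return ClrTable(pd.DataFrame(clr, index=table.counts.index, columns=table.counts.columns))


def asv_dissimilarity(clr: ClrTable, asv: str) -> np.ndarray:
    """|Δclr| between all sample pairs for one ASV (a line metric)."""
    if asv not in clr.values.columns:
        raise KeyError(f"ASV {asv!r} not in clr table")
    v = clr.values[asv].to_numpy()
    return np.abs(v[:, None] - v[None, :])


def _gower_center(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return J @ A @ J


def cailliez_constant(D: np.ndarray) -> float:
    """Smallest additive constant making D + c (off-diagonal) Euclidean.

    Computed as the largest real eigenvalue of the 2n × 2n special matrix
    [[0, 2 Δ1], [−I, −4 Δ2]] with Δ1 and Δ2 the Gower-centred −D²/2 and
    −D/2 (Cailliez 1983).
    """
    n = D.shape[0]
    d1 = _gower_center(-0.5 * D * D)
    d2 = _gower_center(-0.5 * D)
    big = np.block([
        [np.zeros((n, n)), 2.0 * d1],
        [-np.eye(n), -4.0 * d2],
    ])
    ev = np.linalg.eigvals(big)
    return float(max(ev.real.max(), 0.0))


def pcoa_cailliez(D: np.ndarray, eig_tol: float = 1e-8) -> PcoaResult:
    """Principal coordinates with the Cailliez correction when needed.

    If the Gower-centred −D²/2 has eigenvalues below −eig_tol × λ_max, the
    Cailliez constant is added to all off-diagonal dissimilarities first.
    Axes with eigenvalue > eig_tol × λ_max are retained, ordered by
    decreasing eigenvalue; inter-point distances of the scores reproduce the
    (corrected) D.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be a square matrix")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("D must be symmetric")
    D = D.copy()
    np.fill_diagonal(D, 0.0)

    def eig_scores(Dm):
        B = _gower_center(-0.5 * Dm * Dm)
        vals, vecs = np.linalg.eigh(B)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    vals, vecs = eig_scores(D)
    scale = max(abs(vals[0]), 1.0)
    c = 0.0
    if vals[-1] < -eig_tol * scale:
        c = cailliez_constant(D)
        Dc = D + c
        np.fill_diagonal(Dc, 0.0)
        D = Dc
        vals, vecs = eig_scores(D)
        scale = max(abs(vals[0]), 1.0)
    keep = vals > eig_tol * scale
    scores = vecs[:, keep] * np.sqrt(vals[keep])
    ids = [str(i) for i in range(D.shape[0])]
    return PcoaResult(ids, scores, vals[keep], cailliez_c=c)


def predictor_configuration(M, kind: str = "relatedness") -> PcoaResult:
    """PCoA embedding of an inverted predictor matrix.

    Relatedness is clipped to [0, 1]; contact seconds are min–max scaled
    over off-diagonal entries.  The similarity is inverted to D = 1 − M
    (zero diagonal) and embedded with :func:`pcoa_cailliez`.
    """
    if isinstance(M, (RelatednessMatrix, ContactMatrix)):
        ids, V = M.individuals, M.values
    else:
        V = np.asarray(M, dtype=float)
        ids = [str(i) for i in range(V.shape[0])]
    if not np.allclose(V, V.T, atol=1e-10):
        raise ValueError("predictor matrix must be symmetric")
    V = V.astype(float).copy()
    off = ~np.eye(V.shape[0], dtype=bool)
    if kind == "relatedness":
        V = np.clip(V, 0.0, 1.0)
    elif kind == "contact":
        lo, hi = V[off].min(), V[off].max()
        V = (V - lo) / (hi - lo) if hi > lo else np.zeros_like(V)
    else:
        raise ValueError(f"unknown predictor kind {kind!r}")
    D = 1.0 - V
    np.fill_diagonal(D, 0.0)
    res = pcoa_cailliez(D)
    res.sample_ids = list(ids)
    return res


def _normalize_config(scores: np.ndarray) -> np.ndarray:
    X = scores - scores.mean(axis=0, keepdims=True)
    ss = np.sqrt((X * X).sum())
    if ss <= 0:
        raise ValueError("degenerate configuration (all points coincide)")
    return X / ss


def _m2(X: np.ndarray, Y: np.ndarray) -> float:
    # both unit sum of squares and centred; optimal rotation via SVD
    s = np.linalg.svd(X.T @ Y, compute_uv=False)
    return float(max(0.0, 1.0 - s.sum() ** 2))


def procrustes_test(
    response: PcoaResult,
    target: PcoaResult,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Symmetric Procrustes m² with a row-permutation test.

    Both configurations are centred and scaled to unit sum of squares, the
    narrower one zero-padded, and m² = 1 − (Σ singular values)² after the
    optimal rotation.  The p-value uses the (1 + #{m²_perm ≤ m²_obs}) /
    (1 + n_perm) estimator with the response rows permuted, so p is never 0.
    """
    n = len(response.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples for a Procrustes test")
    if n != len(target.sample_ids):
        raise ValueError("configurations must share the sample set")
    X = _normalize_config(response.scores)
    Y = _normalize_config(target.scores)
    k = max(X.shape[1], Y.shape[1])
    if X.shape[1] < k:
        X = np.pad(X, ((0, 0), (0, k - X.shape[1])))
    if Y.shape[1] < k:
        Y = np.pad(Y, ((0, 0), (0, k - Y.shape[1])))
    m2_obs = _m2(X, Y)
    rng = substream(seed, "procrustes")
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _m2(X[perm], Y) <= m2_obs:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_perm)
    return m2_obs, p


def asv_screen(
    counts: CountTable,
    clr: ClrTable,
    predictors: dict[str, RelatednessMatrix | ContactMatrix],
    meta: SampleMeta,
    section: str,
    subspecies: str,
    min_prevalence: int = 20,
    n_perm: int = 999,
    seed: int = 0,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen every qualifying ASV against every predictor matrix.

    ASVs must be present (nonzero) in at least ``min_prevalence`` samples of
    the gut section; each is tested within the given subspecies by
    ``asv_dissimilarity`` → ``pcoa_cailliez`` → ``procrustes_test`` against
    the predictor's PCoA configuration.  BH-FDR is applied within each
    (section, subspecies, predictor) family; ``significant`` marks
    q < ``fdr_alpha``.
    """
    m = meta.table
    section_samples = [s for s in counts.sample_ids
                       if m.at[s, "gut_section"] == section]
    prevalence = (counts.counts.loc[section_samples] > 0).sum(axis=0)
    qualifying = sorted(prevalence.index[prevalence >= min_prevalence])

    samples = [s for s in section_samples if m.at[s, "subspecies"] == subspecies]
    individuals = [str(m.at[s, "individual"]) for s in samples]
    sub_clr = clr.values.loc[samples]

    configs = {}
    for name, mat in predictors.items():
        idx = {x: i for i, x in enumerate(mat.individuals)}
        order = [idx[i] for i in individuals]
        sub = mat.values[np.ix_(order, order)]
        kind = "contact" if isinstance(mat, ContactMatrix) else "relatedness"
        cfg = predictor_configuration(sub, kind=kind)
        cfg.sample_ids = samples
        configs[name] = cfg

    rows = []
    for name, cfg in configs.items():
        for k, asv in enumerate(qualifying):
            v = sub_clr[asv].to_numpy()
            D = np.abs(v[:, None] - v[None, :])
            resp = pcoa_cailliez(D)
            resp.sample_ids = samples
            m2, p = procrustes_test(
                resp, cfg, n_perm=n_perm,
                seed=int(substream(seed, f"screen:{name}:{asv}").integers(2 ** 31)),
            )
            rows.append((asv, section, subspecies, name, m2, p,
                         int(prevalence[asv]), len(samples)))
    out = pd.DataFrame(
        rows,
        columns=["asv", "section", "subspecies", "predictor", "m2", "p",
                 "prevalence", "n_samples"],
    )
    out["q"] = np.nan
    for name, sub in out.groupby("predictor"):
        _, q, _, _ = multipletests(sub["p"], method="fdr_bh")
        out.loc[sub.index, "q"] = q
    out["significant"] = out["q"] < fdr_alpha
    return out.sort_values(["predictor", "asv"]).reset_index(drop=True)


def planted_enrichment_p(results: pd.DataFrame, planted: set[str]) -> float:
    """Hypergeometric tail p for planted ASVs among significant calls."""
    tested = results["asv"].unique()
    sig = set(results.loc[results["significant"], "asv"])
    N, K, n = len(tested), len(planted & set(tested)), len(sig)
    k = len(sig & planted)
    return float(hypergeom.sf(k - 1, N, K, n))


def subspecies_congruence(
    results_a: pd.DataFrame, results_b: pd.DataFrame
) -> dict[str, float]:
    """Concordance of per-ASV Procrustes m² between two subspecies.

    Spearman rank correlation across ASVs tested in both subspecies, plus a
    paired Wilcoxon signed-rank test on the m² pairs (exact where the sample
    is small enough; identical vectors give p = 1).
    """
    a = results_a.set_index("asv")["m2"]
    b = results_b.set_index("asv")["m2"]
    shared = sorted(set(a.index) & set(b.index))
    if not shared:
        raise ValueError("no shared ASVs between the two result sets")
    if len(shared) < 5:
        raise ValueError(f"only {len(shared)} shared ASVs (need >= 5)")
    x, y = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
    rho, p_rho = spearmanr(x, y)
    diffs = x - y
    if np.allclose(diffs, 0.0):
        p_w = 1.0
    else:
        method = "exact" if len(shared) <= 25 and not np.any(diffs == 0) else "auto"
        _, p_w = wilcoxon(x, y, method=method)
    return {
        "n_shared": float(len(shared)),
        "spearman_rho": float(rho),
        "spearman_p": float(p_rho),
        "wilcoxon_p": float(p_w),
    }
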