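"""Age trajectories of kin microbiota similarity.

Parent–offspring (and same-litter sibling) logit similarities are modelled
as smooth functions of offspring age with natural cubic splines inside the
multimembership LMM (parent and offspring — or the two siblings — are the
members).  Model complexity (linear, or splines with 2–4 degrees of
freedom) is chosen by ML-based AIC.  Trajectories are read against the
population-wide baseline: the mean logit similarity of genetically
unrelated pairs (relatedness < 0.25), estimated by an intercept-only
multimembership LMM.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .community_matrix import SampleMeta, SimilarityMatrix
from .mm_lmm import MMLmmFit, fit_mm_lmm_core
from .pedigree_kinship import PedigreeTable, UNRELATED_THRESHOLD
from .dyadic_lmm import lrt

__all__ = [
    "natural_spline_basis",
    "build_kin_series",
    "fit_trajectory",
    "baseline_estimate",
    "trajectory_vs_baseline",
    "TrajectoryFit",
    "BaselineEstimate",
]

PAIR_TYPES = ("mother_offspring", "father_offspring", "same_litter_sib")


def _spline_knots(age: np.ndarray, df: int) -> np.ndarray:
    # boundary knots at the range, interior knots at quantiles
    n_interior = df - 1
    qs = np.linspace(0, 1, n_interior + 2)
    knots = np.quantile(np.unique(age), qs)
    if len(np.unique(knots)) != df + 1:
        raise ValueError("insufficient distinct ages for the requested spline df")
    return knots


def natural_spline_basis(
    age: np.ndarray, df: int, knots: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic spline basis with ``df`` columns (no intercept column).

    Uses the truncated-power natural-spline construction: with knots
    t_1 < … < t_K (K = df + 1), the columns are x and
    d_k(x) − d_{K−1}(x) for k = 1..K−2, where
    d_k(x) = [(x−t_k)₊³ − (x−t_K)₊³] / (t_K − t_k).  Second derivatives
    vanish beyond the boundary knots, so extrapolation is exactly linear.
    Returns (basis, knots).
    """
    age = np.asarray(age, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if df == 1:
        return age[:, None], np.array([age.min(), age.max()])
    if knots is None:
        if len(np.unique(age)) < df + 2:
            raise ValueError(
                f"need at least {df + 2} distinct ages for a df={df} natural spline"
            )
        knots = _spline_knots(age, df)
    knots = np.asarray(knots, dtype=float)
    K = len(knots)

    def d(k: int, x: np.ndarray) -> np.ndarray:
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[K - 1], 0.0) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [age]
    dK2 = d(K - 2, age)
    for k in range(K - 2):
        cols.append(d(k, age) - dK2)
    return np.column_stack(cols), knots


def build_kin_series(
    S: SimilarityMatrix,
    meta: SampleMeta,
    pedigree: PedigreeTable,
    section: str | None = None,
) -> pd.DataFrame:
    """Extract kin-dyad similarity series from a similarity matrix.

    One row per parent–offspring or same-litter full-sib pair with samples
    in the matrix: response y (the similarity value, typically already
    logit-transformed), offspring age at sampling, sexes, and the two
    member ids for the multimembership random effect.  For sibling pairs
    the shared litter age is used.
    """
    m = meta.for_samples(S.sample_ids)
    if section is not None:
        m = m[m["gut_section"] == section]
    sample_of = dict(zip(m["individual"].astype(str), m["sample_id"]))
    sidx = {s: i for i, s in enumerate(S.sample_ids)}
    ped = pedigree.table.set_index("id")
    rows = []
    for child, row in ped.iterrows():
        if child not in sample_of:
            continue
        c_sample = sample_of[child]
        c_age = float(m.at[c_sample, "age_days"])
        c_sex = str(m.at[c_sample, "sex"])
        c_sub = str(m.at[c_sample, "subspecies"])
        c_sec = str(m.at[c_sample, "gut_section"])
        for parent, ptype in ((row["dam"], "mother_offspring"),
                              (row["sire"], "father_offspring")):
            if parent is None or parent not in sample_of:
                continue
            p_sample = sample_of[parent]
            y = S.values[sidx[p_sample], sidx[c_sample]]
            rows.append((ptype, y, c_age, c_sex, c_sub, c_sec, parent, child))
    # same-litter full sibs: same dam, same sire, same birth day
    kids = pedigree.table
    with_parents = kids[[d is not None and s is not None
                         for d, s in zip(kids["dam"], kids["sire"])]]
    for _, grp in with_parents.groupby(["dam", "sire", "birth_day"]):
        ids = [i for i in grp["id"] if i in sample_of]
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                sa, sb = sample_of[ids[a]], sample_of[ids[b]]
                y = S.values[sidx[sa], sidx[sb]]
                age = float(m.at[sa, "age_days"])
                rows.append(("same_litter_sib", y, age, "",
                             str(m.at[sa, "subspecies"]),
                             str(m.at[sa, "gut_section"]), ids[a], ids[b]))
    return pd.DataFrame(
        rows,
        columns=["pair_type", "y", "age_days", "offspring_sex", "subspecies",
                 "gut_section", "member_i", "member_j"],
    )


@dataclass
class TrajectoryFit:
    chosen: str
    aic_table: pd.DataFrame = field(repr=False)
    fit: MMLmmFit = field(repr=False)
    knots: np.ndarray | None
    predictions: pd.DataFrame = field(repr=False)
    interaction_tests: pd.DataFrame | None = field(repr=False, default=None)


def _age_design(age: np.ndarray, candidate: str,
                knots: np.ndarray | None = None):
    if candidate == "linear":
        return age[:, None], np.array([age.min(), age.max()])
    if candidate.startswith("ns"):
        df = int(candidate[2:])
        return natural_spline_basis(age, df, knots=knots)
    raise ValueError(f"unknown candidate {candidate!r}")


def _members(series: pd.DataFrame):
    ids = sorted(set(series["member_i"]) | set(series["member_j"]))
    index = {m: i for i, m in enumerate(ids)}
    mem = np.column_stack(
        [series["member_i"].map(index), series["member_j"].map(index)]
    ).astype(np.int64)
    return mem, ids


def fit_trajectory(
    series: pd.DataFrame,
    candidates: Sequence[str] = ("linear", "ns2", "ns3", "ns4"),
    include_sex: bool = False,
    n_grid: int = 120,
    test_interactions: bool = False,
) -> TrajectoryFit:
    """Fit candidate age models and keep the AIC-best one.

    Each candidate (linear slope, or natural splines with 2–4 df) enters the
    multimembership LMM as fixed-effect columns; AIC is compared on ML fits
    and the winner refitted by REML for reporting.  Predictions with 95%
    delta-method confidence bands are evaluated on an age grid (any extra
    covariates held at their sample mean).  With ``test_interactions`` the
    pooled age × section, age × subspecies and (if ``include_sex``)
    age × sex LRTs are reported alongside.
    """
    if series.empty:
        raise ValueError("empty kin-dyad series")
    if not test_interactions and series["gut_section"].nunique() > 1:
        raise ValueError("fit one gut section at a time (or test interactions pooled)")
    age = series["age_days"].to_numpy(dtype=float)
    y = series["y"].to_numpy(dtype=float)
    mem, ids = _members(series)

    extra_cols: list[np.ndarray] = []
    extra_names: list[str] = []
    if include_sex and series["offspring_sex"].nunique() > 1:
        levels = sorted(series["offspring_sex"].unique())
        for lv in levels[1:]:
            extra_cols.append((series["offspring_sex"] == lv).to_numpy(float))
            extra_names.append(f"sex[{lv}]")

    results = {}
    errors = {}
    for cand in candidates:
        try:
            B, knots = _age_design(age, cand)
            X = np.column_stack([np.ones(len(age)), B] + extra_cols)
            names = (["(Intercept)"] + [f"age{j + 1}" for j in range(B.shape[1])]
                     + extra_names)
            fit_ml = fit_mm_lmm_core(X, y, mem, ids, reml=False, coef_names=names)
            results[cand] = (fit_ml, knots, B.shape[1])
        except Exception as exc:  # noqa: BLE001 - candidates may be infeasible
            errors[cand] = str(exc)
    if not results:
        raise ValueError(f"all trajectory candidates failed: {errors}")
    aic_rows = [(cand, fit.aic) for cand, (fit, _, _) in results.items()]
    aic_table = pd.DataFrame(aic_rows, columns=["candidate", "aic"])
    chosen = aic_table.loc[aic_table["aic"].idxmin(), "candidate"]
    _, knots, n_basis = results[chosen]

    B, knots = _age_design(age, chosen, knots=knots)
    X = np.column_stack([np.ones(len(age)), B] + extra_cols)
    names = (["(Intercept)"] + [f"age{j + 1}" for j in range(B.shape[1])]
             + extra_names)
    fit = fit_mm_lmm_core(X, y, mem, ids, reml=True, coef_names=names)

    grid = np.linspace(age.min(), age.max(), n_grid)
    Bg, _ = _age_design(grid, chosen, knots=knots)
    Xg = np.column_stack([np.ones(len(grid)), Bg]
                         + [np.full(len(grid), c.mean()) for c in extra_cols])
    pred = Xg @ fit.beta
    var = np.einsum("ij,jk,ik->i", Xg, fit.cov_beta, Xg)
    half = 1.96 * np.sqrt(np.maximum(var, 0.0))
    predictions = pd.DataFrame(
        {"age_days": grid, "fit": pred, "lo": pred - half, "hi": pred + half}
    )

    inter = None
    if test_interactions:
        inter = _interaction_tests(series, age, y, mem, ids, B, extra_cols,
                                   include_sex)
    return TrajectoryFit(chosen=str(chosen), aic_table=aic_table, fit=fit,
                         knots=knots, predictions=predictions,
                         interaction_tests=inter)


def _interaction_tests(series, age, y, mem, ids, B, extra_cols, include_sex):
    """Pooled LRTs for age × section / subspecies / sex on ML fits."""
    rows = []
    factors = [("gut_section", "age:gut_section"),
               ("subspecies", "age:subspecies")]
    if include_sex:
        factors.append(("offspring_sex", "age:offspring_sex"))
    for col, label in factors:
        if series[col].nunique() < 2:
            continue
        levels = sorted(series[col].unique())
        dummies = [(series[col] == lv).to_numpy(float) for lv in levels[1:]]
        base_cols = [np.ones(len(age)), B] + [d[:, None] for d in dummies] + \
            [c[:, None] for c in extra_cols]
        X0 = np.column_stack(base_cols)
        X1 = np.column_stack(base_cols + [B * d[:, None] for d in dummies])
        f0 = fit_mm_lmm_core(X0, y, mem, ids, reml=False)
        f1 = fit_mm_lmm_core(X1, y, mem, ids, reml=False)
        stat, df, p = lrt(f1, f0)
        rows.append((label, stat, df, p))
    return pd.DataFrame(rows, columns=["interaction", "lrt_chi2", "df", "p_value"])


@dataclass
class BaselineEstimate:
    gut_section: str
    subspecies: str
    mean_logit_similarity: float
    ci_lower: float
    ci_upper: float
    n_dyads: int
    threshold: float


def baseline_estimate(
    dyads: pd.DataFrame,
    threshold: float = UNRELATED_THRESHOLD,
) -> BaselineEstimate:
    """Population-wide unrelated-pair mean similarity (logit scale).

    Intercept-only multimembership LMM over dyads with relatedness strictly
    below the threshold; the 95% CI is a normal approximation on the
    intercept's standard error.
    """
    sub = dyads.loc[dyads["relatedness"] < threshold].reset_index(drop=True)
    if len(sub) < 10:
        raise ValueError(
            f"only {len(sub)} unrelated dyads below r < {threshold} (need >= 10)"
        )
    if "member_i" not in sub.columns:
        sub = sub.rename(columns={"individual_i": "member_i",
                                  "individual_j": "member_j"})
    mem, ids = _members(sub)
    X = np.ones((len(sub), 1))
    fit = fit_mm_lmm_core(X, sub["y"].to_numpy(float), mem, ids, reml=True,
                          coef_names=["(Intercept)"])
    est = float(fit.beta[0])
    half = 1.96 * float(fit.se[0])
    section = sub["gut_section"].iloc[0] if "gut_section" in sub.columns else ""
    subsp = (sub["subspecies_pair"].iloc[0]
             if "subspecies_pair" in sub.columns and sub["subspecies_pair"].nunique() == 1
             else "pooled")
    return BaselineEstimate(
        gut_section=str(section), subspecies=str(subsp),
        mean_logit_similarity=est, ci_lower=est - half, ci_upper=est + half,
        n_dyads=len(sub), threshold=threshold,
    )


def trajectory_vs_baseline(
    fit: TrajectoryFit, base: BaselineEstimate
) -> dict:
    """Where does the trajectory's 95% CI exclude the baseline CI?

    Uses the non-overlap rule: an age is in an exclusion interval when the
    trajectory band lies entirely above or below the baseline band.  Also
    reports the age of maximal fitted similarity.
    """
    pred = fit.predictions
    above = pred["lo"].to_numpy() > base.ci_upper
    below = pred["hi"].to_numpy() < base.ci_lower
    excluded = above | below
    ages = pred["age_days"].to_numpy()
    intervals = []
    start = None
    for k, flag in enumerate(excluded):
        if flag and start is None:
            start = ages[k]
        elif not flag and start is not None:
            intervals.append((float(start), float(ages[k - 1])))
            start = None
    if start is not None:
        intervals.append((float(start), float(ages[-1])))
    peak_idx = int(np.argmax(pred["fit"].to_numpy()))
    return {
        "exclusion_intervals": intervals,
        "peak_age": float(ages[peak_idx]),
        "peak_fit": float(pred["fit"].iloc[peak_idx]),
        "baseline": base.mean_logit_similarity,
    }
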