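"""Dyadic similarity models: assembly, fitting, selection, partitioning.

A dyad table has one row per unordered pair of same-gut-section samples,
carrying the logit microbiota similarity as response and pedigree
relatedness, scaled social contact, and subspecies identity as predictors.
Non-independence of pairwise values is absorbed by a multimembership random
effect over the two individuals of each dyad.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .community_matrix import SampleMeta, SimilarityMatrix
from .mm_lmm import MMLmmFit, build_design, fit_mm_lmm_core, term_parents
from .pedigree_kinship import RelatednessMatrix
from .rfid_social import ContactMatrix

__all__ = [
    "build_dyads",
    "fit_mm_lmm",
    "lrt_and_stepwise",
    "variance_partition",
    "exclusion_reanalysis",
    "CLOSE_KIN_CLASSES",
    "StepwiseReport",
]

#: dyad classes removed by the close-kin exclusion re-analysis
CLOSE_KIN_CLASSES = ("full_sib", "mother_offspring", "father_offspring")

DEFAULT_TERMS = (
    "relatedness",
    "contact",
    "subspecies_pair",
    "relatedness:subspecies_pair",
    "contact:subspecies_pair",
)


def build_dyads(
    S: SimilarityMatrix,
    meta: SampleMeta,
    relatedness: RelatednessMatrix,
    contacts: ContactMatrix,
    dyad_classes: pd.DataFrame | None = None,
    section: str | None = None,
    within_subspecies_only: bool = True,
) -> pd.DataFrame:
    """Assemble the dyad table from similarity, metadata and predictor matrices.

    One row per unordered pair of samples from the same gut section.  Contact
    is min–max scaled to [0, 1] within each subspecies (cross-subspecies
    dyads, kept only when ``within_subspecies_only`` is False for the pooled
    interaction model, are scaled over all retained dyads).  Relatedness is
    clipped to [0, 1] so the downstream 1 − r inversion stays in range.
    """
    m = meta.for_samples(S.sample_ids)
    if section is not None:
        keep = m["gut_section"] == section
    else:
        keep = pd.Series(True, index=m.index)
    samples = [s for s, k in zip(S.sample_ids, keep) if k]
    sections = m.loc[samples, "gut_section"].to_numpy()
    if len(set(sections)) > 1:
        raise ValueError("dyads must be built within a single gut section")
    indiv = m.loc[samples, "individual"].astype(str).to_numpy()
    subsp = m.loc[samples, "subspecies"].astype(str).to_numpy()
    r_index = {x: i for i, x in enumerate(relatedness.individuals)}
    c_index = {x: i for i, x in enumerate(contacts.individuals)}
    for ind in indiv:
        if ind not in r_index:
            raise ValueError(f"individual {ind!r} missing from relatedness matrix")
        if ind not in c_index:
            raise ValueError(f"individual {ind!r} missing from contact matrix")

    sidx = {s: i for i, s in enumerate(S.sample_ids)}
    cls_map = {}
    if dyad_classes is not None:
        for row in dyad_classes.itertuples(index=False):
            key = frozenset((row.individual_i, row.individual_j))
            cls_map[key] = (row.dyad_class, bool(row.same_litter))

    rows = []
    for a in range(len(samples)):
        for b in range(a + 1, len(samples)):
            ia, ib = indiv[a], indiv[b]
            if ia == ib:
                continue
            sa, sb = subsp[a], subsp[b]
            pair_subsp = sa if sa == sb else "cross"
            if within_subspecies_only and pair_subsp == "cross":
                continue
            r = relatedness.values[r_index[ia], r_index[ib]]
            c_raw = contacts.values[c_index[ia], c_index[ib]]
            cls_, same_litter = cls_map.get(frozenset((ia, ib)), ("other", False))
            rows.append(
                (
                    samples[a], samples[b], ia, ib,
                    S.values[sidx[samples[a]], sidx[samples[b]]],
                    min(max(float(r), 0.0), 1.0), float(c_raw),
                    pair_subsp, sections[0], cls_, same_litter,
                )
            )
    dyads = pd.DataFrame(
        rows,
        columns=[
            "sample_i", "sample_j", "individual_i", "individual_j", "y",
            "relatedness", "contact_raw", "subspecies_pair", "gut_section",
            "dyad_class", "same_litter",
        ],
    )
    dyads["contact"] = 0.0
    for group, sub in dyads.groupby("subspecies_pair"):
        lo, hi = sub["contact_raw"].min(), sub["contact_raw"].max()
        scaled = (sub["contact_raw"] - lo) / (hi - lo) if hi > lo else 0.0 * sub["contact_raw"]
        dyads.loc[sub.index, "contact"] = scaled
    return dyads


def _member_design(dyads: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    ids = sorted(set(dyads["individual_i"]) | set(dyads["individual_j"]))
    index = {m: i for i, m in enumerate(ids)}
    members = np.column_stack(
        [dyads["individual_i"].map(index), dyads["individual_j"].map(index)]
    ).astype(np.int64)
    return members, ids


def fit_mm_lmm(
    dyads: pd.DataFrame,
    terms: Sequence[str] = ("relatedness", "contact"),
    reml: bool = True,
) -> MMLmmFit:
    """Fit the dyadic multimembership LMM with the given fixed-effect terms."""
    def degenerate(t: str) -> bool:
        # a categorical factor with a single observed level carries no columns
        for p in t.split(":"):
            col = dyads[p]
            if (col.dtype == object or col.dtype == bool) and col.nunique() < 2:
                return True
        return False

    usable = [t for t in terms if not degenerate(t)]
    X, names, slices = build_design(dyads, usable)
    members, ids = _member_design(dyads)
    return fit_mm_lmm_core(
        X, dyads["y"].to_numpy(dtype=float), members, ids,
        reml=reml, coef_names=names, term_slices=slices,
    )


def lrt(full: MMLmmFit, reduced: MMLmmFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fixed effects on ML fits."""
    stat = max(0.0, 2.0 * (full.loglik_ml - reduced.loglik_ml))
    df = full.n_params_fixed - reduced.n_params_fixed
    return stat, df, float(chi2.sf(stat, df)) if df > 0 else 1.0


@dataclass
class StepwiseReport:
    final_terms: list[str]
    final_fit: MMLmmFit
    lrt_table: pd.DataFrame = field(repr=False)


def lrt_and_stepwise(
    dyads: pd.DataFrame,
    full_terms: Sequence[str] = DEFAULT_TERMS,
    alpha: float = 0.05,
) -> StepwiseReport:
    """Backward elimination with likelihood-ratio tests on ML fits.

    Interactions are removed before their main effects (marginality); at
    each round the least significant removable term with p >= alpha is
    dropped.  The returned LRT table records, for every term ever tested,
    the statistic from the round in which it was last evaluated.
    """
    terms = list(full_terms)
    records: dict[str, tuple[float, int, float, bool]] = {}
    while True:
        fit_full = fit_mm_lmm(dyads, terms, reml=False)
        removable = [
            t for t in terms
            if not any(t in term_parents(other) for other in terms if other != t)
        ]
        if not removable:
            break
        tests = []
        for t in removable:
            fit_red = fit_mm_lmm(dyads, [x for x in terms if x != t], reml=False)
            stat, df, p = lrt(fit_full, fit_red)
            tests.append((t, stat, df, p))
            records[t] = (stat, df, p, True)
        tests.sort(key=lambda x: -x[3])
        worst_term, stat, df, p = tests[0]
        if p >= alpha:
            terms.remove(worst_term)
            records[worst_term] = (stat, df, p, False)
        else:
            break
        if not terms:
            break
    final_fit = fit_mm_lmm(dyads, terms, reml=True)
    table = pd.DataFrame(
        [(t, *records[t][:3], records[t][3]) for t in records],
        columns=["term", "lrt_chi2", "df", "p_value", "retained"],
    )
    return StepwiseReport(final_terms=terms, final_fit=final_fit, lrt_table=table)


def variance_partition(fit: MMLmmFit, dyads: pd.DataFrame) -> pd.Series:
    """Fraction of total response variance attributed to each model term.

    For fixed term k, the contribution is the empirical variance of
    X_k beta_k over the dyads; the member random effect contributes
    2 sigma2_m (each dyad carries two member effects) and the residual
    sigma2_e.  Fractions sum to 1 by construction.
    """
    X, _, slices = build_design(dyads, [t for t in fit.term_slices if t != "(Intercept)"])
    parts: dict[str, float] = {}
    for term, sl in fit.term_slices.items():
        if term == "(Intercept)":
            continue
        contrib = X[:, sl] @ fit.beta[sl]
        parts[term] = float(np.var(contrib))
    parts["member"] = 2.0 * fit.sigma2_member
    parts["residual"] = fit.sigma2_resid
    total = sum(parts.values())
    return pd.Series({k: v / total for k, v in parts.items()}, name="variance_fraction")


@dataclass
class ExclusionComparison:
    full_fit: MMLmmFit
    excluded_fit: MMLmmFit
    full_fractions: pd.Series
    excluded_fractions: pd.Series
    n_dyads_removed: int


def exclusion_reanalysis(
    dyads: pd.DataFrame,
    terms: Sequence[str] = ("relatedness", "contact"),
) -> ExclusionComparison:
    """Refit after removing close-kin dyads (full sibs, parent–offspring).

    Quantifies how much of the relatedness/contact signal is carried by
    close family members versus the wider population.
    """
    mask = ~dyads["dyad_class"].isin(CLOSE_KIN_CLASSES)
    subset = dyads.loc[mask].reset_index(drop=True)
    n_ind = len(set(subset["individual_i"]) | set(subset["individual_j"]))
    if n_ind < 10:
        raise ValueError(
            f"only {n_ind} individuals remain after close-kin exclusion (need >= 10)"
        )
    fit_all = fit_mm_lmm(dyads, terms, reml=True)
    fit_ex = fit_mm_lmm(subset, terms, reml=True)
    return ExclusionComparison(
        full_fit=fit_all,
        excluded_fit=fit_ex,
        full_fractions=variance_partition(fit_all, dyads),
        excluded_fractions=variance_partition(fit_ex, subset),
        n_dyads_removed=int((~mask).sum()),
    )
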