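"""Multimembership linear mixed model for dyadic responses.

Each dyadic observation (a pair of individuals) loads on *both* members'
random effects: the random-effect design Z has one column per individual and
two unit entries per row.  The model is

    y = X beta + Z u + e,   u ~ N(0, sigma2_m I_q),   e ~ N(0, sigma2_e I_n)

and is estimated by profiling the likelihood over the variance ratio
gamma = sigma2_m / sigma2_e.  Writing V = sigma2_e * W with W = I + gamma Z Z',
all solves with W go through the Woodbury identity and the q x q Gram matrix
Z'Z (q = number of individuals), so the cost per criterion evaluation is
O(n q + q^3) rather than O(n^3).  The determinant uses Sylvester's identity
log|W| = log|I_q + gamma Z'Z|.

The same engine serves the dyadic similarity models, the age-trajectory
spline models (parent and offspring as members) and the unrelated-pair
baseline (intercept-only).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

__all__ = ["MMLmmFit", "fit_mm_lmm_core", "build_design", "term_parents"]

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# fixed-effect design construction
# ---------------------------------------------------------------------------

def term_parents(term: str) -> list[str]:
    """Marginality parents of an interaction term (``a:b`` -> ``a``, ``b``)."""
    parts = term.split(":")
    if len(parts) == 1:
        return []
    return [":".join(c) for k in range(1, len(parts))
            for c in _combinations(parts, k)]


def _combinations(items, k):
    from itertools import combinations

    return combinations(items, k)


def _column_block(df: pd.DataFrame, var: str) -> tuple[np.ndarray, list[str]]:
    col = df[var]
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
        levels = sorted(pd.unique(col.astype(str)))
        # treatment coding, first level is the reference
        block = np.column_stack([(col.astype(str) == lv).astype(float) for lv in levels[1:]]) \
            if len(levels) > 1 else np.zeros((len(df), 0))
        names = [f"{var}[{lv}]" for lv in levels[1:]]
        return block, names
    return col.to_numpy(dtype=float)[:, None], [var]


def build_design(
    df: pd.DataFrame, terms: Sequence[str]
) -> tuple[np.ndarray, list[str], dict[str, slice]]:
    """Build a fixed-effect design matrix from term names.

    Terms reference columns of ``df``; ``a:b`` denotes an interaction
    (elementwise products of the component blocks, categoricals
    treatment-coded).  An intercept column is always prepended.  Returns the
    matrix, per-column names, and a map from term to its column slice.
    """
    blocks = [np.ones((len(df), 1))]
    names = ["(Intercept)"]
    slices: dict[str, slice] = {"(Intercept)": slice(0, 1)}
    pos = 1
    for term in terms:
        parts = term.split(":")
        block, bnames = _column_block(df, parts[0])
        for p in parts[1:]:
            b2, n2 = _column_block(df, p)
            block = np.concatenate(
                [block[:, [i]] * b2 for i in range(block.shape[1])], axis=1
            ) if block.shape[1] and b2.shape[1] else np.zeros((len(df), 0))
            bnames = [f"{a}:{b}" for a in bnames for b in n2]
        blocks.append(block)
        names.extend(bnames)
        slices[term] = slice(pos, pos + block.shape[1])
        pos += block.shape[1]
    X = np.concatenate(blocks, axis=1)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"fixed-effect design is rank deficient ({rank} < {X.shape[1]}); "
            "drop aliased terms"
        )
    return X, names, slices


# ---------------------------------------------------------------------------
# profiled likelihood machinery
# ---------------------------------------------------------------------------

class _Workspace:
    """Cached pieces for criterion evaluations at varying gamma."""

    def __init__(self, X: np.ndarray, y: np.ndarray, Z: sp.csr_matrix):
        self.X, self.y, self.Z = X, y, Z
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        self.G = (Z.T @ Z).toarray()
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def criteria(self, gamma: float) -> dict:
        """Return both −2·loglik criteria and GLS quantities at ``gamma``."""
        n, p, q = self.n, self.p, self.q
        if gamma <= 0:
            XtWiX, XtWiy = self.XtX, self.Xty
            logdetW = 0.0
            ytWiy = self.yty
        else:
            M = gamma * self.G
            M[np.diag_indices(q)] += 1.0
            c, low = cho_factor(M, lower=True, check_finite=False)
            logdetW = 2.0 * float(np.sum(np.log(np.diag(c))))
            MiZtX = cho_solve((c, low), self.ZtX, check_finite=False)
            MiZty = cho_solve((c, low), self.Zty, check_finite=False)
            XtWiX = self.XtX - gamma * (self.ZtX.T @ MiZtX)
            XtWiy = self.Xty - gamma * (self.ZtX.T @ MiZty)
            ytWiy = self.yty - gamma * float(self.Zty @ MiZty)
        cx, lowx = cho_factor(XtWiX, lower=True, check_finite=False)
        beta = cho_solve((cx, lowx), XtWiy, check_finite=False)
        logdet_XtWiX = 2.0 * float(np.sum(np.log(np.diag(cx))))
        rWir = max(ytWiy - float(XtWiy @ beta), 1e-300)
        s2_ml = rWir / n
        s2_reml = rWir / (n - p)
        neg2_ml = n * (_LOG2PI + np.log(s2_ml)) + logdetW + n
        neg2_reml = (
            (n - p) * (_LOG2PI + np.log(s2_reml))
            + logdetW
            + logdet_XtWiX
            + (n - p)
        )
        return {
            "beta": beta,
            "XtWiX": XtWiX,
            "rWir": rWir,
            "s2_ml": s2_ml,
            "s2_reml": s2_reml,
            "neg2_ml": neg2_ml,
            "neg2_reml": neg2_reml,
        }


@dataclass
class MMLmmFit:
    """A fitted multimembership LMM."""

    term_names: list[str]
    coef_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray = field(repr=False)
    sigma2_member: float
    sigma2_resid: float
    gamma: float
    loglik_ml: float
    loglik_reml: float
    n_obs: int
    n_members: int
    reml: bool
    converged: bool
    term_slices: dict[str, slice] = field(repr=False, default_factory=dict)
    member_ids: list[str] = field(default_factory=list)

    @property
    def n_params_fixed(self) -> int:
        return len(self.beta)

    @property
    def aic(self) -> float:
        """ML-based AIC counting fixed effects and both variance components."""
        return -2.0 * self.loglik_ml + 2.0 * (self.n_params_fixed + 2)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.coef_names, "estimate": self.beta, "se": self.se}
        )


def fit_mm_lmm_core(
    X: np.ndarray,
    y: np.ndarray,
    members: np.ndarray,
    member_ids: Sequence[str],
    reml: bool = True,
    coef_names: Sequence[str] | None = None,
    term_slices: dict[str, slice] | None = None,
    gamma_bounds: tuple[float, float] = (1e-8, 1e6),
) -> MMLmmFit:
    """Fit the multimembership LMM by profiled likelihood over gamma.

    ``members`` is an (n, 2) integer array giving the two member indices of
    every observation (indices into ``member_ids``).  Both member columns
    share a single variance component and load with weight 1.  gamma is
    optimised on the log scale by bounded Brent search and compared with the
    gamma = 0 boundary (pure-noise responses collapse to OLS there).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    members = np.asarray(members, dtype=np.int64)
    n, p = X.shape
    if n != len(y) or members.shape != (n, 2):
        raise ValueError("inconsistent input shapes")
    q = len(member_ids)
    if q < 2:
        raise ValueError("need at least 2 distinct members")
    if n <= p:
        raise ValueError("more fixed-effect columns than observations")
    rows = np.repeat(np.arange(n), 2)
    Z = sp.csr_matrix(
        (np.ones(2 * n), (rows, members.ravel())), shape=(n, q)
    )
    ws = _Workspace(X, y, Z)
    key = "neg2_reml" if reml else "neg2_ml"

    def objective(log_gamma: float) -> float:
        return ws.criteria(float(np.exp(log_gamma))) [key]

    lo, hi = np.log(gamma_bounds[0]), np.log(gamma_bounds[1])
    res = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10, "maxiter": 500},
    )
    gamma = float(np.exp(res.x))
    at_opt = ws.criteria(gamma)
    at_zero = ws.criteria(0.0)
    if at_zero[key] <= at_opt[key]:
        gamma, at_opt = 0.0, at_zero
    # both criteria are reported at their own optima so that ML-based tests
    # and REML-based variance components are each taken at the right point
    other_key = "neg2_ml" if reml else "neg2_reml"
    res_o = minimize_scalar(
        lambda lg: ws.criteria(float(np.exp(lg)))[other_key],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10, "maxiter": 500},
    )
    other_opt = min(ws.criteria(float(np.exp(res_o.x)))[other_key],
                    at_zero[other_key])
    neg2 = {key: at_opt[key], other_key: other_opt}

    s2e = at_opt["s2_reml"] if reml else at_opt["s2_ml"]
    cov_beta = s2e * np.linalg.inv(at_opt["XtWiX"])
    se = np.sqrt(np.diag(cov_beta))
    return MMLmmFit(
        term_names=list(term_slices or {}),
        coef_names=list(coef_names or [f"b{i}" for i in range(p)]),
        beta=at_opt["beta"],
        se=se,
        cov_beta=cov_beta,
        sigma2_member=gamma * s2e,
        sigma2_resid=s2e,
        gamma=gamma,
        loglik_ml=-0.5 * neg2["neg2_ml"],
        loglik_reml=-0.5 * neg2["neg2_reml"],
        n_obs=n,
        n_members=q,
        reml=reml,
        converged=bool(res.success),
        term_slices=term_slices or {},
        member_ids=list(member_ids),
    )


def dense_neg2_reml(X, y, Z, sigma2_m, sigma2_e):
    """Dense-matrix −2·REML log-likelihood, for oracle comparisons.

    Builds V = sigma2_m ZZ' + sigma2_e I explicitly and evaluates the REML
    criterion by generic dense linear algebra; only usable for tiny
    instances.
    """
    Z = np.asarray(Z, dtype=float)
    n, p = X.shape
    V = sigma2_m * (Z @ Z.T) + sigma2_e * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    return float((n - p) * _LOG2PI + ldV + ldX + r @ Vi @ r)


def dense_neg2_ml(X, y, Z, sigma2_m, sigma2_e):
    """Dense-matrix −2·ML log-likelihood (oracle counterpart)."""
    Z = np.asarray(Z, dtype=float)
    n, p = X.shape
    V = sigma2_m * (Z @ Z.T) + sigma2_e * np.eye(n)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ beta
    _, ldV = np.linalg.slogdet(V)
    return float(n * _LOG2PI + ldV + r @ Vi @ r)
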