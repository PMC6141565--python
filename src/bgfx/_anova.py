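"""Sequential (model-order) sum-of-squares ANOVA for fixed-effects linear models.

The genome scans test one focal term per model against permutation-derived
thresholds, so the primitives here are built for that access pattern: a model
is an ordered list of named column blocks, each block is orthonormalized
against everything before it, and the block's sum of squares is the squared
norm of the response projected onto that basis.  Because permutations shuffle
only the response, a single orthonormal basis serves every response column,
which is what makes 1000-permutation scans tractable.

Conventions: an intercept is always implicit and comes first; the p-value
floor is 1e-300; a block whose columns are entirely within the span of the
preceding terms has zero degrees of freedom and is reported untestable rather
than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300
#: relative tolerance for declaring a projected column linearly dependent
RANK_RTOL = 1e-8


def orthonormal_block(
    X: np.ndarray, Q_prev: np.ndarray | None, rtol: float = RANK_RTOL
) -> np.ndarray:
    """Orthonormal basis for the part of ``X`` outside the span of ``Q_prev``.

    Returns an (n, r) matrix with r = rank of the residual block; r may be 0.
    ``Q_prev`` must have orthonormal columns.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 1:
        X = X[:, None]
    norms0 = np.linalg.norm(X, axis=0)
    R = X.copy()
    if Q_prev is not None and Q_prev.shape[1]:
        R -= Q_prev @ (Q_prev.T @ X)
        # second pass guards against cancellation in near-dependent designs
        R -= Q_prev @ (Q_prev.T @ R)
    if R.shape[1] > 2:
        # rank-revealing pivoted QR; the first `rank` Q columns span col(R)
        from scipy.linalg import qr

        Qm, Rm, _ = qr(R, mode="economic", pivoting=True)
        diag = np.abs(np.diag(Rm))
        ref = max(float(norms0.max(initial=0.0)), 1.0)
        rank = int(np.sum(diag > rtol * ref))
        return Qm[:, :rank]
    basis: list[np.ndarray] = []
    for j in range(R.shape[1]):
        v = R[:, j].copy()
        for q in basis:
            v -= q * (q @ v)
        nv = np.linalg.norm(v)
        if nv > rtol * max(norms0[j], 1.0):
            basis.append(v / nv)
    if not basis:
        return np.empty((X.shape[0], 0))
    return np.column_stack(basis)


@dataclass(frozen=True)
class TermBasis:
    """Orthonormal bases of a model's term blocks, in model order."""

    names: tuple[str, ...]
    blocks: tuple[np.ndarray, ...]  # per-term orthonormal columns
    Q_full: np.ndarray  # intercept + all term bases
    n: int

    @property
    def df_resid(self) -> int:
        return self.n - self.Q_full.shape[1]

    def term_df(self, name: str) -> int:
        return self.blocks[self.names.index(name)].shape[1]


def build_term_basis(blocks: list[tuple[str, np.ndarray]], n: int) -> TermBasis:
    """Sequentially orthonormalize named column blocks after an intercept."""
    Q = np.full((n, 1), 1.0 / np.sqrt(n))
    names: list[str] = []
    bases: list[np.ndarray] = []
    for name, X in blocks:
        B = orthonormal_block(X, Q)
        names.append(name)
        bases.append(B)
        if B.shape[1]:
            Q = np.hstack([Q, B])
    return TermBasis(tuple(names), tuple(bases), Q, n)


def _f_pvalue(F: np.ndarray, df1: int, df2: int) -> np.ndarray:
    p = stats.f.sf(F, df1, df2)
    return np.maximum(p, P_FLOOR)


def sequential_anova(
    y: np.ndarray, blocks: list[tuple[str, np.ndarray]]
) -> pd.DataFrame:
    """Type-I (sequential) ANOVA table for one response.

    Parameters
    ----------
    y
        Response vector of length n.
    blocks
        Ordered ``(term_name, design_columns)`` pairs; an intercept is
        implicit and always precedes them.

    Returns a DataFrame indexed by term name (plus a ``"residual"`` row) with
    columns ``df``, ``ss``, ``F``, ``p``.  Terms with zero residual degrees of
    freedom after orthogonalization get ``df = 0`` and NaN statistics.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    tb = build_term_basis(blocks, n)
    rows = []
    yty = y @ y
    explained = (np.full(n, 1.0 / np.sqrt(n)) @ y) ** 2
    term_ss = []
    for name, B in zip(tb.names, tb.blocks):
        proj = B.T @ y if B.shape[1] else np.empty(0)
        ss = float(proj @ proj)
        term_ss.append((name, B.shape[1], ss))
        explained += ss
    ss_resid = max(yty - explained, 0.0)
    df_resid = tb.df_resid
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan
    tol = RANK_RTOL * max(yty, 1.0)
    for name, df, ss in term_ss:
        if df == 0:
            rows.append((name, 0, 0.0, np.nan, np.nan))
        elif df_resid <= 0 or ss_resid <= tol:
            if ss > tol:
                # perfect-fit branch: p reported at the floor
                rows.append((name, df, ss, np.inf, P_FLOOR))
            elif df_resid > 0:
                rows.append((name, df, ss, 0.0, 1.0))
            else:
                rows.append((name, df, ss, np.nan, np.nan))
        else:
            F = (ss / df) / ms_resid
            rows.append((name, df, ss, F, float(_f_pvalue(np.array(F), df, df_resid))))
    rows.append(("residual", df_resid, ss_resid, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["term", "df", "ss", "F", "p"]
    ).set_index("term")


def focal_pvalues(
    Y: np.ndarray,
    Q_pre: np.ndarray,
    focal: np.ndarray,
    sumsq_Y: np.ndarray | None = None,
    pre_proj_sq: np.ndarray | None = None,
) -> np.ndarray:
    """Focal-term sequential-F p-values for many response columns at once.

    ``Q_pre`` is the orthonormal basis (including intercept) of every term
    preceding the focal block; ``focal`` holds the focal block's raw columns.
    ``sumsq_Y`` and ``pre_proj_sq`` are optional precomputed per-column
    ``sum(Y**2)`` and ``sum((Q_pre.T @ Y)**2)``.

    Returns an array of shape (Y.shape[1],); NaN where the focal term is not
    estimable or residual df is exhausted.
    """
    B = orthonormal_block(focal, Q_pre)
    df1 = B.shape[1]
    n = Y.shape[0]
    if sumsq_Y is None:
        sumsq_Y = np.einsum("ij,ij->j", Y, Y)
    if pre_proj_sq is None:
        P = Q_pre.T @ Y
        pre_proj_sq = np.einsum("ij,ij->j", P, P)
    if df1 == 0:
        return np.full(Y.shape[1], np.nan)
    PF = B.T @ Y
    ss_focal = np.einsum("ij,ij->j", PF, PF)
    df2 = n - Q_pre.shape[1] - df1
    if df2 <= 0:
        return np.full(Y.shape[1], np.nan)
    ss_resid = np.maximum(sumsq_Y - pre_proj_sq - ss_focal, 0.0)
    scale = np.maximum(sumsq_Y, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_focal / df1) / (ss_resid / df2)
    p = _f_pvalue(F, df1, df2)
    # perfect fit: residual numerically zero but focal SS present
    p = np.where((ss_resid <= RANK_RTOL * scale) & (ss_focal > 0), P_FLOOR, p)
    return p


def ols_fit(X: np.ndarray, y: np.ndarray) -> dict:
    """Least-squares fit with pivoted-QR rank handling.

    Returns coefficient estimates, standard errors, t statistics and two-sided
    p-values; aliased (rank-deficient) columns get NaN throughout so callers
    can flag inestimable contrasts instead of reporting garbage.  Columns are
    admitted left to right, so a column collinear with earlier ones is the one
    dropped (matching R's lm behavior).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    norms = np.linalg.norm(X, axis=0)
    keep_list: list[int] = []
    Q: list[np.ndarray] = []
    for j in range(k):
        v = X[:, j].astype(float).copy()
        for q in Q:
            v -= q * (q @ v)
        for q in Q:
            v -= q * (q @ v)
        nv = np.linalg.norm(v)
        if nv > RANK_RTOL * max(norms[j], 1.0):
            Q.append(v / nv)
            keep_list.append(j)
    rank = len(keep_list)
    keep = np.array(keep_list, dtype=int)
    Xk = X[:, keep]
    beta_k, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ beta_k
    df_resid = n - rank
    sigma2 = float(resid @ resid) / df_resid if df_resid > 0 else np.nan
    XtX_inv = np.linalg.pinv(Xk.T @ Xk)
    se_k = np.sqrt(np.maximum(np.diag(XtX_inv), 0.0) * sigma2)
    beta = np.full(k, np.nan)
    se = np.full(k, np.nan)
    beta[keep] = beta_k
    se[keep] = se_k
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = np.full(k, np.nan)
    if df_resid > 0:
        ok = np.isfinite(t)
        p[ok] = np.maximum(2.0 * stats.t.sf(np.abs(t[ok]), df_resid), P_FLOOR)
    return {
        "beta": beta,
        "se": se,
        "t": t,
        "p": p,
        "df_resid": df_resid,
        "sigma2": sigma2,
        "aliased": ~np.isin(np.arange(k), keep),
        "resid": resid,
    }
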