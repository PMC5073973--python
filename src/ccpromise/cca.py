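"""Per-gene canonical correlation analysis.

For a gene with expression matrix X (n x F) and methylation matrix M
(n x L), canonical correlation analysis finds the linear combinations of
the columns of each matrix that are maximally correlated. The resulting
per-subject score pair summarises each molecular data type in one variable;
the leading canonical correlation r_cc measures how strongly the two data
types co-vary for that gene.

Implementation: columns are standardized, each block is reduced to an
orthonormal basis by SVD with rank truncation (pseudoinverse-style
whitening), and the canonical correlations are the singular values of the
cross-product of the two bases. Rank truncation makes the fit well defined
when markers are collinear or outnumber subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

VAR_TOL = 1e-12  # columns below this variance are dropped
RANK_RTOL = 1e-8  # relative singular-value cutoff for whitening


class DegenerateGeneError(ValueError):
    """All columns constant on one side: no canonical correlation exists."""


@dataclass
class CCAResult:
    """First canonical pair for one gene.

    ``expr_scores`` and ``meth_scores`` have unit sample variance (ddof=1);
    after :func:`orient_scores` their correlation is ``+r_cc``.
    ``effective_rank`` is the retained rank of (expression, methylation)
    after dropping constant columns and truncating tiny singular values.
    """

    r_cc: float
    expr_weights: np.ndarray
    meth_weights: np.ndarray
    expr_scores: np.ndarray
    meth_scores: np.ndarray
    p_cc: float
    effective_rank: tuple[int, int]
    oriented: bool = False


def _standardize(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale columns; returns (standardized matrix, kept column mask)."""
    A = np.asarray(A, dtype=float)
    mu = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1)
    keep = sd > VAR_TOL
    Z = (A[:, keep] - mu[keep]) / sd[keep]
    return Z, keep


def _orthobasis(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD with relative rank truncation; returns (U_r, s_r, Vt_r)."""
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    r = int(np.sum(s > RANK_RTOL * s[0]))
    return U[:, :r], s[:r], Vt[:r]


def _bartlett_pvalue(rhos: np.ndarray, n: int, p: int, q: int) -> float:
    """Bartlett's chi-square approximation to Wilks' Lambda.

    Tests that all canonical correlations are zero using the retained ranks
    p and q: -(n - 1 - (p + q + 1) / 2) * log(prod(1 - rho^2)) ~ chi2(p * q).
    """
    lam = np.prod(1.0 - np.clip(rhos, 0.0, 1.0 - 1e-15) ** 2)
    if lam <= 0:
        return float(np.finfo(float).tiny)
    statistic = -(n - 1 - (p + q + 1) / 2.0) * np.log(lam)
    statistic = max(statistic, 0.0)
    return float(stats.chi2.sf(statistic, p * q))


def fit_cca(X: np.ndarray, M: np.ndarray) -> CCAResult:
    """First canonical correlation of expression X (n x F) vs methylation M (n x L).

    Requires n >= 4 and at least one non-constant column per block. Scores
    are scaled to unit sample variance. ``p_cc`` tests the null hypothesis
    that every canonical correlation is zero (Bartlett's approximation).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if X.ndim != 2 or M.ndim != 2 or X.shape[0] != M.shape[0]:
        raise ValueError("X and M must be 2-D with a common number of rows (subjects)")
    n = X.shape[0]
    if n < 4:
        raise ValueError(f"need n >= 4 subjects for CCA, got {n}")
    Zx, keep_x = _standardize(X)
    Zm, keep_m = _standardize(M)
    if Zx.shape[1] == 0 or Zm.shape[1] == 0:
        raise DegenerateGeneError("all columns constant in one block")

    Ux, sx, Vtx = _orthobasis(Zx)
    Um, sm, Vtm = _orthobasis(Zm)
    C = Ux.T @ Um
    Uc, rhos, Vtc = np.linalg.svd(C)
    rhos = np.clip(rhos, 0.0, 1.0)
    r_cc = float(rhos[0])

    # weights mapped back to the original (dropped-column) feature space,
    # scaled so that Z @ w reproduces the unit-variance scores
    scale = np.sqrt(n - 1.0)
    wx_kept = Vtx.T @ (Uc[:, 0] / sx) * scale
    wm_kept = Vtm.T @ (Vtc[0] / sm) * scale
    expr_weights = np.zeros(X.shape[1])
    meth_weights = np.zeros(M.shape[1])
    expr_weights[keep_x] = wx_kept
    meth_weights[keep_m] = wm_kept

    expr_scores = (Ux @ Uc[:, 0]) * scale
    meth_scores = (Um @ Vtc[0]) * scale

    p_cc = _bartlett_pvalue(rhos, n, Ux.shape[1], Um.shape[1])
    return CCAResult(
        r_cc=r_cc,
        expr_weights=expr_weights,
        meth_weights=meth_weights,
        expr_scores=expr_scores,
        meth_scores=meth_scores,
        p_cc=p_cc,
        effective_rank=(Ux.shape[1], Um.shape[1]),
    )


def orient_scores(result: CCAResult, X: np.ndarray) -> CCAResult:
    """Resolve the sign ambiguity of the canonical score pair.

    The expression score is flipped, if needed, so that its correlation with
    the mean of the standardized expression columns is non-negative (exact
    zero: keep the current sign); the methylation score is then flipped, if
    needed, so that corr(expression score, methylation score) >= 0. After
    orientation the sign multiplier entering the gene-level combined
    statistic is +1.
    """
    Zx, _ = _standardize(np.atleast_2d(np.asarray(X, dtype=float)))
    ref = Zx.mean(axis=1)
    c_ref = float(result.expr_scores @ ref)
    sx = -1.0 if c_ref < 0 else 1.0
    expr_scores = result.expr_scores * sx
    expr_weights = result.expr_weights * sx
    c_xm = float(expr_scores @ result.meth_scores)
    sm = -1.0 if c_xm < 0 else 1.0
    return replace(
        result,
        expr_scores=expr_scores,
        expr_weights=expr_weights,
        meth_scores=result.meth_scores * sm,
        meth_weights=result.meth_weights * sm,
        oriented=True,
    )
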