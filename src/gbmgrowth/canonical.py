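"""Canonical measurement metrics between radiomic feature blocks.

Quantifies how strongly a block of tumor-volume measurements relates to
a block of spatial or histology features: canonical correlations from
the cross-covariance structure, the Wilks' Lambda test of block
independence with Rao's F approximation, and simple Pearson correlation
screens with significance stars.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["canonical_correlations", "wilks_lambda_test", "WilksLambdaResult",
           "correlation_screen"]


def _validate_blocks(X, Y) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    if Y.shape[0] == 1 and Y.shape[1] > 1:
        Y = Y.T
    if X.shape[0] != Y.shape[0]:
        raise ValueError("blocks must have equal row counts")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("blocks must be finite")
    if np.any(X.std(axis=0) <= 0) or np.any(Y.std(axis=0) <= 0):
        raise ValueError("blocks must not contain constant columns")
    return X, Y


def canonical_correlations(X, Y) -> np.ndarray:
    """Canonical correlations between two feature blocks, descending.

    Computed as the singular values of ``Qx' Qy`` where ``Qx`` and
    ``Qy`` are orthonormal bases of the centered blocks — the stable
    equivalent of the generalized eigenproblem of the cross-covariance
    matrices.  Rank-deficient blocks yield fewer correlations, with a
    warning.
    """
    X, Y = _validate_blocks(X, Y)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    qx, rx, px = _economy_basis(Xc)
    qy, ry, py = _economy_basis(Yc)
    if qx.shape[1] < X.shape[1] or qy.shape[1] < Y.shape[1]:
        warnings.warn("rank-deficient block: returning fewer canonical "
                      "correlations", RuntimeWarning)
    rho = np.linalg.svd(qx.T @ qy, compute_uv=False)
    return np.clip(rho, 0.0, 1.0)


def _economy_basis(A: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Orthonormal basis of the column space, rank-truncated."""
    q, r = np.linalg.qr(A)
    diag = np.abs(np.diag(r))
    tol = max(A.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    keep = diag > tol
    return q[:, keep], r[keep], int(keep.sum())


@dataclasses.dataclass(frozen=True)
class WilksLambdaResult:
    """One row of the block-association table: Lambda, Rao's F, dfs,
    p-value and the leading canonical correlation."""

    lambda_: float
    f_stat: float
    df1: float
    df2: float
    p_value: float
    rho: float
    n_complete: int

    def to_row(self) -> dict:
        return {"F-Stat.": self.f_stat, "p-Val.": self.p_value,
                "rho": self.rho, "Lambda": self.lambda_,
                "df1": self.df1, "df2": self.df2, "n": self.n_complete}


def wilks_lambda_test(X, Y) -> WilksLambdaResult:
    """Wilks' Lambda test of independence between two blocks.

    ``Lambda = prod(1 - rho_i^2)`` over canonical correlations, with
    Rao's F approximation (exact when min(p, q) <= 2).  Requires
    ``n > p + q`` for positive error degrees of freedom.
    """
    X, Y = _validate_blocks(X, Y)
    n, p = X.shape
    q = Y.shape[1]
    if n <= p + q:
        raise ValueError(f"need n > p + q for the F approximation "
                         f"(n={n}, p={p}, q={q})")
    rho = canonical_correlations(X, Y)
    lam = float(np.prod(1.0 - rho ** 2))
    pq = p * q
    s2 = (p ** 2 * q ** 2 - 4) / (p ** 2 + q ** 2 - 5) if p ** 2 + q ** 2 - 5 > 0 else 1.0
    s = float(np.sqrt(s2))
    m = n - 1.5 - (p + q) / 2.0
    df1 = float(pq)
    df2 = float(m * s - pq / 2.0 + 1.0)
    if df2 <= 0:
        raise ValueError("nonpositive error degrees of freedom")
    lam_s = lam ** (1.0 / s) if lam > 0 else 0.0
    if lam_s == 0:
        f_stat = float("inf")
        p_value = 0.0
    else:
        f_stat = (1.0 - lam_s) / lam_s * df2 / df1
        p_value = float(stats.f.sf(f_stat, df1, df2))
    return WilksLambdaResult(lambda_=lam, f_stat=float(f_stat), df1=df1,
                             df2=df2, p_value=p_value, rho=float(rho[0]),
                             n_complete=n)


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_screen(table: pd.DataFrame, block_a: list[str],
                       block_b: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between two column blocks.

    Returns ``(r, annotated)``: the correlation matrix and a matrix of
    strings like ``"0.42**"`` starred at 0.05 / 0.01 / 0.001.  Pairs
    involving a constant column are flagged as NaN.  Rows with missing
    values are dropped pairwise (complete cases per pair).
    """
    missing = (set(block_a) | set(block_b)) - set(table.columns)
    if missing:
        raise ValueError(f"columns not in table: {sorted(missing)}")
    r = pd.DataFrame(index=block_a, columns=block_b, dtype=float)
    annotated = pd.DataFrame(index=block_a, columns=block_b, dtype=object)
    for a in block_a:
        for b in block_b:
            pair = pd.DataFrame({"x": table[a], "y": table[b]}).dropna()
            x, y = pair["x"].to_numpy(float), pair["y"].to_numpy(float)
            if len(x) < 3 or x.std() == 0 or y.std() == 0:
                r.loc[a, b] = np.nan
                annotated.loc[a, b] = "n/a"
                continue
            rr, pp = stats.pearsonr(x, y)
            r.loc[a, b] = rr
            annotated.loc[a, b] = f"{rr:.2f}{_stars(pp)}"
    return r, annotated
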