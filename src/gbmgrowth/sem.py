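"""Structural-equation measurement model for heterogeneous radiomic features.

Manifest feature vectors are expressed as intercept + loadings x latent
factors + diagonal Gaussian error:

    x = gamma + Lambda eta + delta,   delta ~ N(0, Theta),  Theta diagonal.

The endogenous block (radiomic features) and the exogenous block
(survival length, age) each get their own factor model.  Estimation is
EM for the Gaussian factor-analysis likelihood; identification fixes the
first loading of every factor to 1 (the latent variance is then free).
Latent posterior-mean scores replace the raw covariates in the Bayesian
regression, which is how heterogeneity across subjects' oncogene
profiles enters the prediction model.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["SemSpec", "SemMeasurementModel", "fit_sem_measurement"]


@dataclasses.dataclass
class SemSpec:
    """Fitted two-block measurement structure."""

    endogenous: "SemMeasurementModel"
    exogenous: "SemMeasurementModel | None"
    endo_columns: list[str]
    exo_columns: list[str]

    @property
    def q1(self) -> int:
        return len(self.endo_columns)

    @property
    def q2(self) -> int:
        return len(self.exo_columns)

    def scores(self, table: pd.DataFrame) -> pd.DataFrame:
        """Latent posterior-mean scores for both blocks, one column per
        factor (eta1_*, eta2_*)."""
        out = {}
        eta1 = self.endogenous.transform(table[self.endo_columns].to_numpy(float))
        for d in range(eta1.shape[1]):
            out[f"eta1_{d}"] = eta1[:, d]
        if self.exogenous is not None and self.exo_columns:
            eta2 = self.exogenous.transform(table[self.exo_columns].to_numpy(float))
            for d in range(eta2.shape[1]):
                out[f"eta2_{d}"] = eta2[:, d]
        return pd.DataFrame(out, index=table.index)


class SemMeasurementModel:
    """EM-estimated Gaussian factor model with diagonal error variances.

    Parameters
    ----------
    n_factors : int
        Latent dimensionality (d1 or d2); 1 by default.
    tol : float
        Relative log-likelihood improvement threshold for EM.
    max_iter : int
        EM iteration cap.
    seed : int
        Initialization seed (loadings start near a scaled PCA solution
        with a small seeded perturbation).

    Fitted attributes
    -----------------
    intercepts_ : (q,) measurement intercepts (column means).
    loadings_ : (q, d) loadings, first loading per factor fixed to 1.
    latent_cov_ : (d, d) latent covariance (free because of the
        first-loading identification).
    theta_ : (q,) diagonal measurement-error variances.
    loglik_path_ : per-iteration observed-data log-likelihood,
        nondecreasing.
    heywood_ : True when an error variance had to be floored.
    """

    _FLOOR = 1e-8

    def __init__(self, n_factors: int = 1, tol: float = 1e-8,
                 max_iter: int = 500, seed: int = 0):
        self.n_factors = n_factors
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k)
                for k in ("n_factors", "tol", "max_iter", "seed")}

    def set_params(self, **params) -> "SemMeasurementModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- EM ---------------------------------------------------------------
    def fit(self, X: np.ndarray) -> "SemMeasurementModel":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x manifest variables)")
        n, q = X.shape
        d = self.n_factors
        if n <= q:
            raise ValueError("need more rows than manifest variables")
        if d < 1 or d >= q:
            raise ValueError("n_factors must be in [1, q)")
        self.intercepts_ = X.mean(axis=0)
        Xc = X - self.intercepts_
        S = (Xc.T @ Xc) / n

        rng = np.random.default_rng(self.seed)
        # PCA-flavored start, slightly perturbed so repeated fits with
        # different seeds explore distinct basins
        evals, evecs = np.linalg.eigh(S)
        order = np.argsort(evals)[::-1]
        L = evecs[:, order[:d]] * np.sqrt(np.maximum(evals[order[:d]], 1e-6))
        L = L + 0.01 * rng.normal(size=L.shape) * np.abs(L).mean()
        psi = np.maximum(np.diag(S) - np.sum(L ** 2, axis=1), 0.1 * np.diag(S))

        loglik_path = []
        prev = -np.inf
        heywood = False
        for _ in range(self.max_iter):
            # E step: eta | x ~ N(B xc, Sigma_eta), B = (I + L'Psi^-1 L)^-1 L'Psi^-1
            psi = np.maximum(psi, self._FLOOR)
            Li = L / psi[:, None]
            M = np.eye(d) + L.T @ Li  # I + L' Psi^-1 L
            Minv = np.linalg.inv(M)
            B = Minv @ Li.T  # (d, q)
            Ez = Xc @ B.T  # (n, d)
            Ezz = n * Minv + Ez.T @ Ez  # sum_i E[eta eta']

            ll = self._loglik(S, L, psi, n)
            loglik_path.append(ll)
            if np.isfinite(prev) and abs(ll - prev) < self.tol * (1.0 + abs(ll)):
                prev = ll
                break
            prev = ll

            # M step
            L = (Xc.T @ Ez) @ np.linalg.inv(Ezz)
            # psi_j = S_jj - sum_d L_jd * (1/n) sum_i E[eta_d] x_ij
            cross = Xc.T @ Ez / n  # (q, d)
            psi = np.diag(S) - np.sum(L * cross, axis=1)
            if np.any(psi <= self._FLOOR):
                heywood = True
                psi = np.maximum(psi, self._FLOOR)

        # identification: first loading per factor scaled to 1
        scale = L[0, :].copy()
        if np.any(np.abs(scale) < 1e-12):
            raise RuntimeError("first manifest variable does not load on "
                               "every factor; reorder columns")
        Lid = L / scale[None, :]
        # raw latent factors have unit prior variance, so the identified
        # scale carries variance scale^2 per factor
        self.loadings_ = Lid
        self.latent_cov_ = np.diag(scale ** 2)
        self.theta_ = psi
        self.loglik_path_ = np.asarray(loglik_path)
        self.heywood_ = heywood
        self.n_iter_ = len(loglik_path)
        self._L_raw = L
        self._psi = psi
        return self

    def _loglik(self, S: np.ndarray, L: np.ndarray, psi: np.ndarray,
                n: int) -> float:
        q = S.shape[0]
        Sigma = L @ L.T + np.diag(psi)
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            return -np.inf
        return float(-0.5 * n * (q * np.log(2 * np.pi) + logdet
                                 + np.trace(np.linalg.solve(Sigma, S))))

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Posterior-mean latent scores on the identified (first
        loading = 1) scale."""
        if not hasattr(self, "loadings_"):
            raise RuntimeError("SemMeasurementModel is not fitted; call fit()")
        X = np.asarray(X, dtype=float)
        Xc = X - self.intercepts_
        L, psi = self._L_raw, np.maximum(self._psi, self._FLOOR)
        d = L.shape[1]
        Li = L / psi[:, None]
        M = np.eye(d) + L.T @ Li
        scores_raw = Xc @ (np.linalg.solve(M, Li.T)).T
        # raw latent scale eta_raw relates to identified scale by
        # eta_id = scale * eta_raw (loadings were divided by scale)
        scale = L[0, :]
        return scores_raw * scale[None, :]

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Model-implied manifest values from the latent scores."""
        eta_id = self.transform(X)
        return self.intercepts_ + eta_id @ self.loadings_.T


def fit_sem_measurement(table: pd.DataFrame, endo_columns: list[str],
                        exo_columns: list[str] | None = None,
                        d1: int = 1, d2: int = 1, tol: float = 1e-8,
                        max_iter: int = 500, seed: int = 0) -> SemSpec:
    """Fit the two-block measurement model on complete-case rows.

    The endogenous block (radiomic features) gets ``d1`` factors, the
    exogenous block (survival length, age) ``d2``.  Raises if fewer
    complete rows than q1 + q2 are available.
    """
    exo_columns = exo_columns or []
    cols = list(endo_columns) + list(exo_columns)
    complete = table[cols].dropna()
    if len(complete) <= len(cols):
        raise ValueError(f"only {len(complete)} complete rows for "
                         f"{len(cols)} manifest variables")
    endo = SemMeasurementModel(n_factors=d1, tol=tol, max_iter=max_iter,
                               seed=seed)
    endo.fit(complete[list(endo_columns)].to_numpy(float))
    exo = None
    if exo_columns:
        exo = SemMeasurementModel(n_factors=d2, tol=tol, max_iter=max_iter,
                                  seed=seed + 1)
        exo.fit(complete[list(exo_columns)].to_numpy(float))
    return SemSpec(endogenous=endo, exogenous=exo,
                   endo_columns=list(endo_columns),
                   exo_columns=list(exo_columns))
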