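"""Step-wise Bayesian growth model for malignant cell populations.

The model couples two stages at each migration step ``t``:

* a **detection** stage — conditional on ``m_t`` cells proliferating in
  the incremental region, the number of malignant ones among them is
  hypergeometric, drawing from the ``nu - M_{t-1}`` still-undetected
  cells of which ``nu* - M*_{t-1}`` are malignant;
* a **proliferation** stage — ``m_t`` itself is Poisson with mean
  ``nu * lam`` (mode ``"literal"``) or ``(nu - M_{t-1}) * lam``
  (mode ``"depleted"``).

The product over steps is the likelihood ``L(nu, nu*; lam)``, maximized
by Newton-Raphson on the continuous relaxation of the counts.  A
weighted Poisson prior (Poisson pmf times its coefficient of variation)
over the per-step malignant counts yields a posterior weight ``H_t`` per
step; the posterior mean ``H_mean`` scales the initial tumor volume into
the eventual volume ``V_new = c * H_mean * V_initial``.  Finally a
geometric construction converts a detected count ``k`` into the
probability ``(k / (k+1))**r`` that no malignant cell went undetected.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy.special import gammaln, logsumexp

from .trajectory import CellTrajectory, GrowthParameters, PosteriorSummary

__all__ = [
    "detection_pmf",
    "proliferation_pmf",
    "joint_step_pmf",
    "log_likelihood",
    "fit_mle",
    "fit_lambda_star",
    "weighted_prior",
    "posterior",
    "eventual_volume",
    "prob_no_undetected",
    "ConvergenceReport",
    "TumorGrowthModel",
]

_NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# probability primitives
# ---------------------------------------------------------------------------

def _log_binom(n: float, k: float) -> float:
    """log C(n, k) on the continuous (gamma-function) relaxation.

    Requires n >= k >= 0; returns -inf otherwise so infeasible
    configurations act as a barrier during optimization.
    """
    if k < 0 or n < k:
        return _NEG_INF
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def detection_pmf(m_star: int, m: int, remaining_total: float,
                  remaining_malignant: float) -> float:
    """Hypergeometric probability of detecting ``m_star`` malignant cells.

    Among ``remaining_total = nu - M_{t-1}`` undetected cells, of which
    ``remaining_malignant = nu* - M*_{t-1}`` are malignant, ``m`` cells
    proliferate; the probability that exactly ``m_star`` of them are
    malignant is ``C(K, k) C(N-K, m-k) / C(N, m)``.
    """
    if m_star < 0 or m < 0 or remaining_total < 0 or remaining_malignant < 0:
        raise ValueError("detection_pmf arguments must be nonnegative")
    if remaining_malignant > remaining_total:
        raise ValueError("remaining_malignant must not exceed remaining_total")
    if m > remaining_total:
        raise ValueError("cannot draw more cells than remain undetected")
    if m_star > m:
        raise ValueError("m_star must not exceed m")
    N, K = float(remaining_total), float(remaining_malignant)
    log_p = (_log_binom(K, m_star)
             + _log_binom(N - K, m - m_star)
             - _log_binom(N, m))
    return 0.0 if log_p == _NEG_INF else float(math.exp(log_p))


def proliferation_pmf(m: int, params: GrowthParameters, M_prev: int = 0,
                      mode: str = "literal") -> float:
    """Poisson probability of ``m`` cells proliferating at a step."""
    if m < 0 or M_prev < 0:
        raise ValueError("m and M_prev must be nonnegative")
    mu = _poisson_mean(params.nu, params.lam, M_prev, mode)
    if mu <= 0:
        raise ValueError("Poisson mean must be positive")
    return float(math.exp(m * math.log(mu) - mu - gammaln(m + 1.0)))


def _poisson_mean(nu: float, lam: float, M_prev: float, mode: str) -> float:
    if mode == "literal":
        return nu * lam
    if mode == "depleted":
        return (nu - M_prev) * lam
    raise ValueError(f"unknown mode {mode!r}; use 'literal' or 'depleted'")


def joint_step_pmf(m: int, m_star: int, params: GrowthParameters,
                   M_prev: int = 0, M_star_prev: int = 0,
                   mode: str = "literal") -> float:
    """Joint pmf of (m_t, m*_t): detection factor times proliferation factor."""
    det = detection_pmf(m_star, m, params.nu - M_prev,
                        params.nu_star - M_star_prev)
    return det * proliferation_pmf(m, params, M_prev, mode)


def _log_binom_vec(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def _log_likelihood_raw(m: np.ndarray, m_star: np.ndarray, nu: float,
                        nu_star: float, lam: float, mode: str) -> float:
    """Sum of per-step log joint pmfs; -inf for any infeasible config."""
    if nu <= 0 or nu_star < 0 or nu_star > nu or lam <= 0:
        return _NEG_INF
    m = np.asarray(m, dtype=float)
    k = np.asarray(m_star, dtype=float)
    M_prev = np.concatenate([[0.0], np.cumsum(m)[:-1]])
    Ms_prev = np.concatenate([[0.0], np.cumsum(k)[:-1]])
    N = nu - M_prev
    K = nu_star - Ms_prev
    if np.any(N < m) or np.any(K < k) or np.any((N - K) < (m - k)):
        return _NEG_INF
    log_det = (_log_binom_vec(K, k) + _log_binom_vec(N - K, m - k)
               - _log_binom_vec(N, m))
    mu = nu * lam if mode == "literal" else (nu - M_prev) * lam
    mu = np.broadcast_to(np.asarray(mu, dtype=float), m.shape)
    if np.any(mu <= 0):
        return _NEG_INF
    if mode not in ("literal", "depleted"):
        raise ValueError(f"unknown mode {mode!r}; use 'literal' or 'depleted'")
    log_pois = m * np.log(mu) - mu - gammaln(m + 1.0)
    total = float(np.sum(log_det) + np.sum(log_pois))
    return total if np.isfinite(total) else _NEG_INF


def log_likelihood(traj: CellTrajectory, params: GrowthParameters,
                   mode: str = "literal") -> float:
    """Log likelihood of a trajectory; -inf when infeasible (no exception)."""
    return _log_likelihood_raw(traj.m, traj.m_star, params.nu,
                               params.nu_star, params.lam, mode)


# ---------------------------------------------------------------------------
# Newton-Raphson maximum likelihood
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConvergenceReport:
    converged: bool
    n_iter: int
    grad_norm: float
    step_halving_used: bool
    boundary: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _num_grad(f, x: np.ndarray, h: np.ndarray) -> np.ndarray:
    g = np.zeros_like(x)
    for i in range(len(x)):
        hi = h[i]
        for _ in range(6):  # shrink near the feasibility boundary
            e = np.zeros_like(x)
            e[i] = hi
            fp, fm = f(x + e), f(x - e)
            if np.isfinite(fp) and np.isfinite(fm):
                g[i] = (fp - fm) / (2 * hi)
                break
            hi *= 0.1
        else:
            g[i] = 0.0
    return g


def _num_hess(f, x: np.ndarray, h: np.ndarray) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        fpp = f(x + ei)
        fmm = f(x - ei)
        if np.isfinite(fpp) and np.isfinite(fmm):
            H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        else:
            H[i, i] = -1.0 / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            vals = [f(x + ei + ej), f(x + ei - ej), f(x - ei + ej), f(x - ei - ej)]
            if all(np.isfinite(v) for v in vals):
                H[i, j] = H[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (
                    4 * h[i] * h[j])
    return H


def _newton_maximize(f, x0: np.ndarray, tol: float, max_iter: int):
    """Maximize f by Newton-Raphson with step-halving; -inf is a barrier."""
    x = np.asarray(x0, dtype=float)
    fx = f(x)
    if not np.isfinite(fx):
        raise ValueError("initial point is infeasible")
    halved = False
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        h = 1e-5 * np.maximum(np.abs(x), 1.0)
        g = _num_grad(f, x, h)
        grad_norm = float(np.linalg.norm(g))
        if grad_norm < tol:
            return x, fx, ConvergenceReport(True, it, grad_norm, halved)
        H = _num_hess(f, x, h)
        step = None
        try:
            cand = np.linalg.solve(H, -g)
            if np.all(np.isfinite(cand)) and float(g @ cand) > 0:
                step = cand
        except np.linalg.LinAlgError:
            pass
        if step is None:  # singular or non-ascent Hessian: gradient step
            scale = max(np.max(np.abs(np.diag(H))), 1e-12)
            step = g / scale
        t = 1.0
        improved = False
        for _ in range(40):
            fn = f(x + t * step)
            if np.isfinite(fn) and fn > fx:
                gain = fn - fx
                x = x + t * step
                fx = fn
                improved = True
                break
            t *= 0.5
            halved = True
        if not improved:
            return x, fx, ConvergenceReport(
                True, it, grad_norm, halved,
                message="no ascent direction improves the likelihood")
        if gain < 1e-10 * (1.0 + abs(fx)):
            return x, fx, ConvergenceReport(True, it, grad_norm, halved)
        if abs(t * np.max(np.abs(step) / np.maximum(np.abs(x), 1.0))) < 1e-12:
            return x, fx, ConvergenceReport(True, it, grad_norm, halved)
    return x, fx, ConvergenceReport(False, it, grad_norm, halved,
                                    message="max_iter reached")


def _profiled_lambda(m: np.ndarray, nu: float, mode: str) -> float:
    """Closed-form inner maximizer of lam given nu (both Poisson modes)."""
    m = np.asarray(m, dtype=float)
    if mode == "literal":
        return float(np.mean(m)) / nu
    M_prev = np.concatenate([[0.0], np.cumsum(m)[:-1]])
    denom = float(np.sum(nu - M_prev))
    return float(np.sum(m)) / denom if denom > 0 else 1e-12


_NU_UPPER = 1e8  # beyond this the population size is effectively unidentified


def fit_mle(traj: CellTrajectory, init: GrowthParameters | None = None,
            tol: float = 1e-8, max_iter: int = 200,
            mode: str = "depleted") -> tuple[GrowthParameters, ConvergenceReport]:
    """Maximum-likelihood (nu, nu*, lam) by Newton-Raphson.

    Newton-Raphson runs on the continuous relaxation of (nu, nu*) — the
    gamma-function binomials — with lam concentrated out analytically at
    each trial point (its inner maximizer has a closed form in both
    Poisson modes).  Infeasible regions (cumulative counts exceeding nu
    or nu*) contribute -inf and act as a barrier; when the data carry no
    depletion signal the population size drifts to a large upper bound
    and the fit is flagged as weakly identified.

    Estimation defaults to the depleted proliferation mean
    ``(nu - M_{t-1}) * lam`` (removal-sampling structure).  Under the
    literal mean ``nu * lam`` the MLE is degenerate: lam profiles to
    ``mean(m)/nu``, the Poisson factor then carries no information on
    nu, and the hypergeometric factor is maximized at the boundary
    ``nu = M_T`` for any data, which forces ``lam_hat = 1/T``.  The
    literal mode remains available for likelihood evaluation.
    """
    from scipy.special import expit, logit

    M_T = float(traj.M[-1])
    Ms_T = float(traj.M_star[-1])
    m_arr, ms_arr = traj.m, traj.m_star

    # Unconstrained coordinates: nu = M_T + e^u, nu* = M*_T + e^u * sigmoid(v)
    # satisfy every feasibility constraint (nu >= M_T, nu* >= M*_T,
    # nu - nu* >= M_T - M*_T) identically, so Newton-Raphson never meets
    # the -inf barrier of the raw parametrization.
    def decode(z: np.ndarray) -> tuple[float, float]:
        u, v = z
        excess = math.exp(min(u, math.log(_NU_UPPER)))
        return M_T + excess, Ms_T + excess * expit(v)

    if init is None:
        u0 = math.log(max(M_T, 4.0))  # nu0 = 2 M_T
        ratio = (Ms_T + 0.5) / (M_T + 1.0)
        v0 = float(logit(min(max(ratio, 0.02), 0.98)))
        z0 = np.array([u0, v0])
    else:
        u0 = math.log(max(float(init.nu) - M_T, 1e-3))
        frac = (float(init.nu_star) - Ms_T) / max(float(init.nu) - M_T, 1e-3)
        v0 = float(logit(min(max(frac, 0.02), 0.98)))
        z0 = np.array([u0, v0])

    def objective(z: np.ndarray) -> float:
        nu, nu_star = decode(z)
        lam = _profiled_lambda(m_arr, nu, mode)
        return _log_likelihood_raw(m_arr, ms_arr, nu, nu_star, lam, mode)

    z, _, report = _newton_maximize(objective, z0, tol, max_iter)
    nu_hat, nus_hat = decode(z)
    if nu_hat > 0.99 * _NU_UPPER:
        report.boundary = True
        report.message = (report.message + "; " if report.message else "") + \
            "nu at upper bound: no depletion signal"
    lam_hat = max(_profiled_lambda(m_arr, nu_hat, mode), 1e-12)
    fitted = GrowthParameters(nu=nu_hat, nu_star=nus_hat, lam=lam_hat)
    return fitted, report


def fit_lambda_star(traj: CellTrajectory, nu_star: float, tol: float = 1e-8,
                    max_iter: int = 200,
                    counts: np.ndarray | None = None,
                    ) -> tuple[float, ConvergenceReport]:
    """Newton-Raphson estimate of the prior rate lam* (> 1).

    Maximizes the product over steps of Poisson(counts_t) at means
    ``(nu* - M*_{t-1}) * lam*``, where the exposures ``nu* - M*_{t-1}``
    always come from the trajectory's own cumulative malignant counts.
    ``counts`` defaults to the trajectory's detected malignant counts;
    passing prior-simulated counts evaluates the prior law against the
    observed depletion state.  When the unconstrained optimum falls at
    or below 1 the boundary value ``1 + 1e-6`` is returned with the
    report's ``boundary`` flag set.
    """
    Ms_prev = np.concatenate([[0.0], traj.M_star[:-1].astype(float)])
    c = nu_star - Ms_prev
    obs = traj.m_star if counts is None else np.asarray(counts)
    if len(obs) != traj.T:
        raise ValueError("counts must have one entry per migration step")
    keep = c > 0
    c = c[keep]
    ms = obs[keep].astype(float)
    A = float(ms.sum())
    C = float(c.sum())
    if C <= 0:
        return 1.0 + 1e-6, ConvergenceReport(True, 0, 0.0, False, boundary=True,
                                             message="no remaining malignant cells")
    if A == 0:
        return 1.0 + 1e-6, ConvergenceReport(True, 0, 0.0, False, boundary=True,
                                             message="no malignant detections")
    lam = max(A / C, 1.5)  # start interior; NR on d/dlam [A log lam - C lam]
    report = ConvergenceReport(False, max_iter, np.inf, False)
    for it in range(1, max_iter + 1):
        grad = A / lam - C
        hess = -A / lam ** 2
        step = -grad / hess
        lam_new = lam + step
        if lam_new <= 0:
            lam_new = lam / 2
        if abs(lam_new - lam) < tol * max(1.0, lam):
            lam = lam_new
            report = ConvergenceReport(True, it, abs(A / lam - C), False)
            break
        lam = lam_new
    if lam <= 1.0:
        return 1.0 + 1e-6, ConvergenceReport(report.converged, report.n_iter,
                                             report.grad_norm, False,
                                             boundary=True,
                                             message="optimum at or below 1")
    return float(lam), report


# ---------------------------------------------------------------------------
# weighted prior, posterior, volume, detection-completeness probability
# ---------------------------------------------------------------------------

def weighted_prior(m_star: int, params: GrowthParameters,
                   M_star_prev: int = 0) -> float:
    """Weighted Poisson prior weight g(m*) = Poisson(m*; mu) * c.v.

    ``mu = (nu* - M*_{t-1}) * lam*`` and the coefficient of variation of
    a Poisson law is ``mu ** -0.5``; the model's constraint c.v. < 1
    requires ``mu > 1``.  The weight is unnormalized — normalization
    happens across steps in :func:`posterior`.
    """
    if m_star < 0:
        raise ValueError("m_star must be nonnegative")
    if params.lam_star is None:
        raise ValueError("params.lam_star is required for the weighted prior")
    mu = (params.nu_star - M_star_prev) * params.lam_star
    if mu <= 1.0:
        raise ValueError(
            f"(nu* - M*) * lam* = {mu:.6g} <= 1 violates the c.v. < 1 constraint")
    log_f = m_star * math.log(mu) - mu - gammaln(m_star + 1.0)
    return float(math.exp(log_f) * mu ** -0.5)


def _log_weighted_prior(m_star: float, mu: float) -> float:
    return m_star * math.log(mu) - mu - gammaln(m_star + 1.0) - 0.5 * math.log(mu)


def posterior(traj: CellTrajectory, params: GrowthParameters,
              include_likelihood_factor: bool = False,
              mode: str = "literal") -> tuple[np.ndarray, float]:
    """Posterior step weights H_t and posterior mean H_mean.

    ``H_t = g_t(m*_t) L / sum_s g_s(m*_s) L``; the likelihood factor
    ``L(nu, nu*; lam)`` is constant across steps and cancels.  With
    ``include_likelihood_factor=True`` the computation is carried out in
    log space with the factor retained, which must agree with the
    cancelled route to floating-point accuracy.
    """
    if params.lam_star is None:
        raise ValueError("fitted lam_star required")
    Ms_prev = np.concatenate([[0.0], traj.M_star[:-1].astype(float)])
    mu = (params.nu_star - Ms_prev) * params.lam_star
    if np.any(mu <= 1.0):
        bad = int(np.argmax(mu <= 1.0)) + 1
        raise ValueError(
            f"(nu* - M*) * lam* <= 1 at step {bad}; weighted prior undefined")
    log_g = np.array([_log_weighted_prior(k, m)
                      for k, m in zip(traj.m_star.astype(float), mu)])
    if include_likelihood_factor:
        log_g = log_g + log_likelihood(traj, params, mode=mode)
    if np.all(np.isneginf(log_g)):
        raise ValueError("degenerate posterior: all step weights are zero")
    log_w = log_g - logsumexp(log_g)
    weights = np.exp(log_w)
    weights /= weights.sum()
    h_mean = float(np.sum(traj.m_star * weights))
    return weights, h_mean


def eventual_volume(posterior_mean: float, v_initial: float, c: float = 1.0,
                    discrete: bool = False) -> float:
    """Eventual malignant volume V_new = c * H_mean * V_initial (mm^3)."""
    if posterior_mean < 0 or v_initial < 0 or c < 0:
        raise ValueError("posterior_mean, v_initial and c must be nonnegative")
    v = c * posterior_mean * v_initial
    return float(np.round(v)) if discrete else float(v)


def prob_no_undetected(counts, r: int = 2) -> np.ndarray:
    """Probability that no malignant cell went undetected, per count.

    For a detected count ``k`` the probability is the survival function
    at ``r`` of a geometric law with success probability ``1/(k+1)``,
    i.e. ``(k / (k + 1)) ** r``; zero detections give zero evidence of
    completeness.
    """
    k = np.atleast_1d(np.asarray(counts, dtype=float))
    if np.any(k < 0):
        raise ValueError("counts must be nonnegative")
    if r < 1:
        raise ValueError("r must be a positive integer")
    return (k / (k + 1.0)) ** r


# ---------------------------------------------------------------------------
# estimator surface
# ---------------------------------------------------------------------------

class TumorGrowthModel:
    """Growth-model estimator: fit on one trajectory, predict eventual volume.

    Parameters
    ----------
    mode : {"depleted", "literal"}
        Poisson proliferation mean: the self-consistent depleted form
        ``(nu - M_{t-1})*lam`` (default — the literal ``nu*lam`` form
        admits only a degenerate MLE, see :func:`fit_mle`).
    c : float
        Proportionality constant of the eventual-volume relation.
    r : int
        Exponent of the geometric detection-completeness probability.
    discrete_volumes : bool
        Round predicted volumes to the nearest integer mm^3.
    """

    def __init__(self, mode: str = "depleted", c: float = 1.0, r: int = 2,
                 tol: float = 1e-8, max_iter: int = 200,
                 discrete_volumes: bool = False):
        self.mode = mode
        self.c = c
        self.r = r
        self.tol = tol
        self.max_iter = max_iter
        self.discrete_volumes = discrete_volumes

    # sklearn-compatible parameter plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k)
                for k in ("mode", "c", "r", "tol", "max_iter", "discrete_volumes")}

    def set_params(self, **params) -> "TumorGrowthModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, trajectory: CellTrajectory) -> "TumorGrowthModel":
        params, report = fit_mle(trajectory, tol=self.tol,
                                 max_iter=self.max_iter, mode=self.mode)
        lam_star, ls_report = fit_lambda_star(trajectory, params.nu_star,
                                              tol=self.tol,
                                              max_iter=self.max_iter)
        if ls_report.boundary:
            warnings.warn("lambda_star optimum at or below 1; "
                          "returning boundary value", RuntimeWarning)
        self.params_ = GrowthParameters(nu=params.nu, nu_star=params.nu_star,
                                        lam=params.lam, lam_star=lam_star)
        self.convergence_ = report
        self.lambda_star_report_ = ls_report
        self.trajectory_ = trajectory
        weights, h_mean = posterior(trajectory, self.params_, mode=self.mode)
        self.step_weights_ = weights
        self.posterior_mean_ = h_mean
        return self

    def predict(self, v_initial: float) -> float:
        """Eventual malignant volume in mm^3 for a given initial volume."""
        self._check_fitted()
        return eventual_volume(self.posterior_mean_, v_initial, c=self.c,
                               discrete=self.discrete_volumes)

    def summarize(self, v_initial: float) -> PosteriorSummary:
        self._check_fitted()
        p_steps = prob_no_undetected(self.trajectory_.m_star, r=self.r)
        k_subject = float(np.round(self.posterior_mean_))
        p_subject = float(prob_no_undetected([k_subject], r=self.r)[0])
        return PosteriorSummary(
            step_weights=self.step_weights_,
            posterior_mean=self.posterior_mean_,
            v_initial=float(v_initial),
            v_new=self.predict(v_initial),
            p_no_undetected=p_steps,
            p_subject=p_subject,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("TumorGrowthModel is not fitted yet; call fit()")
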