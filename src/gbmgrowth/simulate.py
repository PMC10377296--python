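"""Generative model of the migration/detection process.

Reads the growth model forward: per step, draw a Poisson number of
proliferating cells (capped at the undetected remainder so trajectories
stay feasible), then draw the malignant subset hypergeometrically from
the undetected pool.  Used for estimator validation and for synthetic
cohorts matching the study's sample size (102 subjects).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .trajectory import CellTrajectory, GrowthParameters

__all__ = ["SimulationConfig", "Subject", "simulate_trajectory",
           "simulate_cohort", "simulate_prior_counts"]


@dataclasses.dataclass
class SimulationConfig:
    """Cohort simulation settings; defaults give a realistic spread of
    population sizes, malignant fractions and proliferation rates."""

    n_subjects: int = 102
    T_range: tuple[int, int] = (3, 12)
    nu_range: tuple[float, float] = (500.0, 10000.0)
    nu_star_frac_range: tuple[float, float] = (0.2, 0.8)
    lam_range: tuple[float, float] = (0.01, 0.2)
    lam_star_range: tuple[float, float] = (1.1, 3.0)
    voxel_increment_range: tuple[int, int] = (50, 500)
    # initial ROI volume (mm^3), lognormal; moments match a whole-tumor
    # scale of ~1.1e5 +/- 5.3e4 mm^3
    v_initial_mean: float = 107999.84
    v_initial_sd: float = 52700.74
    mode: str = "depleted"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("T_range", "nu_range", "nu_star_frac_range", "lam_range",
                     "lam_star_range", "voxel_increment_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be nonnegative")


@dataclasses.dataclass
class Subject:
    subject_id: str
    trajectory: CellTrajectory
    v_initial: float
    true_params: GrowthParameters
    seed: int


def simulate_trajectory(params: GrowthParameters, T: int,
                        seed: int | np.random.Generator = 0,
                        mode: str = "depleted",
                        voxel_increment_range: tuple[int, int] = (50, 500),
                        ) -> CellTrajectory:
    """Draw one T-step trajectory under the growth model.

    Per step: ``m_t ~ Poisson(mu)`` clipped to the undetected remainder
    ``nu - M_{t-1}`` (keeps cumulative counts feasible), then ``m*_t``
    hypergeometric with population ``nu - M_{t-1}``, successes
    ``nu* - M*_{t-1}`` and draws ``m_t``.  If the population is
    exhausted before step T the trajectory is truncated and flagged.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nu = int(round(params.nu))
    nu_star = int(round(params.nu_star))
    m, m_star, delta = [], [], []
    M_prev = 0
    Ms_prev = 0
    truncated = False
    for _ in range(T):
        remaining = nu - M_prev
        if remaining <= 0:
            truncated = True
            break
        mu = params.nu * params.lam if mode == "literal" else remaining * params.lam
        mt = int(min(rng.poisson(mu), remaining))
        K = nu_star - Ms_prev
        kt = int(rng.hypergeometric(K, remaining - K, mt)) if mt > 0 else 0
        m.append(mt)
        m_star.append(kt)
        delta.append(int(rng.integers(voxel_increment_range[0],
                                      voxel_increment_range[1] + 1)))
        M_prev += mt
        Ms_prev += kt
    if not m:
        raise ValueError("population exhausted before the first step")
    return CellTrajectory(m=np.array(m), m_star=np.array(m_star),
                          delta_voxels=np.array(delta), truncated=truncated)


def simulate_prior_counts(traj: CellTrajectory, nu_star: float,
                          lam_star: float,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw per-step malignant counts from the weighted-prior Poisson law.

    Exposures are the trajectory's own remaining malignant pools
    ``nu* - M*_{t-1}``; counts are Poisson with mean ``exposure * lam*``
    (zero where the pool is exhausted).  Used to validate lam*
    estimation, since detection itself never involves lam*.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Ms_prev = np.concatenate([[0.0], traj.M_star[:-1].astype(float)])
    exposure = np.maximum(nu_star - Ms_prev, 0.0)
    return rng.poisson(exposure * lam_star)


def simulate_cohort(config: SimulationConfig) -> list[Subject]:
    """Independent subjects with parameters drawn uniformly from the
    configured ranges; per-subject seeds spawn deterministically from the
    master seed."""
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(max(config.n_subjects, 1))
    subjects: list[Subject] = []
    for i in range(config.n_subjects):
        sub_seed = int(children[i].generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(sub_seed)
        nu = float(rng.uniform(*config.nu_range))
        frac = float(rng.uniform(*config.nu_star_frac_range))
        lam = float(rng.uniform(*config.lam_range))
        lam_star = float(rng.uniform(*config.lam_star_range))
        T = int(rng.integers(config.T_range[0], config.T_range[1] + 1))
        params = GrowthParameters(nu=nu, nu_star=frac * nu, lam=lam,
                                  lam_star=lam_star)
        traj = simulate_trajectory(params, T, rng, mode=config.mode,
                                   voxel_increment_range=config.voxel_increment_range)
        # lognormal initial volume moment-matched to the configured mean/sd
        s2 = np.log(1.0 + (config.v_initial_sd / config.v_initial_mean) ** 2)
        mu_ln = np.log(config.v_initial_mean) - s2 / 2
        v_init = float(np.exp(rng.normal(mu_ln, np.sqrt(s2))))
        subjects.append(Subject(subject_id=f"S{i:03d}", trajectory=traj,
                                v_initial=v_init, true_params=params,
                                seed=sub_seed))
    return subjects
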