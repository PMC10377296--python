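"""Containers for step-wise tumor-cell detection data.

The migration process is discrete: at step ``t`` the tumor occupies the
voxel set ``R(t)``, and the incremental region ``dR(t) = R(t) - R(t-1)``
(always non-empty) receives ``m_t`` newly proliferating cells, of which
``m_star_t`` are malignant.  A :class:`CellTrajectory` records those
per-step counts together with the incremental region sizes; cumulative
counts are derived, never stored.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["CellTrajectory", "GrowthParameters", "PosteriorSummary"]


def _as_int_array(values: Iterable, name: str) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(arr.astype(float))):
        raise ValueError(f"{name} contains non-finite entries")
    if np.any(arr.astype(float) != np.round(arr.astype(float))):
        raise ValueError(f"{name} must be integer-valued")
    return arr.astype(np.int64)


@dataclasses.dataclass(frozen=True)
class CellTrajectory:
    """Per-step detected cell counts for one subject.

    Parameters
    ----------
    m : array of int
        Total (malignant + benign) cells detected per migration step.
    m_star : array of int
        Malignant cells detected per migration step; ``m_star <= m``.
    delta_voxels : array of int
        Size ``|dR(t)|`` of the incremental region, strictly positive.
    truncated : bool
        Set by the simulator when the cell population was exhausted
        before the requested number of steps.
    """

    m: np.ndarray
    m_star: np.ndarray
    delta_voxels: np.ndarray
    truncated: bool = False

    def __post_init__(self) -> None:
        m = _as_int_array(self.m, "m")
        m_star = _as_int_array(self.m_star, "m_star")
        delta = _as_int_array(self.delta_voxels, "delta_voxels")
        if not (len(m) == len(m_star) == len(delta)):
            raise ValueError("m, m_star and delta_voxels must have equal length")
        if np.any(m < 0) or np.any(m_star < 0):
            raise ValueError("cell counts must be nonnegative")
        if np.any(m_star > m):
            raise ValueError("m_star must not exceed m at any step")
        if np.any(delta <= 0):
            raise ValueError("incremental region sizes |dR(t)| must be positive")
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "m_star", m_star)
        object.__setattr__(self, "delta_voxels", delta)

    @property
    def T(self) -> int:
        """Number of migration steps."""
        return len(self.m)

    @property
    def M(self) -> np.ndarray:
        """Cumulative total counts ``M_t``."""
        return np.cumsum(self.m)

    @property
    def M_star(self) -> np.ndarray:
        """Cumulative malignant counts ``M*_t``."""
        return np.cumsum(self.m_star)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, self.T + 1),
                "m": self.m,
                "m_star": self.m_star,
                "delta_voxels": self.delta_voxels,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CellTrajectory":
        missing = {"m", "m_star", "delta_voxels"} - set(frame.columns)
        if missing:
            raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
        frame = frame.sort_values("step") if "step" in frame.columns else frame
        return cls(
            m=frame["m"].to_numpy(),
            m_star=frame["m_star"].to_numpy(),
            delta_voxels=frame["delta_voxels"].to_numpy(),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CellTrajectory":
        return cls.from_frame(pd.read_csv(path))


@dataclasses.dataclass(frozen=True)
class GrowthParameters:
    """Population/rate parameters of the growth model.

    ``nu`` (total cells that can proliferate by the final step) and
    ``nu_star <= nu`` (the malignant subset) govern the hypergeometric
    detection stage; ``lam`` is the Poisson proliferation rate and
    ``lam_star > 1`` the prior rate for malignant proliferation.
    """

    nu: float
    nu_star: float
    lam: float
    lam_star: float | None = None

    def __post_init__(self) -> None:
        if not (self.nu > 0 and self.nu_star >= 0):
            raise ValueError("nu must be positive and nu_star nonnegative")
        if self.nu_star > self.nu:
            raise ValueError("nu_star must not exceed nu")
        if not self.lam > 0:
            raise ValueError("lam must be positive")
        if self.lam_star is not None and not self.lam_star > 1:
            raise ValueError("lam_star must exceed 1")

    def to_dict(self) -> dict:
        return {
            "nu": float(self.nu),
            "nu_star": float(self.nu_star),
            "lambda": float(self.lam),
            "lambda_star": None if self.lam_star is None else float(self.lam_star),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthParameters":
        return cls(
            nu=d["nu"],
            nu_star=d["nu_star"],
            lam=d.get("lambda", d.get("lam")),
            lam_star=d.get("lambda_star", d.get("lam_star")),
        )


@dataclasses.dataclass(frozen=True)
class PosteriorSummary:
    """Posterior over migration steps and the implied eventual volume.

    ``step_weights`` are the normalized posterior weights ``H_t`` (sum to
    one), ``posterior_mean`` is ``H_mean = sum_t m*_t H_t``, and
    ``v_new = c * H_mean * v_initial``.  ``p_no_undetected`` holds the
    per-step geometric probabilities that no malignant cell went
    undetected; ``p_subject`` applies the same construction to the
    rounded posterior mean.
    """

    step_weights: np.ndarray
    posterior_mean: float
    v_initial: float
    v_new: float
    p_no_undetected: np.ndarray
    p_subject: float

    def __post_init__(self) -> None:
        w = np.asarray(self.step_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-10:
            raise ValueError("step weights must sum to 1")
        p = np.asarray(self.p_no_undetected, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "step_weights", w)
        object.__setattr__(self, "p_no_undetected", p)

    def to_dict(self) -> dict:
        return {
            "step_weights": [float(x) for x in self.step_weights],
            "posterior_mean": float(self.posterior_mean),
            "v_initial": float(self.v_initial),
            "v_new": float(self.v_new),
            "p_no_undetected": [float(x) for x in self.p_no_undetected],
            "p_subject": float(self.p_subject),
        }
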