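"""Synthetic cohorts: radiomic feature tables, multimodal phantoms and
bundled fixtures.

The feature generator emulates the structure of a GBM radiomics summary
table — ROI volumes (whole tumor, edema, tumor core, non-enhancing and
GD-enhancing tumor), spatial and histology involvement scores,
morphology, survival length and age — with cross-feature correlation
induced solely through latent factors (one endogenous "tumor burden"
factor, one exogenous clinical factor).  Marginal means and standard
deviations default to realistic GBM magnitudes (whole-tumor volume
~108,000 +/- 52,700 mm^3).  Volumes are lognormal so the heavy right
tail and nonnegativity come for free.

The phantom generator builds four co-registered modality volumes with an
ellipsoidal lesion of modality-specific contrast plus Gaussian noise,
returning the ground-truth mask alongside.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import MODALITIES, MultimodalVolume, TumorMask
from .simulate import SimulationConfig, Subject, simulate_cohort

__all__ = ["ROI_VOLUME_TARGETS", "SPATIAL_TARGETS", "HISTOLOGY_TARGETS",
           "MORPHOLOGY_TARGETS", "generate_feature_table", "generate_phantom",
           "generate_cohort_fixture", "CohortFixture"]

# Default marginal calibration targets (mean, sd) for the feature table.
ROI_VOLUME_TARGETS = {
    "volume_wt": (107999.84, 52700.74),
    "volume_ed": (62139.61, 35360.39),
    "volume_tc": (45560.24, 31424.16),
    "volume_net": (15578.29, 17475.42),
    "volume_et": (29981.94, 22104.20),
}
SPATIAL_TARGETS = {
    "spatial_frontal": (25.64, 35.69),
    "spatial_temporal": (42.39, 38.89),
    "spatial_occipital": (4.22, 14.13),
    "spatial_insula": (2.95, 5.76),
    "spatial_fornix": (1.19, 3.04),
    "spatial_parietal": (18.34, 29.50),
    "spatial_brain_stem": (0.25, 0.71),
}
HISTOLOGY_TARGETS = {
    "histology_occipital_cortex": (0.375, 0.8097),
    "histology_temporal_cortex": (0.146, 0.3546),
    "histology_basal_ganglia": (0.681, 1.508),
}
MORPHOLOGY_TARGETS = {
    "eccentricity": (0.68, 0.09),
    "solidity": (0.40, 0.14),
}
SURVIVAL_TARGET = (1.5, 1.4)  # years
AGE_TARGET = (58.0, 12.0)     # not in the summary table; typical GBM cohort


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def generate_feature_table(n: int = 102, factor_weight: float = 0.7,
                           noise_sd: float = 1.0, seed: int = 0,
                           volume_targets: dict | None = None,
                           ) -> tuple[pd.DataFrame, dict]:
    """Radiomic feature table with latent-factor correlation structure.

    Each subject carries an endogenous latent factor ``eta1`` (tumor
    burden) and an exogenous factor ``eta2`` (clinical frailty).  ROI
    volumes are lognormal with log-scale correlation ``factor_weight``
    to ``eta1``; spatial/histology scores load on ``eta1`` with
    ``noise_sd``-scaled residuals; survival length and age load on
    ``eta2``.  Returns the table and the ground-truth latent draws and
    coefficients.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    volume_targets = volume_targets or ROI_VOLUME_TARGETS
    w = float(np.clip(factor_weight, 0.0, 1.0))
    eta1 = rng.normal(size=n)
    eta2 = rng.normal(size=n)
    cols: dict[str, np.ndarray] = {}
    for name, (mean, sd) in volume_targets.items():
        mu, sigma = _lognormal_params(mean, sd)
        z = w * eta1 + np.sqrt(1 - w ** 2) * rng.normal(size=n)
        cols[name] = np.exp(mu + sigma * z)
    for name, (mean, sd) in {**SPATIAL_TARGETS, **HISTOLOGY_TARGETS}.items():
        raw = mean + sd * (w * eta1
                           + np.sqrt(1 - w ** 2) * noise_sd * rng.normal(size=n))
        cols[name] = np.maximum(raw, 0.0)
    for name, (mean, sd) in MORPHOLOGY_TARGETS.items():
        cols[name] = np.clip(mean + sd * rng.normal(size=n), 0.0, 1.0)
    mu_s, sig_s = _lognormal_params(*SURVIVAL_TARGET)
    cols["survival_years"] = np.exp(mu_s + sig_s * (w * eta2 + np.sqrt(1 - w ** 2)
                                                    * rng.normal(size=n)))
    cols["age"] = np.clip(AGE_TARGET[0] + AGE_TARGET[1]
                          * (-0.5 * eta2 + np.sqrt(1 - 0.25) * rng.normal(size=n)),
                          18.0, 95.0)
    table = pd.DataFrame(cols)
    table.index.name = "subject"
    truth = {"eta1": eta1, "eta2": eta2, "factor_weight": w,
             "noise_sd": noise_sd, "seed": seed}
    return table, truth


def generate_phantom(shape: tuple[int, int, int] = (48, 48, 48),
                     center: tuple[float, float, float] | None = None,
                     radii: tuple[float, float, float] = (12.0, 10.0, 8.0),
                     contrast: dict[str, float] | None = None,
                     background: float = 100.0,
                     noise_sd: float = 0.0, seed: int = 0,
                     voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                     ) -> tuple[MultimodalVolume, TumorMask]:
    """Four-modality ellipsoid phantom plus its ground-truth mask.

    Default contrasts put the strongest lesion signal on T1-Gd and
    FLAIR, as for an enhancing GBM.  The lesion must fit inside the
    volume.
    """
    contrast = contrast if contrast is not None else {
        "t1": 40.0, "t1gd": 120.0, "t2": 80.0, "flair": 100.0}
    if set(contrast) - set(MODALITIES):
        raise ValueError(f"unknown modalities: {set(contrast) - set(MODALITIES)}")
    center = center if center is not None else tuple(s / 2.0 for s in shape)
    for c, r, s in zip(center, radii, shape):
        if c - r < 0 or c + r > s:
            raise ValueError("lesion extends outside the volume")
    rng = np.random.default_rng(seed)
    grids = np.mgrid[:shape[0], :shape[1], :shape[2]].astype(float)
    ell = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii)) <= 1.0
    modalities = {}
    for name, con in contrast.items():
        arr = np.full(shape, background, dtype=float)
        arr[ell] += con
        if noise_sd > 0:
            arr = arr + rng.normal(0.0, noise_sd, shape)
        modalities[name] = arr
    return (MultimodalVolume(modalities, voxel_spacing),
            TumorMask(ell, voxel_spacing))


@dataclasses.dataclass
class CohortFixture:
    """Bundled synthetic study: trajectories + initial volumes + feature
    table + ground truth, reproducible from one seed."""

    subjects: list[Subject]
    features: pd.DataFrame
    truth: dict
    seed: int

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_subjects": len(self.subjects),
            "subjects": [
                {"id": s.subject_id, "seed": s.seed,
                 "v_initial": s.v_initial,
                 "true_params": s.true_params.to_dict(),
                 "T": s.trajectory.T}
                for s in self.subjects
            ],
        }

    def manifest_hash(self) -> str:
        payload = json.dumps(self.manifest(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def write(self, directory) -> Path:
        directory = Path(directory)
        (directory / "trajectories").mkdir(parents=True, exist_ok=True)
        for s in self.subjects:
            s.trajectory.to_csv(directory / "trajectories" / f"{s.subject_id}.csv")
        self.features.to_csv(directory / "features.csv")
        with open(directory / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)
        truth_json = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                      for k, v in self.truth.items()}
        with open(directory / "truth.json", "w") as fh:
            json.dump(truth_json, fh, indent=2, sort_keys=True)
        return directory


def generate_cohort_fixture(config: SimulationConfig | None = None,
                            seed: int = 0) -> CohortFixture:
    """Simulator cohort + matching feature table in one reproducible
    bundle; the config's own seed is overridden by ``seed``."""
    config = dataclasses.replace(config or SimulationConfig(), seed=seed)
    subjects = simulate_cohort(config)
    features, truth = generate_feature_table(n=config.n_subjects,
                                             seed=seed + 1)
    if len(features) == len(subjects):
        features = features.set_axis([s.subject_id for s in subjects])
        features.index.name = "subject"
    return CohortFixture(subjects=subjects, features=features,
                         truth=truth, seed=seed)
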