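"""Two-step parallel K-means tumor localization on multimodal MRI.

Step 1 clusters each modality's intensities independently with K-means
and flags the lesion-like (highest-mean) cluster; step 2 fuses the
per-modality candidate maps by voxel-wise voting and cleans the result
morphologically (opening, closing, largest connected component).
Registration and skull stripping are assumed done upstream.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from skimage import measure, morphology
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

__all__ = ["MultimodalVolume", "TumorMask", "EmptyMaskError",
           "KMeansTumorLocalizer", "localize_tumor", "morphological_clean",
           "apply_mask", "roi_volume", "dice_coefficient",
           "MODALITIES"]

MODALITIES = ("t1", "t1gd", "t2", "flair")


class EmptyMaskError(ValueError):
    """Raised when no lesion voxels survive localization."""


@dataclasses.dataclass
class MultimodalVolume:
    """Co-registered T1 / T1-Gd / T2 / FLAIR intensity volumes."""

    modalities: dict[str, np.ndarray]
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValueError("at least one modality is required")
        shapes = {v.shape for v in self.modalities.values()}
        if len(shapes) != 1:
            raise ValueError("all modalities must share one shape")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        for name, arr in self.modalities.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"modality {name!r} has non-finite intensities")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.modalities.values())).shape


@dataclasses.dataclass
class TumorMask:
    data: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def n_components(self) -> int:
        return int(measure.label(self.data).max())

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


class KMeansTumorLocalizer:
    """Parallel per-modality K-means lesion localizer.

    Parameters
    ----------
    k : int
        Number of intensity clusters per modality (background, CSF-like,
        tissue-like, lesion-like by default).
    vote_threshold : int
        Minimum number of modalities that must flag a voxel.
    clean_radius : int
        Ball radius (voxels) of the morphological opening/closing.
    seed : int
        K-means initialization seed; the pipeline is deterministic
        given this value.
    """

    def __init__(self, k: int = 4, vote_threshold: int = 2,
                 clean_radius: int = 1, seed: int = 0):
        self.k = k
        self.vote_threshold = vote_threshold
        self.clean_radius = clean_radius
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name)
                for name in ("k", "vote_threshold", "clean_radius", "seed")}

    def set_params(self, **params) -> "KMeansTumorLocalizer":
        for name, value in params.items():
            if name not in self.get_params():
                raise ValueError(f"unknown parameter {name!r}")
            setattr(self, name, value)
        return self

    def fit(self, volume: MultimodalVolume) -> "KMeansTumorLocalizer":
        if self.k < 2:
            raise ValueError("k must be at least 2")
        votes = np.zeros(volume.shape, dtype=int)
        n_informative = 0
        for name, arr in volume.modalities.items():
            flat = arr.reshape(-1, 1).astype(float)
            if np.ptp(flat) <= 1e-12:
                continue  # constant modality carries no contrast
            n_informative += 1
            km = KMeans(n_clusters=self.k, random_state=self.seed, n_init=4)
            with warnings.catch_warnings():
                # noise-free phantoms have few distinct intensities
                warnings.simplefilter("ignore", ConvergenceWarning)
                labels = km.fit_predict(flat)
            lesion_label = int(np.argmax(km.cluster_centers_.ravel()))
            votes += (labels == lesion_label).reshape(volume.shape)
        if n_informative == 0:
            raise EmptyMaskError("all modalities are constant; nothing to segment")
        threshold = min(self.vote_threshold, n_informative)
        fused = TumorMask(votes >= threshold, volume.voxel_spacing)
        cleaned = morphological_clean(fused, self.clean_radius)
        if cleaned.n_voxels == 0:
            raise EmptyMaskError("no lesion voxels survived fusion and cleaning")
        self.mask_ = cleaned
        return self

    def predict(self, volume: MultimodalVolume) -> TumorMask:
        self.fit(volume)
        return self.mask_


def localize_tumor(volume: MultimodalVolume, k: int = 4, seed: int = 0,
                   vote_threshold: int = 2, clean_radius: int = 1) -> TumorMask:
    """Functional wrapper over :class:`KMeansTumorLocalizer`."""
    return KMeansTumorLocalizer(k=k, vote_threshold=vote_threshold,
                                clean_radius=clean_radius, seed=seed).predict(volume)


def morphological_clean(mask: TumorMask, radius_voxels: int = 1) -> TumorMask:
    """Binary opening then closing with a ball element; keep the largest
    connected component."""
    if radius_voxels < 1:
        raise ValueError("radius_voxels must be >= 1")
    data = mask.data
    if not data.any():
        return TumorMask(data.copy(), mask.voxel_spacing)
    selem = morphology.ball(radius_voxels)
    cleaned = morphology.closing(morphology.opening(data, selem), selem).astype(bool)
    labels = measure.label(cleaned)
    if labels.max() == 0:
        return TumorMask(np.zeros_like(data, dtype=bool), mask.voxel_spacing)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return TumorMask(labels == largest, mask.voxel_spacing)


def apply_mask(volume: MultimodalVolume, mask: TumorMask) -> MultimodalVolume:
    """Voxel-wise product of every modality with the binary mask."""
    if mask.data.shape != volume.shape:
        raise ValueError("mask and volume shapes differ")
    masked = {name: arr * mask.data for name, arr in volume.modalities.items()}
    return MultimodalVolume(masked, volume.voxel_spacing, volume.affine)


def roi_volume(mask: TumorMask,
               voxel_spacing: tuple[float, float, float] | None = None) -> float:
    """ROI volume in mm^3: voxel count times voxel volume (equals the
    count at the study's 1 mm^3 resampling resolution)."""
    spacing = voxel_spacing if voxel_spacing is not None else mask.voxel_spacing
    if any(s <= 0 for s in spacing):
        raise ValueError("voxel spacing must be positive")
    return float(mask.data.sum() * np.prod(spacing))


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); 1.0 for two empty masks."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
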