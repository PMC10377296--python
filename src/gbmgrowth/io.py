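"""Format readers/writers: trajectory CSV, parameter/posterior JSON,
NIfTI volumes and masks.  JSON numbers use Python's shortest
round-trip float repr, so write-then-read is exact."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .segmentation import MODALITIES, MultimodalVolume, TumorMask
from .trajectory import CellTrajectory, GrowthParameters, PosteriorSummary

__all__ = ["read_trajectory", "write_trajectory", "write_json", "read_json",
           "read_multimodal", "write_mask", "read_mask",
           "write_growth_result"]


def read_trajectory(path) -> CellTrajectory:
    return CellTrajectory.from_csv(path)


def write_trajectory(traj: CellTrajectory, path) -> None:
    traj.to_csv(path)


def write_json(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_growth_result(path, params: GrowthParameters,
                        summary: PosteriorSummary | None = None,
                        convergence: dict | None = None,
                        seed: int | None = None) -> None:
    """Fitted parameters (+ posterior summary) in the documented JSON
    layout; the seed of any stochastic stage rides along."""
    out: dict = params.to_dict()
    if summary is not None:
        out.update(summary.to_dict())
    if convergence is not None:
        out["convergence"] = convergence
    if seed is not None:
        out["seed"] = int(seed)
    write_json(out, path)


def _spacing_from_affine(img) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_multimodal(paths: dict[str, str | Path]) -> MultimodalVolume:
    """Load co-registered modality volumes from NIfTI files keyed by
    modality name (t1, t1gd, t2, flair)."""
    unknown = set(paths) - set(MODALITIES)
    if unknown:
        raise ValueError(f"unknown modalities: {sorted(unknown)}")
    modalities = {}
    spacing = None
    affine = None
    for name, p in paths.items():
        img = nib.load(str(p))
        modalities[name] = np.asarray(img.get_fdata(), dtype=float)
        if spacing is None:
            spacing = _spacing_from_affine(img)
            affine = img.affine
    return MultimodalVolume(modalities, spacing, affine)


def write_mask(mask: TumorMask, path, affine: np.ndarray | None = None) -> None:
    aff = affine if affine is not None else np.diag(list(mask.voxel_spacing) + [1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), aff)
    nib.save(img, str(path))


def read_mask(path) -> TumorMask:
    img = nib.load(str(path))
    return TumorMask(np.asarray(img.get_fdata()) > 0.5,
                     _spacing_from_affine(img))
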