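"""Voxel-wise correction maps: the image-space route around re-reconstruction.

The correction map is defined as

    C = (PET_4C − PET_CT+MR) / PET_4C

within the pelvic mask, where PET_4C is the PET image reconstructed with the
bone-blind four-class µ-map and PET_CT+MR the one reconstructed with the
bone-augmented reference µ-map. Solving the definition for the reference
image gives the corrected image

    PET_cor = PET_4C · (1 − C),

which is exact when C is the true map and is how a *predicted* map is applied
to new data without any re-reconstruction. C < 0 means the four-class image
underestimates activity (the typical situation in and near bone); C > 0 means
overestimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import ImageVolume, VolumeError

#: activity floor below which the map is undefined (reuses the evaluation threshold)
DEFAULT_FLOOR_BQML = 300.0
#: clamp range applied to predicted maps before use
DEFAULT_CLAMP = (-2.0, 1.0)


@dataclass
class CorrectionMap:
    """Dimensionless voxel-wise map C with the mask where it is defined.

    Zero outside ``valid_mask`` by construction; finite inside.
    """

    volume: ImageVolume
    valid_mask: np.ndarray

    def __post_init__(self):
        if self.volume.role != "dimensionless":
            raise VolumeError("correction map must be dimensionless")
        if self.valid_mask.shape != self.volume.shape:
            raise VolumeError("valid_mask shape mismatch")
        data = np.asarray(self.volume.data)
        if not np.isfinite(data[self.valid_mask]).all():
            raise VolumeError("non-finite correction values inside valid_mask")
        if np.any(data[~self.valid_mask] != 0):
            raise VolumeError("correction map must be exactly 0 outside valid_mask")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


def compute_correction_map(
    pet4c: ImageVolume,
    petref: ImageVolume,
    pelvic_mask: np.ndarray,
    floor_bqml: float = DEFAULT_FLOOR_BQML,
) -> CorrectionMap:
    """Exact correction map from a reconstructed PET pair.

    Defined where the pelvic mask holds and PET_4C ≥ ``floor_bqml`` (the
    ratio is unstable in near-zero activity); zero and excluded from
    ``valid_mask`` elsewhere.
    """
    pet4c.require_same_grid(petref, "PET pair")
    if pelvic_mask.shape != pet4c.shape:
        raise VolumeError("pelvic mask shape mismatch")
    if floor_bqml <= 0:
        raise ValueError("floor_bqml must be > 0")
    p4 = np.asarray(pet4c.data, dtype=np.float64)
    pr = np.asarray(petref.data, dtype=np.float64)
    valid = pelvic_mask & (p4 >= floor_bqml)
    cmap = np.zeros_like(p4)
    cmap[valid] = (p4[valid] - pr[valid]) / p4[valid]
    return CorrectionMap(pet4c.with_data(cmap, role="dimensionless"), valid)


def apply_correction_map(pet4c: ImageVolume, cmap: CorrectionMap) -> ImageVolume:
    """PET_cor = PET_4C · (1 − C) inside valid_mask, PET_4C elsewhere.

    Output is clamped at 0 (an over-corrected voxel with C > 1 would
    otherwise go negative, which is unphysical for activity).
    """
    pet4c.require_same_grid(cmap.volume, "PET and correction map")
    c = np.asarray(cmap.data, dtype=np.float64)
    if not np.isfinite(c[cmap.valid_mask]).all():
        raise VolumeError("non-finite correction values inside valid_mask")
    p4 = np.asarray(pet4c.data, dtype=np.float64)
    out = p4.copy()
    out[cmap.valid_mask] = p4[cmap.valid_mask] * (1.0 - c[cmap.valid_mask])
    return pet4c.with_data(np.maximum(out, 0.0), role="activity_bqml")


def clamp_correction_map(cmap: CorrectionMap,
                         bounds: tuple[float, float] = DEFAULT_CLAMP) -> CorrectionMap:
    """Clamp a (predicted) map into a physical range before application."""
    lo, hi = bounds
    data = np.clip(cmap.data, lo, hi)
    data[~cmap.valid_mask] = 0.0
    return CorrectionMap(cmap.volume.with_data(data), cmap.valid_mask)
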