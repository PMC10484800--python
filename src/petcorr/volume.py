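"""Role-tagged 3D image volumes with NIfTI-1 serialization.

Every array that flows through the pipeline (CT in Hounsfield units, µ-maps
in cm⁻¹, PET activity in Bq/ml, Dixon MR intensities, label maps) is wrapped
in an :class:`ImageVolume` that carries voxel spacing, origin and a *role*
tag. Role-specific invariants (HU range, non-negativity of attenuation and
activity) are enforced at construction time so unit mistakes fail early.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Allowed role tags and the physical quantity they denote.
ROLES = {
    "hu",            # CT intensity, Hounsfield units
    "lac_cm",        # linear attenuation coefficient at 511 keV, cm^-1
    "activity_bqml", # tracer activity concentration, Bq/ml
    "mr_intensity",  # arbitrary (possibly signed) MR intensity
    "label",         # integer tissue-class codes
    "dimensionless", # e.g. correction maps, relative-error images
}

HU_MIN, HU_MAX = -1024.0, 3000.0


class VolumeError(ValueError):
    """Raised on invalid volume construction or grid mismatch."""


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing (mm), origin (mm) and a role tag.

    Parameters
    ----------
    data
        3D array, shape ``(nx, ny, nz)``; axial slices are ``data[:, :, k]``.
    spacing
        Voxel edge lengths ``(dx, dy, dz)`` in millimetres, strictly positive.
    origin
        World coordinate of voxel ``(0, 0, 0)`` in millimetres.
    role
        One of :data:`ROLES`.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = "dimensionless"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if self.role not in ROLES:
            raise VolumeError(f"unknown role {self.role!r}; expected one of {sorted(ROLES)}")
        self._check_role_values()

    def _check_role_values(self) -> None:
        d = self.data
        if self.role in ("lac_cm", "activity_bqml"):
            if d.size and float(np.nanmin(d)) < 0:
                raise VolumeError(f"role={self.role} requires non-negative values")
        elif self.role == "hu":
            if d.size and (float(np.nanmin(d)) < HU_MIN or float(np.nanmax(d)) > HU_MAX):
                raise VolumeError(f"role=hu requires values in [{HU_MIN}, {HU_MAX}]")

    # -- grid helpers ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_grid(self, other: "ImageVolume", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise VolumeError(
                f"{what} are not co-registered: "
                f"{self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )

    def with_data(self, data: np.ndarray, role: str | None = None) -> "ImageVolume":
        """Return a new volume on the same grid with different data (and role)."""
        return ImageVolume(data, self.spacing, self.origin, role or self.role)

    # -- NIfTI-1 I/O -------------------------------------------------------

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, role: str = "dimensionless") -> "ImageVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        if data.ndim != 3:
            raise VolumeError(f"{path}: expected a 3D NIfTI volume, got ndim={data.ndim}")
        aff = img.affine
        spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
        origin = tuple(float(v) for v in aff[:3, 3])
        if role == "label":
            data = np.rint(data).astype(np.int16)
        return cls(data, spacing, origin, role)


def resample_to_grid(vol: ImageVolume, target: ImageVolume, order: int = 1) -> ImageVolume:
    """Resample ``vol`` onto the grid of ``target`` by linear interpolation.

    Intended for user-supplied volumes that are not already on the PET grid;
    phantoms are generated co-registered and never need this. Values outside
    the source field of view are zero-filled.
    """
    if vol.same_grid(target):
        return target.with_data(vol.data.copy(), role=vol.role)
    # world coords of target voxel centres -> source voxel index coords
    idx = np.indices(target.shape, dtype=np.float64)
    src = np.empty_like(idx)
    for ax in range(3):
        world = target.origin[ax] + idx[ax] * target.spacing[ax]
        src[ax] = (world - vol.origin[ax]) / vol.spacing[ax]
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=np.float64), src, order=order, mode="constant", cval=0.0
    )
    return ImageVolume(out, target.spacing, target.origin, vol.role)
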