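"""Randomized synthetic pelvic phantoms.

Each phantom stands in for one co-registered patient dataset: a tissue label
map (air / fat / soft tissue / cortical bone / marrow), a CT volume in
Hounsfield units, a Dixon in-phase / out-of-phase MR pair, and a tracer
activity map with spherical lesions placed in bone and in soft tissue. All
volumes are generated on a single grid, so they are co-registered by
construction, and every lesion has a known ground-truth uptake.

Geometry is randomized per seed (jittered body ellipse and bone positions) so
that phantoms used for training and testing differ anatomically. The MR
channels are class-conditional intensity draws, not a fat/water physics
simulation: in-phase is water+fat signal, out-of-phase is the signed
water−fat difference, which is what makes fat and soft tissue separable by a
fat-fraction rule. Cortical bone and air carry (near) zero MR signal, the
property that makes bone invisible to Dixon-based attenuation correction and
creates the error this package corrects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .volume import ImageVolume, VolumeError

# label codes
AIR, FAT, SOFT_TISSUE, CORTICAL_BONE, MARROW = 0, 1, 2, 3, 4

LABEL_NAMES = {AIR: "air", FAT: "fat", SOFT_TISSUE: "soft_tissue",
               CORTICAL_BONE: "cortical_bone", MARROW: "marrow"}

# per-class CT draw ranges (HU)
HU_RANGES = {
    FAT: (-120.0, -80.0),
    SOFT_TISSUE: (20.0, 60.0),
    MARROW: (100.0, 300.0),
    CORTICAL_BONE: (700.0, 1500.0),
}
HU_AIR = -1000.0


class PlacementError(RuntimeError):
    """Lesion placement failed after bounded retries (phantom too small)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one randomized pelvic phantom.

    Defaults give a 64×64×24 grid at 4 mm isotropic spacing (256×256×96 mm
    field of view) with three bone structures (two lateral "hips", one
    posterior "sacrum"), two bone lesions and three soft-tissue lesions of
    8–16 mm diameter at 4:1 lesion-to-background uptake.
    """

    shape: tuple[int, int, int] = (64, 64, 24)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    body_semi_axes_mm: tuple[float, float] = (110.0, 85.0)
    body_jitter_mm: float = 8.0
    fat_rim_mm: float = 12.0
    n_bones: int = 3
    bone_center_jitter_mm: float = 8.0
    bone_radius_range_mm: tuple[float, float] = (16.0, 26.0)
    bone_z_semi_axis_range_mm: tuple[float, float] = (30.0, 46.0)
    marrow_fraction: float = 0.78
    n_bone_lesions: int = 2
    n_soft_lesions: int = 3
    lesion_diameter_range_mm: tuple[float, float] = (8.0, 16.0)
    lesion_activity_ratio: float = 4.0
    background_activity_bqml: float = 3000.0
    cortical_activity_fraction: float = 0.3
    pelvic_z_fraction_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self):
        dlo, dhi = self.lesion_diameter_range_mm
        if dlo < 2 * max(self.spacing):
            raise ValueError(
                f"lesion diameter {dlo} mm < 2 voxels ({2 * max(self.spacing)} mm)"
            )
        if self.lesion_activity_ratio <= 1:
            raise ValueError("lesion-to-background activity ratio must be > 1")
        if self.background_activity_bqml <= 0:
            raise ValueError("background activity must be > 0")


@dataclass
class Lesion:
    id: int
    tissue_class: str               # "bone" | "soft_tissue"
    center_mm: tuple[float, float, float]
    radius_mm: float
    roi_mask: np.ndarray | None = None

    def to_record(self) -> dict:
        return {"id": self.id, "tissue_class": self.tissue_class,
                "center_mm": list(self.center_mm), "radius_mm": self.radius_mm}


@dataclass
class Phantom:
    labels: ImageVolume
    ct: ImageVolume
    dixon_ip: ImageVolume
    dixon_op: ImageVolume
    activity: ImageVolume
    lesions: list[Lesion]
    body_mask: np.ndarray
    pelvic_mask: np.ndarray
    spec: PhantomSpec | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


# ---------------------------------------------------------------------------
# generation helpers

def _voxel_centers_mm(shape, spacing):
    """World coordinates (mm) of voxel centres, origin at the grid centre."""
    coords = []
    for n, d in zip(shape, spacing):
        coords.append((np.arange(n) - (n - 1) / 2.0) * d)
    return np.meshgrid(*coords, indexing="ij")


def _sphere_mask(shape, spacing, center_mm, radius_mm):
    x, y, z = _voxel_centers_mm(shape, spacing)
    r2 = ((x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2
          + (z - center_mm[2]) ** 2)
    return r2 <= radius_mm ** 2


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one co-registered phantom; deterministic for a given spec."""
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.spacing
    x, y, z = _voxel_centers_mm(shape, spacing)

    # body: elliptic cylinder along z with jittered semi-axes
    a = spec.body_semi_axes_mm[0] + rng.uniform(-spec.body_jitter_mm, spec.body_jitter_mm)
    b = spec.body_semi_axes_mm[1] + rng.uniform(-spec.body_jitter_mm, spec.body_jitter_mm)
    body = (x / a) ** 2 + (y / b) ** 2 <= 1.0

    labels = np.full(shape, AIR, dtype=np.int16)
    # subcutaneous fat rim: between the body ellipse and a shrunken ellipse
    ai, bi = a - spec.fat_rim_mm, b - spec.fat_rim_mm
    inner = (x / ai) ** 2 + (y / bi) ** 2 <= 1.0
    labels[body & ~inner] = FAT
    labels[inner] = SOFT_TISSUE

    # bone structures: ellipsoids of cortical bone around a marrow core,
    # at jittered canonical pelvic positions (two lateral, one posterior)
    base_positions = [(-0.45 * a, 0.0), (0.45 * a, 0.0), (0.0, 0.38 * b),
                      (0.0, -0.38 * b), (-0.25 * a, -0.3 * b), (0.25 * a, -0.3 * b)]
    for k in range(spec.n_bones):
        bx, by = base_positions[k % len(base_positions)]
        cx = bx + rng.uniform(-spec.bone_center_jitter_mm, spec.bone_center_jitter_mm)
        cy = by + rng.uniform(-spec.bone_center_jitter_mm, spec.bone_center_jitter_mm)
        rx = rng.uniform(*spec.bone_radius_range_mm)
        ry = rng.uniform(*spec.bone_radius_range_mm)
        rz = rng.uniform(*spec.bone_z_semi_axis_range_mm)
        cz = rng.uniform(-0.15, 0.15) * shape[2] * spacing[2]
        d2 = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
        outer = (d2 <= 1.0) & inner          # bone only inside soft tissue
        f = spec.marrow_fraction
        d2m = ((x - cx) / (f * rx)) ** 2 + ((y - cy) / (f * ry)) ** 2 \
            + ((z - cz) / (f * rz)) ** 2
        core = (d2m <= 1.0) & inner
        labels[outer] = CORTICAL_BONE
        labels[core] = MARROW

    # CT in HU: per-voxel draws within class ranges
    ct = np.full(shape, HU_AIR, dtype=np.float64)
    for cls, (lo, hi) in HU_RANGES.items():
        m = labels == cls
        ct[m] = rng.uniform(lo, hi, size=int(m.sum()))

    # Dixon pair: IP = water+fat, OP = water−fat (signed), class-conditional
    water = np.zeros(shape)
    fat_sig = np.zeros(shape)
    draws = {
        FAT: ((20.0, 100.0), (800.0, 1200.0)),
        SOFT_TISSUE: ((600.0, 1000.0), (20.0, 100.0)),
        MARROW: ((300.0, 600.0), (30.0, 120.0)),
        CORTICAL_BONE: ((0.0, 12.0), (0.0, 12.0)),
        AIR: ((0.0, 12.0), (0.0, 12.0)),
    }
    for cls, ((wlo, whi), (flo, fhi)) in draws.items():
        m = labels == cls
        n = int(m.sum())
        water[m] = rng.uniform(wlo, whi, size=n)
        fat_sig[m] = rng.uniform(flo, fhi, size=n)
    dixon_ip = water + fat_sig
    dixon_op = water - fat_sig

    # activity: uniform background in perfused tissue, reduced in cortical
    # bone, zero in air; lesions overwrite to background × ratio exactly
    bg = spec.background_activity_bqml
    activity = np.zeros(shape)
    activity[(labels == FAT) | (labels == SOFT_TISSUE) | (labels == MARROW)] = bg
    activity[labels == CORTICAL_BONE] = spec.cortical_activity_fraction * bg

    lesions = _place_lesions(spec, rng, labels, body)
    for les in lesions:
        activity[les.roi_mask] = bg * spec.lesion_activity_ratio

    mk = lambda d, role: ImageVolume(d, spacing, tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing)), role)
    phantom = Phantom(
        labels=mk(labels, "label"),
        ct=mk(ct, "hu"),
        dixon_ip=mk(dixon_ip, "mr_intensity"),
        dixon_op=mk(dixon_op, "mr_intensity"),
        activity=mk(activity, "activity_bqml"),
        lesions=lesions,
        body_mask=body,
        pelvic_mask=np.zeros(shape, dtype=bool),
        spec=spec,
    )
    phantom.pelvic_mask = make_pelvic_mask(phantom, spec.pelvic_z_fraction_range)
    return phantom


def _place_lesions(spec: PhantomSpec, rng, labels, body, max_tries: int = 400):
    # lesions live inside the pelvic slab: outside it the reference µ-map has
    # no bone inserted, so a "bone lesion" there would see no AC error at all
    lesions: list[Lesion] = []
    occupied = np.zeros(labels.shape, dtype=bool)
    shape, spacing = spec.shape, spec.spacing
    lo, hi = spec.pelvic_z_fraction_range
    z0, z1 = int(np.floor(lo * shape[2])), (int(np.floor(hi * shape[2])) if hi < 1 else shape[2])
    slab = np.zeros(shape, dtype=bool)
    slab[:, :, z0:z1] = True
    plan = [("bone", spec.n_bone_lesions), ("soft_tissue", spec.n_soft_lesions)]
    lid = 0
    for tissue, count in plan:
        if tissue == "bone":
            eligible = (labels == CORTICAL_BONE) | (labels == MARROW)
        else:
            eligible = labels == SOFT_TISSUE
        centers = np.argwhere(eligible)
        for _ in range(count):
            placed = False
            for _try in range(max_tries):
                if centers.size == 0:
                    break
                idx = centers[rng.integers(len(centers))]
                center_mm = tuple((idx[ax] - (shape[ax] - 1) / 2.0) * spacing[ax]
                                  for ax in range(3))
                radius = rng.uniform(*spec.lesion_diameter_range_mm) / 2.0
                roi = _sphere_mask(shape, spacing, center_mm, radius)
                if not roi.any():
                    continue
                if not (body & slab)[roi].all():
                    continue
                if (occupied & roi).any():
                    continue
                lesions.append(Lesion(lid, tissue, center_mm, radius, roi))
                occupied |= roi
                lid += 1
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place a {tissue} lesion after {max_tries} tries; "
                    "phantom too small or too crowded"
                )
    return lesions


# ---------------------------------------------------------------------------
# masks

def make_pelvic_mask(phantom: Phantom, z_fraction_range: tuple[float, float]) -> np.ndarray:
    """Axial slab [lo·Nz, hi·Nz) intersected with the body mask.

    Emulates restricting the analysis to the pelvic region (roughly upper
    thighs to the lower lumbar spine); the endpoints are configurable slab
    fractions, not anatomical landmarks.
    """
    lo, hi = z_fraction_range
    if not (0 <= lo < hi <= 1):
        raise ValueError(f"need 0 <= lo < hi <= 1, got ({lo}, {hi})")
    nz = phantom.shape[2]
    z0, z1 = int(np.floor(lo * nz)), int(np.floor(hi * nz)) if hi < 1 else nz
    if z1 <= z0:
        raise ValueError(f"empty axial slab: slices [{z0}, {z1})")
    mask = np.zeros(phantom.shape, dtype=bool)
    mask[:, :, z0:z1] = True
    return mask & phantom.body_mask


def body_contour_mask(volume: ImageVolume) -> np.ndarray:
    """Body mask from an MR intensity volume by automatic thresholding.

    Otsu bimodal split of the intensity histogram, followed by per-slice hole
    filling (bone and air cavities have no MR signal but belong inside the
    body) and largest-connected-component selection.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    if not np.isfinite(data).all():
        raise VolumeError("non-finite intensities")
    if np.ptp(data) == 0:
        raise VolumeError("degenerate (constant) intensity histogram")
    thr = filters.threshold_otsu(data)
    mask = data > thr
    filled = np.zeros_like(mask)
    for k in range(mask.shape[2]):
        filled[:, :, k] = ndimage.binary_fill_holes(mask[:, :, k])
    lab = measure.label(filled, connectivity=1)
    if lab.max() == 0:
        raise VolumeError("empty body mask after thresholding")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == int(np.argmax(sizes))


# ---------------------------------------------------------------------------
# serialization: a phantom as a directory of NIfTI files + lesions.json

_VOLUME_FILES = {
    "labels": ("labels.nii.gz", "label"),
    "ct": ("ct.nii.gz", "hu"),
    "dixon_ip": ("dixon_ip.nii.gz", "mr_intensity"),
    "dixon_op": ("dixon_op.nii.gz", "mr_intensity"),
    "activity": ("activity.nii.gz", "activity_bqml"),
}


def save_phantom(phantom: Phantom, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for attr, (fname, _role) in _VOLUME_FILES.items():
        getattr(phantom, attr).to_nifti(out / fname)
    ref = phantom.labels
    for name, mask in (("body_mask", phantom.body_mask), ("pelvic_mask", phantom.pelvic_mask)):
        ImageVolume(mask.astype(np.uint8), ref.spacing, ref.origin, "label").to_nifti(
            out / f"{name}.nii.gz")
    (out / "lesions.json").write_text(
        json.dumps([l.to_record() for l in phantom.lesions], indent=2))
    return out


def load_phantom(in_dir) -> Phantom:
    src = Path(in_dir)
    vols = {attr: ImageVolume.from_nifti(src / fname, role)
            for attr, (fname, role) in _VOLUME_FILES.items()}
    body = ImageVolume.from_nifti(src / "body_mask.nii.gz", "label").data.astype(bool)
    pelvic = ImageVolume.from_nifti(src / "pelvic_mask.nii.gz", "label").data.astype(bool)
    ref = vols["labels"]
    lesions = []
    for rec in json.loads((src / "lesions.json").read_text()):
        center = tuple(rec["center_mm"])
        # centres are stored relative to the grid centre; rebuild ROI mask
        roi = _sphere_mask(ref.shape, ref.spacing, center, rec["radius_mm"])
        lesions.append(Lesion(rec["id"], rec["tissue_class"], center,
                              rec["radius_mm"], roi))
    return Phantom(lesions=lesions, body_mask=body, pelvic_mask=pelvic, **vols)
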