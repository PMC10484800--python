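"""µ-map construction: four-class Dixon-based AC and the bone-augmented reference.

Four-class MR-based attenuation correction segments the Dixon pair into
background air, fat and soft tissue (no lung in a pelvic field of view) and
assigns each class a predefined linear attenuation coefficient (LAC) at
511 keV. Cortical bone gives no Dixon signal, so it is absorbed into soft
tissue — the systematic error this package quantifies and corrects.

The reference µ-map keeps the four-class soft-tissue values and overwrites
only bone: every voxel whose CT-derived LAC exceeds a threshold (default
0.1 cm⁻¹), restricted to the pelvic mask, takes the CT-derived value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import ImageVolume, VolumeError

#: predefined class LACs at 511 keV, cm^-1 (standard four-class values)
DEFAULT_CLASS_LACS = {"air": 0.0, "fat": 0.0854, "soft_tissue": 0.1000}

#: CT LAC above this is treated as bone information
DEFAULT_BONE_THRESHOLD_LAC = 0.1


@dataclass
class MuMap:
    """A LAC volume (cm⁻¹) with provenance and the class LACs that built it."""

    volume: ImageVolume
    provenance: str  # "four_class" | "reference"
    class_lacs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_LACS))

    def __post_init__(self):
        if self.provenance not in ("four_class", "reference"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.volume.role != "lac_cm":
            raise VolumeError("MuMap volume must have role lac_cm")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


@dataclass(frozen=True)
class HuLacTransform:
    """Bilinear HU → LAC(511 keV) conversion.

    Below the breakpoint the CT number scales like an air–water mixture,
    LAC = water_lac·(1000+HU)/1000; above it a shallower bone segment
    continues linearly. Continuous at the breakpoint and monotone by
    construction when both slopes are non-negative. The default bone slope
    (5.64e-5 cm⁻¹/HU) belongs to the commonly used bilinear transform family
    for 511 keV; the water point and both slopes are configurable.
    """

    water_lac: float = 0.096
    breakpoint_hu: float = 0.0
    bone_slope_per_hu: float = 5.64e-5

    def __post_init__(self):
        if self.water_lac <= 0 or self.bone_slope_per_hu < 0:
            raise ValueError("slopes must be non-negative, water LAC positive")

    def __call__(self, hu):
        hu = np.asarray(hu, dtype=np.float64)
        below = self.water_lac * (1000.0 + np.minimum(hu, self.breakpoint_hu)) / 1000.0
        value_at_bp = self.water_lac * (1000.0 + self.breakpoint_hu) / 1000.0
        above = value_at_bp + self.bone_slope_per_hu * np.maximum(hu - self.breakpoint_hu, 0.0)
        out = np.where(hu <= self.breakpoint_hu, below, above)
        return np.maximum(out, 0.0)


def hu_to_lac(ct: ImageVolume, transform: HuLacTransform | None = None) -> ImageVolume:
    """Scale a CT volume in Hounsfield units to LAC at 511 keV (cm⁻¹)."""
    if ct.role != "hu":
        raise VolumeError(f"expected role=hu, got {ct.role}")
    t = transform or HuLacTransform()
    return ct.with_data(t(ct.data), role="lac_cm")


def four_class_mumap(
    dixon_ip: ImageVolume,
    dixon_op: ImageVolume,
    body_mask: np.ndarray,
    class_lacs: dict | None = None,
) -> MuMap:
    """Four-class µ-map from the Dixon pair.

    Outside the body mask → background air (LAC 0). Inside, a fat-fraction
    proxy FF = (IP − OP)/(2·IP) (with IP the in-phase water+fat signal and OP
    the signed water−fat difference) is thresholded at 0.5: FF > 0.5 → fat,
    otherwise soft tissue. Voxels with no in-phase signal (bone, internal
    air) default to soft tissue, exactly as Dixon-based AC misclassifies
    bone. No lung class: a pelvic field of view contains none.
    """
    dixon_ip.require_same_grid(dixon_op, "Dixon volumes")
    if body_mask.shape != dixon_ip.shape:
        raise VolumeError("body mask shape does not match Dixon grid")
    if not body_mask.any():
        raise VolumeError("empty body mask")
    lacs = dict(class_lacs or DEFAULT_CLASS_LACS)

    ip = np.asarray(dixon_ip.data, dtype=np.float64)
    op = np.asarray(dixon_op.data, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        fat_fraction = np.where(ip > 0, (ip - op) / (2.0 * np.maximum(ip, 1e-30)), 0.0)
    # the fat fraction is meaningless where there is no in-phase signal
    # (cortical bone, internal air): such voxels fall through to soft tissue
    signal_floor = 0.05 * float(np.percentile(ip[body_mask], 99))
    mu = np.full(dixon_ip.shape, lacs["air"], dtype=np.float64)
    inside_fat = body_mask & (ip > signal_floor) & (fat_fraction > 0.5)
    mu[body_mask] = lacs["soft_tissue"]
    mu[inside_fat] = lacs["fat"]
    return MuMap(dixon_ip.with_data(mu, role="lac_cm"), "four_class", lacs)


def insert_bone(
    mu4c: MuMap,
    ct_lac: ImageVolume,
    pelvic_mask: np.ndarray,
    threshold_lac: float = DEFAULT_BONE_THRESHOLD_LAC,
) -> MuMap:
    """Insert CT bone information into a four-class µ-map → reference µ-map.

    Bone information is every voxel of the CT-derived LAC volume strictly
    above ``threshold_lac``; it replaces the four-class value only within the
    pelvic mask. The input µ-map is not mutated.
    """
    if threshold_lac <= 0:
        raise ValueError("threshold_lac must be > 0")
    mu4c.volume.require_same_grid(ct_lac, "µ-map and CT LAC")
    if pelvic_mask.shape != mu4c.volume.shape:
        raise VolumeError("pelvic mask shape does not match µ-map grid")
    bone = (np.asarray(ct_lac.data) > threshold_lac) & pelvic_mask
    out = np.array(mu4c.data, dtype=np.float64, copy=True)
    out[bone] = np.asarray(ct_lac.data)[bone]
    return MuMap(mu4c.volume.with_data(out), "reference", dict(mu4c.class_lacs))
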