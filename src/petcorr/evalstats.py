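"""Voxel- and lesion-based evaluation of corrected PET images.

Given a reference-standard PET image I_GS and a comparison image I_x, the
relative-error image is RE_x = (I_x − I_GS)/I_GS, evaluated only inside the
analysis mask at voxels whose reference activity exceeds a floor (default
300 Bq/ml). Two scalar summaries are reported in percent:

    MAPE  = 100 · mean(|RE|)
    RMSPE = 100 · sqrt(µ_RE² + σ_RE²) = 100 · sqrt(mean(RE²))

with the mean and the *population* standard deviation taken over the n_mask
evaluated voxels (the population convention makes the second equality exact,
and RMSPE ≥ MAPE always holds by Cauchy–Schwarz). Lesion performance uses
SUV_max — the maximum value in each lesion ROI under a linear SUV scale that
cancels in every relative error. Group comparisons use the two-sided
Wilcoxon signed-rank test (paired), the Mann–Whitney U test (unpaired) and
Benjamini–Hochberg correction across multiple comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .volume import ImageVolume, VolumeError

DEFAULT_ACTIVITY_FLOOR_BQML = 300.0
SIGNIFICANCE_LEVEL = 0.05


@dataclass
class MetricsResult:
    mu_re: float
    sigma_re: float
    mape: float      # percent
    rmspe: float     # percent
    n_mask: int


@dataclass
class LesionResult:
    lesion_id: int
    tissue_class: str
    suvmax: dict            # image name -> SUV_max
    relative_error: dict    # image name -> RE vs reference (reference excluded)
    abs_percentage_error: dict
    error: str | None = None


@dataclass
class TestReport:
    test: str
    statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False
    note: str = ""


def relative_error_image(
    img_x: ImageVolume,
    img_gs: ImageVolume,
    mask: np.ndarray,
    act_floor_bqml: float = DEFAULT_ACTIVITY_FLOOR_BQML,
) -> tuple[ImageVolume, np.ndarray]:
    """RE image and the evaluable mask (mask ∧ reference ≥ floor).

    Voxels below the floor are excluded, not zero-filled: the returned
    evaluable mask is the record of where RE is defined.
    """
    img_x.require_same_grid(img_gs, "compared and reference images")
    if mask.shape != img_x.shape:
        raise VolumeError("mask shape mismatch")
    gs = np.asarray(img_gs.data, dtype=np.float64)
    evaluable = mask & (gs >= act_floor_bqml)
    if not evaluable.any():
        raise VolumeError("no evaluable voxels above the activity floor")
    re = np.zeros_like(gs)
    re[evaluable] = (np.asarray(img_x.data, dtype=np.float64)[evaluable]
                     - gs[evaluable]) / gs[evaluable]
    return img_x.with_data(re, role="dimensionless"), evaluable


def compute_metrics(re_image: ImageVolume, evaluable_mask: np.ndarray) -> MetricsResult:
    """MAPE and RMSPE (percent) over the evaluable voxels."""
    if evaluable_mask.shape != re_image.shape:
        raise VolumeError("mask shape mismatch")
    re = np.asarray(re_image.data, dtype=np.float64)[evaluable_mask]
    if re.size == 0:
        raise VolumeError("empty evaluable set")
    mu = float(re.mean())
    sigma = float(re.std())  # population (n-denominator) standard deviation
    return MetricsResult(
        mu_re=mu,
        sigma_re=sigma,
        mape=100.0 * float(np.abs(re).mean()),
        rmspe=100.0 * float(np.sqrt(mu * mu + sigma * sigma)),
        n_mask=int(re.size),
    )


def evaluate_pair(img_x, img_gs, mask,
                  act_floor_bqml=DEFAULT_ACTIVITY_FLOOR_BQML) -> MetricsResult:
    """Convenience: RE image + metrics in one call."""
    re, ev = relative_error_image(img_x, img_gs, mask, act_floor_bqml)
    return compute_metrics(re, ev)


def suv_scale(weight_kg: float = 80.0, dose_mbq: float = 200.0) -> float:
    """Linear Bq/ml → SUV factor (g/ml per Bq/ml). Cancels in relative errors."""
    return weight_kg * 1000.0 / (dose_mbq * 1e6)


def lesion_metrics(lesions, pet_images: dict, gs_name: str,
                   suv_factor: float | None = None) -> list[LesionResult]:
    """Per-lesion SUV_max in every image and relative error vs the reference.

    SUV_max is taken over the full lesion ROI (the ROI, not the pelvic mask,
    defines the region). An empty ROI yields a per-lesion error record
    rather than aborting the analysis.
    """
    if gs_name not in pet_images:
        raise KeyError(f"reference image {gs_name!r} not among {sorted(pet_images)}")
    f = suv_scale() if suv_factor is None else suv_factor
    results = []
    for les in lesions:
        roi = les.roi_mask
        if roi is None or not roi.any():
            results.append(LesionResult(les.id, les.tissue_class, {}, {}, {},
                                        error="empty ROI"))
            continue
        suv = {name: f * float(np.asarray(img.data)[roi].max())
               for name, img in pet_images.items()}
        gs = suv[gs_name]
        rel, ape = {}, {}
        for name, v in suv.items():
            if name == gs_name:
                continue
            rel[name] = (v - gs) / gs
            ape[name] = 100.0 * abs(rel[name])
        results.append(LesionResult(les.id, les.tissue_class, suv, rel, ape))
    return results


# ---------------------------------------------------------------------------
# nonparametric comparisons

def paired_compare(metric_a, metric_b, name_a="a", name_b="b") -> TestReport:
    """Two-sided Wilcoxon signed-rank test on paired per-subject values."""
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D arrays")
    if a.size < 5:
        raise ValueError("need at least 5 pairs for the signed-rank test")
    diff = a - b
    if np.all(diff == 0):
        return TestReport("wilcoxon", 0.0, 1.0, False, degenerate=True,
                          note=f"all {name_a}−{name_b} differences are zero")
    stat, p = stats.wilcoxon(a, b, alternative="two-sided")
    return TestReport("wilcoxon", float(stat), float(p), bool(p < SIGNIFICANCE_LEVEL))


def unpaired_compare(group_a, group_b) -> TestReport:
    """Two-sided Mann–Whitney U test on two independent groups."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return TestReport("mannwhitneyu", float(a.size * b.size / 2.0), 1.0,
                          False, degenerate=True, note="all observations tied")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return TestReport("mannwhitneyu", float(stat), float(p),
                      bool(p < SIGNIFICANCE_LEVEL))


def bh_adjust(p_values, alpha: float = SIGNIFICANCE_LEVEL):
    """Benjamini–Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=np.float64)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def median_range(values) -> str:
    """Format as 'median [min, max]', the convention used in the reports."""
    v = np.asarray(values, dtype=np.float64)
    return f"{np.median(v):.1f} [{v.min():.1f}, {v.max():.1f}]"
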