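# Methods

This note documents the models, parameter choices and numerical decisions
behind `petcorr`, and what the synthetic experiments do and do not show.

## Correction-map model

The object of study is the voxel-wise map `C = (PET_4C − PET_CT+MR)/PET_4C`,
where `PET_4C` is reconstructed with a four-class (air/fat/soft-tissue)
Dixon-based µ-map and `PET_CT+MR` with the same µ-map plus CT-derived bone.
`C < 0` marks underestimation by the four-class reconstruction. Applying a
map to a four-class image inverts the definition,
`PET_cor = PET_4C·(1 − C)`, which is an exact algebraic identity when `C` is
the true map (property-tested to ~1e-14 relative) and a learned postprocessing
filter when `C` is predicted by the network.

`C` is undefined where `PET_4C = 0`. We define it only where the pelvic mask
holds and `PET_4C ≥ 300 Bq/ml` (the same activity floor used by the voxel
evaluation), set it to zero elsewhere, and record the defined region in a
validity mask. Predicted maps are clamped to `[−2, 1]` before application
(an applied `1 − C` factor between 0 and 3), and corrected images are clamped
at zero; both bounds express physical non-negativity. Training targets are
clamped to the same `[−2, 1]` range: values outside it are unreachable by the
clamped applied map, and a handful of extreme low-activity voxels would
otherwise dominate the L2 loss.

## Synthetic phantoms

One phantom plays the role of one co-registered patient dataset. Defaults:
64×64×24 voxels at 4 mm isotropic spacing; an elliptic-cylinder body
(semi-axes 110×85 mm, jittered ±8 mm per seed) with a 12 mm subcutaneous fat
rim; three ellipsoidal bone structures (two lateral, one posterior; in-plane
semi-axes 16–26 mm, jittered positions) consisting of a cortical shell around
a marrow core (`marrow_fraction = 0.78`, i.e. shells of roughly one voxel —
anatomically plausible cortical thickness, and the setting at which the
four-class bone-lesion SUV_max errors land in the clinically reported range
of about −10 % to −30 %). CT values are drawn per voxel per class
(fat −120…−80 HU, soft tissue 20…60 HU, marrow 100…300 HU, cortical bone
700…1500 HU, air −1000 HU).

The Dixon pair is *not* an MR physics simulation: in-phase is water+fat and
out-of-phase the signed water−fat difference, drawn per class so that fat and
soft tissue are separable by a fat-fraction rule, marrow is water-dominant
(so four-class segmentation maps the whole bone to soft tissue, as real
Dixon AC does), and cortical bone and air have near-zero signal. Activity is
3000 Bq/ml in perfused tissue, 30 % of that in cortical bone, zero in air;
spherical lesions (8–16 mm diameter, 4:1 uptake ratio, two in bone and three
in soft tissue) are placed non-overlapping inside the body and inside the
pelvic slab — outside the slab the reference µ-map carries no bone, so a
lesion there would see no AC error by construction. The pelvic mask is an
axial slab (default fractions 0.10–0.90 of the z-extent) intersected with the
body; its endpoints are configurable, not anatomical landmarks. The body
contour used at preprocessing time is recovered from the in-phase image by
Otsu thresholding, per-slice hole filling (bone and air cavities belong
inside) and largest-component selection.

Not emulated: MR artifacts and bias fields, respiratory motion, metal
implants, continuous tissue mixtures, inter-patient weight/dose variation.
Passing tests therefore demonstrate the machinery and the physics of the
bone-omission error, not clinical performance.

## µ-maps

CT is scaled to LAC at 511 keV with a bilinear transform: below the
breakpoint (0 HU) an air–water mixture line through (−1000 HU → 0) and
(0 HU → 0.096 cm⁻¹); above it a bone segment of 5.64e-5 cm⁻¹/HU. The three
constants belong to the standard bilinear family for 511 keV and are
configurable. Four-class LACs: fat 0.0854, soft tissue 0.1000, air 0 cm⁻¹;
no lung class in a pelvic field of view. Segmentation thresholds the
fat-fraction proxy `(IP−OP)/(2·IP)` at 0.5 where the in-phase signal exceeds
5 % of its 99th percentile within the body; no-signal voxels (cortical bone,
internal air) fall through to soft tissue — deliberately reproducing the
misclassification under study. The reference µ-map overwrites the four-class
values with the CT-derived LAC at voxels where the latter exceeds 0.1 cm⁻¹,
restricted to the pelvic mask; full CT values are inserted (not the increment
over soft tissue), matching the definition of transferred "bone information".

## PET simulator

Slice-wise 2D parallel-beam geometry: a pixel-driven sparse projector (linear
splat of each pixel onto two adjacent radial bins per angle; 126 angles over
180°, radial bin width = pixel size) whose transpose is the exact adjoint.
Expected counts per line of response are
`scale · exp(−∫µ dl) · ∫activity dl` — a single attenuation factor from the
full line integral, as both annihilation photons must escape. The global
scale is set so the mean true count per slice is 5e5 (a free desk-scale
parameter; clinical count levels per 2D slice are not identifiable from
bed-position acquisitions), with optional seeded Poisson noise. Ordinary
Poisson OSEM uses interleaved angle subsets, multiplicative attenuation
weighting in the system matrix, uniform initialization, exclusion (not
division) of zero-sensitivity voxels, and an in-plane Gaussian post-filter of
4 mm FWHM after the final of 3 iterations × 21 subsets. With one subset the
loop is textbook MLEM (asserted update-for-update against an independent
loop). Not modeled: PSF, scatter, randoms, time-of-flight, decay,
normalization.

A noiseless matched-µ reconstruction recovers a uniform disc's mean to ~0.4 %
(tolerance 5 %). With mismatched µ-maps, line-integral deficits of a few
percent concentrate into much deeper voxel deficits inside the bone
structures (verified independently with a filtered-back-projection route) —
the bone-omission artifact this package exists to correct, in exaggerated 2D
form (see Limitations).

## Network and training

A fully-convolutional residual encoder–decoder implemented in NumPy
(`petcorr.nn`: im2col-based conv/transposed-conv with exact adjoint pairs,
ReLU, residual blocks, Adam, masked MSE; all backward passes verified against
central differences). The front-end downsamples by a power of two, residual
blocks transform at low resolution, a transposed-convolution back-end
restores full resolution, and the single-channel output is linear (correction
values are signed). Zero padding and no normalization layers: at the network
sizes used here Adam trains stably without normalization, and this keeps the
hand-written backward passes small and verifiable.

Inputs are per-volume min–max scaled to [0, 1] (per volume, not per slice, so
axial intensity relations survive; the µ-map channel is scaled by its own
range) and zeroed outside the body contour. The loss is MSE weighted by the
target validity mask — zero weight outside it, so mask-border voxels do not
drag predictions toward zero. The learning rate is constant for the first
half of training, then decays linearly to zero. The reference configuration
(9 residual blocks, 64 base filters, ×4 downsampling, 100 epochs, decay from
epoch 50) is retained as the `NetConfig` default; learning rate 2e-4, batch
16 and the filter count are package choices, not literature-prescribed. The
desk-scale experiments use a reduced setting (2 blocks, 16 filters, ×2
downsampling, 40 epochs, LR 1e-3, batch 8, decay from epoch 20): at 4 mm
voxels, ×2 downsampling keeps an 8 mm effective grid, comparable to ×4 at
~2 mm clinical pixels, and the training set (8 phantoms × 24 slices = 192
slices) fits in a few CPU-minutes. No data augmentation. Training is
deterministic given the seed; the best-validation snapshot is retained.

## Evaluation

Relative-error images are computed against the reference reconstruction at
voxels inside the pelvic mask whose *reference* activity is ≥ 300 Bq/ml (the
reference is the fixed comparator across methods; undefined voxels are
excluded, never zero-filled). `σ_RE` uses the population (n-denominator)
convention, which makes `RMSPE = 100·sqrt(mean(RE²))` an exact identity
(asserted), and guarantees `RMSPE ≥ MAPE`. Lesion SUV_max is the ROI maximum
under a linear SUV scale that cancels in every relative error; ROIs are used
in full regardless of the pelvic mask. Summaries are medians with ranges.
Wilcoxon signed-rank (paired), Mann–Whitney U (unpaired) and
Benjamini–Hochberg adjustment come from scipy/statsmodels and are checked
against exact small-sample distributions; significance at p < 0.05.

## Limitations

The 2D slice geometry concentrates attenuation mismatch more strongly than
clinical 3D reconstruction: inside the synthetic bones the four-class error
reaches −50 % to −99 % at voxel level, versus tens of percent clinically. A
consequence is that the true correction map becomes strongly
*activity-dependent* near hot bone lesions (the map value at a lesion voxel
differs severalfold from the value the same voxel would have without the
lesion), and an anatomy-only predictor cannot resolve that ambiguity: it
learns the conditional mean of the map given anatomy. The learned correction
therefore roughly halves the voxel RMSPE on held-out phantoms — the central
quantitative behavior of the method — but *over-corrects* bone-lesion
SUV_max, unlike the clinical regime where the map's dynamic range is small
and lesion quantification improves. Soft-tissue lesion errors are small and
essentially unchanged. Interpreting the lesion-level outputs requires keeping
this desk-scale artifact in mind; the honest numbers are reported as-is by
`scripts/acceptance.py`.

Other limitations: phantoms share one grid (a resampling operation exists for
external co-registered NIfTI inputs but is not exercised by the default
pipeline); no scatter or PSF modeling; count levels, noise and geometry are
configurable but desk-scale; the five-class atlas-based AC baseline is out of
scope (it requires a proprietary bone atlas).
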