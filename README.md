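# petcorr

Image-space correction of the PET quantification error caused by bone being
invisible to four-class Dixon-based MR attenuation correction (AC), evaluated
end-to-end on synthetic pelvic phantoms.

## The problem

PET/MR scanners build their 511 keV attenuation map (µ-map) by segmenting a
Dixon MR acquisition into air, lung, fat and soft tissue, each with a fixed
linear attenuation coefficient (LAC). Cortical bone gives almost no MR signal
and is absorbed into soft tissue, so activity in and near bone — exactly where
skeletal metastases live — is systematically **underestimated**. Instead of
predicting a better µ-map and re-reconstructing, the approach implemented here
corrects the already-reconstructed PET image directly. Define the voxel-wise
correction map from a training pair of reconstructions,

```
C = (PET_4C − PET_CT+MR) / PET_4C
```

where `PET_4C` uses the four-class µ-map and `PET_CT+MR` uses a reference
µ-map (four-class soft tissue + CT-derived bone, inserted where the CT LAC
exceeds 0.1 cm⁻¹ within a pelvic mask). A residual encoder–decoder network is
trained (L2 loss, Adam, linearly decaying learning rate) to predict `C` from
three anatomy channels — Dixon in-phase, Dixon out-of-phase and the four-class
µ-map — and the corrected image is obtained by inverting the definition:

```
PET_cor = PET_4C · (1 − Ĉ)
```

Evaluation uses the relative-error image `RE = (I_x − I_GS)/I_GS` against the
reference reconstruction, restricted to the pelvic mask and voxels above
300 Bq/ml, summarized as `MAPE = 100·mean(|RE|)` and
`RMSPE = 100·sqrt(µ_RE² + σ_RE²)`, plus per-lesion SUV_max errors and
nonparametric tests (Wilcoxon signed-rank, Mann–Whitney U,
Benjamini–Hochberg).

Because clinical PET/MR+CT datasets of this kind are not publicly available,
the package ships a first-class synthetic phantom generator and a simplified
slice-wise PET simulator (attenuated parallel-beam forward projection, Poisson
noise, ordinary-Poisson OSEM with 3 iterations × 21 subsets and a 4-mm
Gaussian post-filter), so that every stage — µ-map construction, the
bone-omission artifact, correction-map learning, and the statistical
evaluation — runs from scratch on one CPU.

## Worked example

```python
import petcorr as pc
from petcorr import experiment as E

cfg = E.ExperimentConfig(save_volumes=False)   # 8 train / 2 val / 4 test phantoms
summary = E.run_experiment(cfg, "runs/demo")
print(summary["rmspe_pet4c"], "->", summary["rmspe_petcor"])
```

A run of exactly this configuration printed:

```
21.4 [20.9, 23.9] -> 10.6 [9.1, 12.1]
```

i.e. the median voxel RMSPE of the four-class reconstructions across the four
held-out phantoms was 21.4% (range in brackets), and applying the predicted
correction map roughly halved it to 10.6% — the learned map removes most of
the bone-omission error without any re-reconstruction. `runs/demo/` contains
the per-subject voxel metrics, lesion SUV_max tables, the training loss
history and a machine-readable `summary.json`.

The same pipeline is scriptable from the shell:

```
petcorr phantom  --out ph/ --seed 7
petcorr mumap    --phantom ph/ --out mu/
petcorr simulate --phantom ph/ --mumaps mu/ --out pet/
petcorr evaluate --ref pet/pet_ctmr.nii.gz --images pet/pet_4c.nii.gz \
                 --mask ph/pelvic_mask.nii.gz --out report/
petcorr run      --config experiment.yaml --out runs/exp1
```

All volumes are NIfTI-1; lesions are a JSON sidecar.

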