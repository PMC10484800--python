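"""End-to-end experiment: phantoms → µ-maps → PET pairs → training → evaluation.

One call reproduces the whole workflow at a configurable scale: generate
disjoint train/validation/test phantom cohorts, build the four-class and
reference µ-maps for each, simulate the PET_4C / PET_CT+MR pair, derive the
ground-truth correction maps, train the predictor on the training cohort,
then predict, correct and evaluate on the held-out test cohort. All
randomness is seeded per split with disjoint seed ranges so the cohorts
differ anatomically and no test phantom is ever seen in training.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correction, evalstats, model as model_mod, mumap as mumap_mod
from . import petsim, phantom as phantom_mod
from .phantom import Phantom, PhantomSpec
from .petsim import ReconConfig
from .model import NetConfig

log = logging.getLogger("petcorr")

#: reduced desk-scale network settings used by the default experiment; the
#: paper-scale NetConfig defaults (9 blocks, 64 filters, 100 epochs) are far
#: beyond what a single-CPU run needs for 64x64 phantom slices
DESK_SCALE_NET = {
    "n_res_blocks": 2, "base_filters": 16, "downsample_factor": 2,
    "epochs": 40, "lr": 1e-3, "batch_size": 8, "lr_decay_start_epoch": 20,
    "seed": 0,
}


@dataclass(frozen=True)
class ExperimentConfig:
    phantom: dict = field(default_factory=dict)     # PhantomSpec overrides (no seed)
    recon: dict = field(default_factory=dict)       # ReconConfig overrides (no seed)
    net: dict = field(default_factory=lambda: dict(DESK_SCALE_NET))  # NetConfig overrides
    n_train: int = 8
    n_val: int = 2
    n_test: int = 4
    seed_train: int = 100
    seed_val: int = 200
    seed_test: int = 300
    correction_floor_bqml: float = correction.DEFAULT_FLOOR_BQML
    activity_floor_bqml: float = evalstats.DEFAULT_ACTIVITY_FLOOR_BQML
    bone_threshold_lac: float = mumap_mod.DEFAULT_BONE_THRESHOLD_LAC
    save_volumes: bool = True

    def __post_init__(self):
        ranges = [
            range(self.seed_train, self.seed_train + self.n_train),
            range(self.seed_val, self.seed_val + self.n_val),
            range(self.seed_test, self.seed_test + self.n_test),
        ]
        seeds = [s for r in ranges for s in r]
        if len(set(seeds)) != len(seeds):
            raise ValueError("train/val/test seed ranges must be disjoint")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**cfg)


@dataclass
class SubjectData:
    """All simulated artifacts for one phantom ('subject')."""

    phantom: Phantom
    mu4c: mumap_mod.MuMap
    muref: mumap_mod.MuMap
    pet4c: object
    petref: object
    cmap_true: correction.CorrectionMap


def prepare_subject(spec: PhantomSpec, cfg: ExperimentConfig) -> SubjectData:
    """Generate one phantom and simulate everything up to the true correction map."""
    ph = phantom_mod.generate_phantom(spec)
    body = phantom_mod.body_contour_mask(ph.dixon_ip)
    mu4c = mumap_mod.four_class_mumap(ph.dixon_ip, ph.dixon_op, body)
    ct_lac = mumap_mod.hu_to_lac(ph.ct)
    muref = mumap_mod.insert_bone(mu4c, ct_lac, ph.pelvic_mask, cfg.bone_threshold_lac)
    recon_cfg = ReconConfig(**{**cfg.recon, "seed": spec.seed})
    pet4c, petref = petsim.simulate_pet_pair(ph, mu4c, muref, recon_cfg)
    cmap = correction.compute_correction_map(
        pet4c, petref, ph.pelvic_mask, cfg.correction_floor_bqml)
    return SubjectData(ph, mu4c, muref, pet4c, petref, cmap)


def _training_samples(subjects):
    samples = []
    for s in subjects:
        inp = model_mod.preprocess(s.phantom, s.mu4c)
        samples.extend(model_mod.attach_targets(inp, s.cmap_true))
    return samples


def evaluate_subject(s: SubjectData, net, cfg: ExperimentConfig) -> dict:
    """Predict, correct and evaluate one held-out subject."""
    cmap_pred = model_mod.predict_correction_map(
        net, s.phantom, s.mu4c, s.phantom.pelvic_mask)
    petcor = correction.apply_correction_map(s.pet4c, cmap_pred)
    m4 = evalstats.evaluate_pair(s.pet4c, s.petref, s.phantom.pelvic_mask,
                                 cfg.activity_floor_bqml)
    mc = evalstats.evaluate_pair(petcor, s.petref, s.phantom.pelvic_mask,
                                 cfg.activity_floor_bqml)
    lesions = evalstats.lesion_metrics(
        s.phantom.lesions,
        {"pet_4c": s.pet4c, "pet_cor": petcor, "pet_ctmr": s.petref},
        gs_name="pet_ctmr")
    return {"metrics_4c": m4, "metrics_cor": mc, "lesions": lesions,
            "petcor": petcor, "cmap_pred": cmap_pred}


def run_experiment(cfg: ExperimentConfig, out_dir) -> dict:
    """Run the full workflow; returns (and writes) the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log.info("experiment config: %s", asdict(cfg))
    (out / "config.json").write_text(json.dumps(asdict(cfg), indent=2, default=str))

    def stage(name):
        log.info("[%7.1fs] %s", time.time() - t0, name)

    splits = {}
    for split, n, seed0 in (("train", cfg.n_train, cfg.seed_train),
                            ("val", cfg.n_val, cfg.seed_val),
                            ("test", cfg.n_test, cfg.seed_test)):
        stage(f"simulate {split} cohort (n={n})")
        subjects = []
        for i in range(n):
            spec = PhantomSpec(**{**cfg.phantom, "seed": seed0 + i})
            subjects.append(prepare_subject(spec, cfg))
        splits[split] = subjects

    stage("build training samples")
    train_samples = _training_samples(splits["train"])
    val_samples = _training_samples(splits["val"]) if splits["val"] else None

    stage(f"train network on {len(train_samples)} slices")
    net_cfg = NetConfig(**{**DESK_SCALE_NET, **cfg.net})
    net = model_mod.build_network(net_cfg)
    result = model_mod.train(net, train_samples, net_cfg, val_samples,
                             log=log.info)
    pd.DataFrame({"epoch": np.arange(1, len(result.train_loss) + 1),
                  "train_loss": result.train_loss,
                  "val_loss": result.val_loss}).to_csv(out / "loss_history.csv",
                                                       index=False)

    stage("evaluate test cohort")
    rows, lesion_rows = [], []
    for i, s in enumerate(splits["test"]):
        ev = evaluate_subject(s, net, cfg)
        for tag, m in (("pet_4c", ev["metrics_4c"]), ("pet_cor", ev["metrics_cor"])):
            rows.append({"subject": i, "image": tag, **asdict(m)})
        for lr in ev["lesions"]:
            for img, ape in lr.abs_percentage_error.items():
                lesion_rows.append({
                    "subject": i, "lesion": lr.lesion_id,
                    "tissue_class": lr.tissue_class, "image": img,
                    "suvmax": lr.suvmax[img],
                    "relative_error": lr.relative_error[img],
                    "abs_percentage_error": ape})
        if cfg.save_volumes:
            sub = out / f"test_{i:02d}"
            sub.mkdir(exist_ok=True)
            phantom_mod.save_phantom(s.phantom, sub / "phantom")
            s.mu4c.volume.to_nifti(sub / "mu_4c.nii.gz")
            s.muref.volume.to_nifti(sub / "mu_reference.nii.gz")
            s.pet4c.to_nifti(sub / "pet_4c.nii.gz")
            s.petref.to_nifti(sub / "pet_ctmr.nii.gz")
            ev["petcor"].to_nifti(sub / "pet_cor.nii.gz")
            ev["cmap_pred"].volume.to_nifti(sub / "cmap_pred.nii.gz")

    voxel_df = pd.DataFrame(rows)
    voxel_df.to_csv(out / "voxel_metrics.csv", index=False)
    lesion_df = pd.DataFrame(lesion_rows)
    lesion_df.to_csv(out / "lesion_metrics.csv", index=False)

    r4 = voxel_df.query("image == 'pet_4c'")["rmspe"].to_numpy()
    rc = voxel_df.query("image == 'pet_cor'")["rmspe"].to_numpy()
    summary = {
        "n_train_slices": len(train_samples),
        "best_epoch": result.best_epoch,
        "rmspe_pet4c_median": float(np.median(r4)),
        "rmspe_petcor_median": float(np.median(rc)),
        "rmspe_pet4c": evalstats.median_range(r4),
        "rmspe_petcor": evalstats.median_range(rc),
        "mape_pet4c_median": float(voxel_df.query("image=='pet_4c'")["mape"].median()),
        "mape_petcor_median": float(voxel_df.query("image=='pet_cor'")["mape"].median()),
        "rmspe_median_reduction_percent": float(
            100.0 * (np.median(r4) - np.median(rc)) / np.median(r4)),
        "wall_time_s": time.time() - t0,
    }
    if len(r4) >= 5:
        rep = evalstats.paired_compare(r4, rc, "pet_4c", "pet_cor")
        summary["wilcoxon_rmspe_p"] = rep.p_value
    if not lesion_df.empty:
        for tissue in ("bone", "soft_tissue"):
            sel = lesion_df[lesion_df.tissue_class == tissue]
            for img in ("pet_4c", "pet_cor"):
                vals = sel[sel.image == img]["abs_percentage_error"]
                if len(vals):
                    summary[f"lesion_mape_{tissue}_{img}_median"] = float(vals.median())
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    stage("done")
    return summary
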