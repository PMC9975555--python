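"""End-to-end experiment plans: config, caching, logging and report bundles.

An :class:`ExperimentPlan` (YAML-serializable) names a synthetic dataset
configuration, a list of training conditions (policy x seeds), and the
evaluation batteries to run. :func:`run_plan` generates the data, trains (or
reuses cached checkpoints, keyed by a content hash of the condition), runs
the selected evaluations, and writes a JSON+CSV report bundle — optionally
with figure panels. One master seed expands deterministically into per-stage
seeds, and every number in the report traces back to (plan hash, condition,
seed, checkpoint id).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, representation
from .policies import BlurPolicy, TrainConfig
from .synthetic import generate_cue_conflict_set, generate_dataset
from .training import BlurTraining, ModelSpec, TrainingResults
from .zero_shot import ExclusionConfig, run_zero_shot

__all__ = ["ExperimentPlan", "run_plan"]

log = logging.getLogger("blurlab")

EVALUATIONS = ("lowpass", "bandpass", "tiles", "shapebias", "sb_correlation")


@dataclass
class ExperimentPlan:
    """Declarative description of a full experiment."""

    dataset: dict = field(default_factory=lambda: {
        "classes": 16, "train": 128, "test": 32, "size": 64})
    conditions: list[dict] = field(default_factory=list)
    evaluations: list[str] = field(default_factory=lambda: ["lowpass"])
    zero_shot: list[dict] = field(default_factory=list)
    master_seed: int = 0
    output: str = "blurlab_out"

    def __post_init__(self) -> None:
        for ev in self.evaluations:
            if ev not in EVALUATIONS:
                raise ValueError(f"unknown evaluation {ev!r}; one of {EVALUATIONS}")
        if not self.conditions:
            raise ValueError("plan must define at least one training condition")

    @staticmethod
    def from_yaml(path: str | Path) -> "ExperimentPlan":
        d = yaml.safe_load(Path(path).read_text())
        return ExperimentPlan(**d)

    def to_dict(self) -> dict:
        return {"dataset": self.dataset, "conditions": self.conditions,
                "evaluations": self.evaluations, "zero_shot": self.zero_shot,
                "master_seed": self.master_seed, "output": self.output}

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _condition_hash(plan_dataset: dict, cond: dict, seed: int) -> str:
    blob = json.dumps({"dataset": plan_dataset, "cond": cond, "seed": seed},
                      sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _train_condition(dataset, cond: dict, seed: int, ckpt_dir: Path,
                     plan_dataset: dict) -> tuple[TrainingResults, str, bool]:
    """Train one (condition, seed) cell, reusing a cached checkpoint if present."""
    chash = _condition_hash(plan_dataset, cond, seed)
    prefix = ckpt_dir / chash
    if prefix.with_suffix(".npz").exists() and prefix.with_suffix(".json").exists():
        log.info("condition %s seed %d: cache hit (%s)", cond["name"], seed, chash)
        return TrainingResults.load(prefix), chash, True
    policy = BlurPolicy.from_dict(cond["policy"])
    config = TrainConfig.from_dict(cond.get("config", {}))
    spec = None
    if "model" in cond:
        spec = ModelSpec.from_dict({"n_classes": dataset.n_classes,
                                    "image_size": dataset.manifest.image_size,
                                    **cond["model"]})
    model = BlurTraining.from_dataset(dataset, policy, spec=spec, config=config)
    results = model.fit(seed=seed)
    results.save(prefix)
    log.info("condition %s seed %d: trained, realized blur fraction %.3f",
             cond["name"], seed,
             results.blur_audit["n_blurred"].sum() / results.blur_audit["n_total"].sum())
    return results, chash, False


def run_plan(plan: ExperimentPlan, figures: bool = False) -> dict:
    """Execute an experiment plan; returns the report dict it also writes.

    Per-condition failures are isolated: the bundle is marked partial and the
    error recorded, instead of aborting the remaining conditions.
    """
    out = Path(plan.output)
    ckpt_dir = out / "checkpoints"
    ckpt_dir.mkdir(parents=True, exist_ok=True)
    ds_cfg = plan.dataset
    dataset = generate_dataset(
        n_classes=ds_cfg.get("classes", 16), n_train=ds_cfg.get("train", 128),
        n_test=ds_cfg.get("test", 32), image_size=ds_cfg.get("size", 64),
        master_seed=plan.master_seed)
    log.info("dataset: %d train / %d test images, manifest %s",
             len(dataset.train_images), len(dataset.test_images),
             dataset.manifest.hash())

    cc = None
    if "shapebias" in plan.evaluations:
        cc = generate_cue_conflict_set(dataset.classes,
                                       n_per_pair=ds_cfg.get("cue_per_pair", 1),
                                       image_size=ds_cfg.get("size", 64),
                                       master_seed=plan.master_seed)

    rows, profiles_frames, failures = [], [], []
    report: dict = {"plan_hash": plan.hash(), "plan": plan.to_dict(),
                    "dataset_hash": dataset.manifest.hash(),
                    "conditions": {}, "partial": False}
    for cond in plan.conditions:
        for seed in cond.get("seeds", [0]):
            try:
                res, chash, cached = _train_condition(dataset, cond, seed,
                                                      ckpt_dir, plan.dataset)
            except Exception as exc:
                log.error("condition %s seed %d failed: %r", cond["name"], seed, exc)
                failures.append({"condition": cond["name"], "seed": seed,
                                 "error": repr(exc)})
                continue
            cinfo = {"checkpoint": chash, "cached": cached,
                     "final": res.final_metrics}
            if "lowpass" in plan.evaluations:
                curve = behavior.lowpass_sweep(res, dataset.test_images,
                                               dataset.test_labels)
                for c, a in zip(curve.conditions, curve.accuracies):
                    rows.append({"model": cond["name"], "seed": seed,
                                 "battery": "lowpass", "condition": c,
                                 "accuracy": a, "checkpoint": chash})
            if "bandpass" in plan.evaluations:
                curve = behavior.bandpass_eval(res, dataset.test_images,
                                               dataset.test_labels)
                for c, a in zip(curve.conditions, curve.accuracies):
                    rows.append({"model": cond["name"], "seed": seed,
                                 "battery": "bandpass", "condition": c,
                                 "accuracy": a, "checkpoint": chash})
            if "tiles" in plan.evaluations:
                tdf = behavior.tile_eval(res, dataset.test_images,
                                         dataset.test_labels,
                                         seed=plan.master_seed)
                for _, r in tdf.iterrows():
                    rows.append({"model": cond["name"], "seed": seed,
                                 "battery": "tiles",
                                 "condition": f"{int(r['grid'])}x{int(r['grid'])}:{r['mode']}",
                                 "accuracy": float(r["accuracy"]),
                                 "checkpoint": chash})
            if "shapebias" in plan.evaluations and cc is not None:
                sb = behavior.compute_shape_bias(res, cc.images,
                                                 cc.shape_labels,
                                                 cc.texture_labels)
                rows.append({"model": cond["name"], "seed": seed,
                             "battery": "shapebias", "condition": "bias",
                             "accuracy": sb.bias, "checkpoint": chash})
            if "sb_correlation" in plan.evaluations:
                profs = representation.sb_profiles(
                    res, dataset.test_images, dataset.test_labels,
                    budget=2000, seed=plan.master_seed)
                for case, prof in profs.items():
                    df = prof.to_frame()
                    df.insert(0, "model", cond["name"])
                    df.insert(1, "seed", seed)
                    profiles_frames.append(df)
            report["conditions"][f"{cond['name']}/seed{seed}"] = cinfo

    for zcfg in plan.zero_shot:
        cfg = ExclusionConfig(zcfg["excluded_classes"], zcfg["excluded_type"],
                              zcfg.get("sigma", 4.0))
        config = TrainConfig.from_dict(zcfg.get("config", {}))
        tr = run_zero_shot(dataset, cfg, config=config, seed=plan.master_seed)
        rows.append({"model": tr.condition, "seed": plan.master_seed,
                     "battery": "zero_shot", "condition": "unseen",
                     "accuracy": tr.unseen_label_accuracy, "checkpoint": ""})
        rows.append({"model": tr.condition, "seed": plan.master_seed,
                     "battery": "zero_shot", "condition": "seen",
                     "accuracy": tr.seen_label_accuracy, "checkpoint": ""})

    results_df = pd.DataFrame(rows)
    results_df.to_csv(out / "results.csv", index=False)
    if profiles_frames:
        pd.concat(profiles_frames).to_csv(out / "sb_profiles.csv", index=False)
    if failures:
        report["partial"] = True
        report["failures"] = failures
    report["n_rows"] = len(results_df)
    (out / "report.json").write_text(json.dumps(report, indent=1))

    if figures and not results_df.empty:
        _write_figures(results_df, out)
    return report


def _write_figures(df: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    for battery, sub in df.groupby("battery"):
        fig, ax = plt.subplots(figsize=(6, 4))
        piv = sub.pivot_table(index="condition", columns="model",
                              values="accuracy", sort=False)
        piv.plot(ax=ax, marker="o")
        ax.set_ylabel("top-1 accuracy" if battery != "shapebias" else "shape bias")
        ax.set_ylim(0, 1)
        ax.set_title(battery)
        fig.tight_layout()
        fig.savefig(out / f"fig_{battery}.png", dpi=120)
        plt.close(fig)
        piv.to_csv(out / f"fig_{battery}.csv")
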