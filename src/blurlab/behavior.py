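"""Behavioral test battery for blur-trained classifiers.

Top-1 accuracy under: Gaussian low-pass sweeps, band-pass conditions,
tile-grid manipulations (jumble / gray occluder / both), and the shape-bias
statistic on shape-texture cue-conflict images:

    shape bias = correct shape decisions /
                 (correct shape decisions + correct texture decisions)

Evaluation is deterministic: test images receive no crop/flip augmentation,
and exact score ties in the argmax resolve to the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import BandSpec, BlurSpec, TileSpec, bandpass_display, lowpass, tile_manipulate
from .training import mean_ci

__all__ = [
    "AccuracyCurve", "ShapeBiasResult", "UniformRandomClassifier",
    "evaluate_topk", "lowpass_sweep", "bandpass_eval", "tile_eval",
    "compute_shape_bias", "aggregate_curves",
]

DEFAULT_SIGMAS = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0)
DEFAULT_BANDS = ((1.0, 2.0), (4.0, 8.0))
DEFAULT_GRIDS = (4, 8, 16, 32)
TILE_MODES = ("jumble", "gray_occluder", "jumble_and_occluder")


class UniformRandomClassifier:
    """Chance-level reference: predicts a uniformly random class per image.

    Exposes the same ``predict`` / ``predict_logits`` surface as
    :class:`blurlab.training.TrainingResults`, so every battery runs on it
    unchanged. Used for chance calibration of the evaluation pipeline.
    """

    def __init__(self, n_classes: int, seed: int = 0):
        self.n_classes = n_classes
        self._rng = np.random.default_rng(seed)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self._rng.integers(0, self.n_classes, size=len(images))

    def predict_logits(self, images: np.ndarray) -> np.ndarray:
        logits = np.zeros((len(images), self.n_classes))
        logits[np.arange(len(images)), self.predict(images)] = 1.0
        return logits


@dataclass
class AccuracyCurve:
    """Top-1 accuracy per condition for one model (tidy-frame convertible)."""

    conditions: list[str]
    accuracies: list[float]
    kind: str = "lowpass"

    def __getitem__(self, condition: str) -> float:
        return self.accuracies[self.conditions.index(condition)]

    def argmax_condition(self) -> str:
        return self.conditions[int(np.argmax(self.accuracies))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"condition": self.conditions,
                             "accuracy": self.accuracies, "kind": self.kind})


def evaluate_topk(model, images: np.ndarray, labels: np.ndarray, k: int = 1,
                  return_log: bool = False):
    """Top-k accuracy (k=1 by default): first choice matches the true label.

    With ``return_log=True`` also returns a per-image prediction DataFrame.
    """
    labels = np.asarray(labels)
    if len(images) == 0:
        raise ValueError("empty test set")
    if len(images) != len(labels):
        raise ValueError("images and labels differ in length")
    if k == 1:
        pred = np.asarray(model.predict(images))
        correct = pred == labels
    else:
        logits = np.asarray(model.predict_logits(images))
        # stable tie-break: lowest class index wins among equal scores
        order = np.argsort(-logits, axis=1, kind="stable")[:, :k]
        pred = order[:, 0]
        correct = (order == labels[:, None]).any(axis=1)
    acc = float(correct.mean())
    if return_log:
        log = pd.DataFrame({"image": np.arange(len(labels)), "label": labels,
                            "prediction": pred, "correct": correct})
        return acc, log
    return acc


def lowpass_sweep(model, images: np.ndarray, labels: np.ndarray,
                  sigmas=DEFAULT_SIGMAS) -> AccuracyCurve:
    """Accuracy at each blur level; sigma=0 is the sharp baseline."""
    sigmas = list(sigmas)
    if not sigmas:
        raise ValueError("sigma list must be non-empty")
    conds, accs = [], []
    for s in sigmas:
        blurred = lowpass(images, BlurSpec(float(s)))
        conds.append(f"sigma={s:g}")
        accs.append(evaluate_topk(model, blurred, labels))
    return AccuracyCurve(conds, accs, kind="lowpass")


def bandpass_eval(model, images: np.ndarray, labels: np.ndarray,
                  bands=DEFAULT_BANDS) -> AccuracyCurve:
    """Accuracy on band-pass images (display remap: +0.5, clipped to [0,1])."""
    conds, accs = [], []
    for lo, hi in bands:
        spec = BandSpec(float(lo), float(hi))
        conds.append(spec.name)
        accs.append(evaluate_topk(model, bandpass_display(images, spec), labels))
    return AccuracyCurve(conds, accs, kind="bandpass")


def tile_eval(model, images: np.ndarray, labels: np.ndarray,
              grids=DEFAULT_GRIDS, modes=TILE_MODES, seed: int = 0) -> pd.DataFrame:
    """Accuracy for every (grid, mode) tile-manipulation cell."""
    rows = []
    for g in grids:
        for mode in modes:
            spec = TileSpec(grid=int(g), mode=mode, permutation_seed=seed)
            acc = evaluate_topk(model, tile_manipulate(images, spec), labels)
            rows.append({"grid": int(g), "mode": mode, "accuracy": acc})
    return pd.DataFrame(rows)


@dataclass
class ShapeBiasResult:
    """Shape-vs-texture decision counts on cue-conflict images.

    ``bias`` is undefined (NaN, ``defined=False``) when no decision matched
    either label; it is never silently NaN-propagated into aggregates.
    """

    n_shape_correct: int
    n_texture_correct: int
    n_other: int
    decision_log: pd.DataFrame = field(repr=False, default=None)

    @property
    def total(self) -> int:
        return self.n_shape_correct + self.n_texture_correct + self.n_other

    @property
    def defined(self) -> bool:
        return (self.n_shape_correct + self.n_texture_correct) > 0

    @property
    def bias(self) -> float:
        d = self.n_shape_correct + self.n_texture_correct
        return self.n_shape_correct / d if d else float("nan")

    @property
    def cue_conflict_recognition(self) -> float:
        return (self.n_shape_correct + self.n_texture_correct) / self.total


def compute_shape_bias(model, images: np.ndarray, shape_labels: np.ndarray,
                       texture_labels: np.ndarray) -> ShapeBiasResult:
    """Shape bias over a two-label cue-conflict set, with a decision log."""
    shape_labels = np.asarray(shape_labels)
    texture_labels = np.asarray(texture_labels)
    if np.any(shape_labels == texture_labels):
        raise ValueError("cue-conflict images must have shape != texture labels")
    pred = np.asarray(model.predict(images))
    is_shape = pred == shape_labels
    is_texture = pred == texture_labels
    log = pd.DataFrame({
        "image": np.arange(len(pred)), "prediction": pred,
        "shape_class": shape_labels, "texture_class": texture_labels,
        "decision": np.where(is_shape, "shape",
                             np.where(is_texture, "texture", "other")),
    })
    return ShapeBiasResult(int(is_shape.sum()), int(is_texture.sum()),
                           int((~is_shape & ~is_texture).sum()), log)


def aggregate_curves(curves: list[AccuracyCurve]) -> pd.DataFrame:
    """Per-condition mean and 95% t-CI over an ensemble of accuracy curves."""
    if not curves:
        raise ValueError("need at least one curve")
    conds = curves[0].conditions
    rows = []
    for c in conds:
        vals = [cv[c] for cv in curves]
        m, lo, hi = mean_ci(vals)
        rows.append({"condition": c, "mean": m, "ci_lo": lo, "ci_hi": hi,
                     "n_seeds": len(vals)})
    return pd.DataFrame(rows)


def plot_accuracy_curves(frames: dict[str, AccuracyCurve], ax=None, title=""):
    """One line per model over shared conditions (layout mirrors a sweep panel)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for name, curve in frames.items():
        ax.plot(curve.conditions, curve.accuracies, marker="o", label=name)
    ax.set_ylabel("top-1 accuracy")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    return ax
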