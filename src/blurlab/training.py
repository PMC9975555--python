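"""Model objects for blur-policy training.

:class:`BlurTraining` bundles a labeled image set with a blur policy, an
architecture and an optimizer config; :meth:`BlurTraining.fit` runs SGD and
returns a :class:`TrainingResults` carrying the fitted network, the per-epoch
metrics, a blur audit log (realized per-class blur counts, used to verify the
policy contract), and prediction / activation / summary methods. An ensemble
helper refits across seeds and reports per-condition means with 95%
t-confidence intervals.

Training is deterministic given the seed: a single seed expands through
``numpy.random.SeedSequence`` into independent streams for weight
initialization, batch shuffling, blur-sample selection and augmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import nn
from .policies import BlurPolicy, TrainConfig
from .stimuli import BlurSpec, lowpass

__all__ = ["ModelSpec", "BlurTraining", "TrainingResults", "EnsembleResults",
           "train_seed_ensemble", "mean_ci"]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description for the small convolutional classifier.

    The default is a 4-conv-block + 2-dense analogue of the classic
    5-conv/3-dense ImageNet architecture, sized for 64x64 inputs. Capture
    points (post-ReLU) are conv1..conv4 and fc1, plus the logits as 'out'.
    """

    n_classes: int
    image_size: int = 64
    conv_channels: tuple[int, ...] = (16, 32, 64, 64)
    fc_units: int = 128
    head: str = "flatten"  # 'flatten' or 'gap' (global average pooling)

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 output classes")
        if self.image_size % 8 != 0:
            raise ValueError("image_size must be divisible by 8")
        if self.head not in ("flatten", "gap"):
            raise ValueError("head must be 'flatten' or 'gap'")

    @property
    def capture_points(self) -> list[str]:
        convs = [f"conv{i + 1}" for i in range(len(self.conv_channels))]
        return convs + ["fc1", "out"]

    def build(self, rng: np.random.Generator) -> nn.Network:
        c1, c2, c3, c4 = self.conv_channels
        s = self.image_size
        layers = [
            nn.Conv2d(3, c1, 5, stride=2, pad=2, rng=rng), nn.ReLU("conv1"),
            nn.MaxPool2x2(),
            nn.Conv2d(c1, c2, 3, pad=1, rng=rng), nn.ReLU("conv2"),
            nn.MaxPool2x2(),
            nn.Conv2d(c2, c3, 3, pad=1, rng=rng), nn.ReLU("conv3"),
            nn.Conv2d(c3, c4, 3, pad=1, rng=rng), nn.ReLU("conv4"),
            nn.MaxPool2x2(),
        ]
        if self.head == "gap":
            layers.append(nn.GlobalAvgPool())
            feat = c4
        else:
            layers.append(nn.Flatten())
            feat = c4 * (s // 16) ** 2
        layers += [nn.Dense(feat, self.fc_units, rng=rng), nn.ReLU("fc1"),
                   nn.Dense(self.fc_units, self.n_classes, rng=rng)]
        return nn.Network(layers, logits_name="out")

    def to_dict(self) -> dict:
        return {"n_classes": self.n_classes, "image_size": self.image_size,
                "conv_channels": list(self.conv_channels),
                "fc_units": self.fc_units, "head": self.head}

    @staticmethod
    def from_dict(d: dict) -> "ModelSpec":
        return ModelSpec(d["n_classes"], d["image_size"],
                         tuple(d["conv_channels"]), d["fc_units"],
                         d.get("head", "flatten"))


def _augment(batch: np.ndarray, cfg: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    """Random crop (after reflect padding) and random horizontal flip, NHWC."""
    n, h, w, _ = batch.shape
    p = cfg.crop_pad
    out = batch
    if p > 0:
        padded = np.pad(batch, ((0, 0), (p, p), (p, p), (0, 0)), mode="reflect")
        oy = rng.integers(0, 2 * p + 1, size=n)
        ox = rng.integers(0, 2 * p + 1, size=n)
        out = np.empty_like(batch)
        for i in range(n):
            out[i] = padded[i, oy[i]:oy[i] + h, ox[i]:ox[i] + w]
    if cfg.hflip:
        if out is batch:
            out = batch.copy()
        flip = rng.random(n) < 0.5
        out[flip] = out[flip, :, ::-1]
    return out


def _prepare_input(batch: np.ndarray, cfg: TrainConfig) -> np.ndarray:
    """NHWC [0,1] images -> network input (NCHW float32), per the config."""
    x = np.asarray(batch, dtype=np.float32)
    if cfg.input_norm == "standardize":
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        sd = x.std(axis=(1, 2, 3), keepdims=True)
        x = (x - mu) / np.maximum(sd, 1e-4)
    else:
        x = x - cfg.input_offset
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _blur_batch(batch: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Blur each sample at its assigned sigma (grouped by unique sigma)."""
    out = batch
    for s in np.unique(sigmas):
        if s == 0:
            continue
        if out is batch:
            out = batch.copy()
        idx = sigmas == s
        out[idx] = lowpass(batch[idx], BlurSpec(float(s)))
    return out


@dataclass
class TrainingResults:
    """A fitted blur-trained classifier plus its provenance and diagnostics."""

    spec: ModelSpec
    policy: BlurPolicy
    config: TrainConfig
    seed: int
    net: nn.Network = field(repr=False)
    history: pd.DataFrame = field(repr=False)      # per-epoch loss/acc/lr/sigma stats
    blur_audit: pd.DataFrame = field(repr=False)   # per-epoch, per-class blur counts
    class_names: list[str] | None = None
    exclusion: dict | None = None

    # -- inference ----------------------------------------------------------
    def predict_logits(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Logits for NHWC images in [0,1] (no test-time augmentation)."""
        xs = []
        for i in range(0, len(images), batch_size):
            x = self._to_input(images[i:i + batch_size])
            xs.append(self.net.forward(x))
        return np.concatenate(xs, axis=0)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_logits(images).argmax(axis=1)

    def evaluate(self, images: np.ndarray, labels: np.ndarray) -> float:
        if len(images) == 0:
            raise ValueError("empty evaluation set")
        return float((self.predict(images) == np.asarray(labels)).mean())

    def activations(self, images: np.ndarray, points: list[str] | None = None,
                    batch_size: int = 128) -> dict[str, np.ndarray]:
        """Post-ReLU activation vectors (and logits) per capture point."""
        valid = self.net.capture_points
        points = points or valid
        unknown = set(points) - set(valid)
        if unknown:
            raise ValueError(f"unknown capture points {sorted(unknown)}; "
                             f"available: {valid}")
        chunks: dict[str, list[np.ndarray]] = {p: [] for p in points}
        for i in range(0, len(images), batch_size):
            x = self._to_input(images[i:i + batch_size])
            _, acts = self.net.forward(x, capture=True)
            for p in points:
                chunks[p].append(acts[p])
        return {p: np.concatenate(chunks[p], axis=0) for p in points}

    def _to_input(self, images: np.ndarray) -> np.ndarray:
        return _prepare_input(images, self.config)

    # -- reporting ----------------------------------------------------------
    @property
    def final_metrics(self) -> dict:
        last = self.history.iloc[-1]
        return {"train_loss": float(last["loss"]), "train_acc": float(last["acc"])}

    def summary(self) -> str:
        lines = [
            "Blur-training results",
            "=" * 52,
            f"policy:        {self.policy.kind} (sigma={self.policy.sigma:g})",
            f"architecture:  conv{list(self.spec.conv_channels)} + "
            f"fc[{self.spec.fc_units}, {self.spec.n_classes}] @ "
            f"{self.spec.image_size}px",
            f"epochs:        {self.config.epochs}  (batch {self.config.batch_size}, "
            f"lr0 {self.config.lr0:g}, momentum {self.config.momentum:g}, "
            f"wd {self.config.weight_decay:g})",
            f"seed:          {self.seed}",
            f"final train:   loss {self.final_metrics['train_loss']:.4f}, "
            f"acc {self.final_metrics['train_acc']:.4f}",
            f"blurred frac:  {self.blur_audit['n_blurred'].sum() / max(1, self.blur_audit['n_total'].sum()):.3f} "
            f"(nominal {self._nominal_fraction():.3f})",
        ]
        if self.exclusion:
            lines.append(f"exclusion:     {self.exclusion}")
        return "\n".join(lines)

    def _nominal_fraction(self) -> float:
        if self.policy.kind == "S":
            return 0.0
        if self.policy.kind in ("B+S", "B+S_random"):
            return self.policy.blur_fraction
        if self.policy.kind == "B2S":
            sig = [self.policy.sigma_at_epoch(e) > 0 for e in range(self.config.epochs)]
            return float(np.mean(sig))
        return 1.0

    # -- persistence --------------------------------------------------------
    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.npz`` (weights), ``<prefix>.json`` (metadata) and
        ``<prefix>.metrics.csv`` (the per-epoch training log)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.savez(prefix.with_suffix(".npz"), **self.net.state_dict())
        self.history.to_csv(prefix.parent / f"{prefix.name}.metrics.csv",
                            index=False)
        meta = {
            "spec": self.spec.to_dict(), "policy": self.policy.to_dict(),
            "config": self.config.to_dict(), "seed": self.seed,
            "class_names": self.class_names, "exclusion": self.exclusion,
            "history": self.history.to_dict(orient="list"),
            "blur_audit": self.blur_audit.to_dict(orient="list"),
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @staticmethod
    def load(prefix: str | Path) -> "TrainingResults":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        spec = ModelSpec.from_dict(meta["spec"])
        net = spec.build(np.random.default_rng(0))
        with np.load(prefix.with_suffix(".npz")) as z:
            net.load_state_dict(dict(z))
        return TrainingResults(
            spec=spec, policy=BlurPolicy.from_dict(meta["policy"]),
            config=TrainConfig.from_dict(meta["config"]), seed=meta["seed"],
            net=net, history=pd.DataFrame(meta["history"]),
            blur_audit=pd.DataFrame(meta["blur_audit"]),
            class_names=meta.get("class_names"), exclusion=meta.get("exclusion"))


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


class BlurTraining:
    """Model object: dataset + blur policy + architecture + optimizer config.

    Parameters
    ----------
    train_images, train_labels
        NHWC float images in [0,1] and integer class labels.
    policy
        The blur-training policy (S / B / B+S / B2S / B+S_random).
    spec, config
        Architecture and optimizer settings; defaults are the desk-scale
        4-conv network and the reference SGD schedule.
    exclusion
        Optional class-exclusion rule (see :mod:`blurlab.zero_shot`) applied
        on top of the policy, with a per-class audit.
    """

    def __init__(self, train_images: np.ndarray, train_labels: np.ndarray,
                 policy: BlurPolicy, spec: ModelSpec | None = None,
                 config: TrainConfig | None = None, exclusion=None,
                 class_names: list[str] | None = None):
        self.x = np.asarray(train_images, dtype=np.float32)
        self.y = np.asarray(train_labels, dtype=np.int64)
        if len(self.x) != len(self.y):
            raise ValueError("images and labels differ in length")
        n_classes = int(self.y.max()) + 1
        self.policy = policy
        self.spec = spec or ModelSpec(n_classes=n_classes,
                                      image_size=self.x.shape[1])
        self.config = config or TrainConfig()
        self.exclusion = exclusion
        self.class_names = class_names
        if exclusion is not None:
            exclusion.validate(n_classes)

    @classmethod
    def from_dataset(cls, dataset, policy: BlurPolicy, **kw) -> "BlurTraining":
        """Construct from a :class:`blurlab.synthetic.SyntheticDataset`."""
        return cls(dataset.train_images, dataset.train_labels, policy,
                   class_names=[c.name for c in dataset.classes], **kw)

    def fit(self, seed: int = 0, verbose: bool = False) -> TrainingResults:
        cfg, policy = self.config, self.policy
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(17,))
        init_rng, shuffle_rng, blur_rng, aug_rng = map(
            np.random.default_rng, ss.spawn(4))
        net = self.spec.build(init_rng)
        opt = nn.SGD(net.params(), momentum=cfg.momentum,
                     weight_decay=cfg.weight_decay)

        n = len(self.x)
        hist, audit = [], []
        n_classes = self.spec.n_classes
        for epoch in range(cfg.epochs):
            lr = cfg.lr_at_epoch(epoch)
            order = shuffle_rng.permutation(n)
            losses, correct = [], 0
            blur_count = np.zeros(n_classes, dtype=np.int64)
            class_count = np.zeros(n_classes, dtype=np.int64)
            sigma_sum = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                labels = self.y[idx]
                batch = _augment(self.x[idx], cfg, aug_rng)
                sigmas = policy.assign_sigmas(epoch, labels, blur_rng,
                                              exclusion=self.exclusion)
                batch = _blur_batch(batch, sigmas)
                x = _prepare_input(batch, cfg)
                logits = net.forward(x)
                loss, dlogits = nn.softmax_cross_entropy(logits, labels)
                if not np.isfinite(loss):
                    raise DivergenceError(
                        f"training loss became non-finite at epoch {epoch}")
                net.backward(dlogits)
                opt.step(lr)
                losses.append(loss)
                correct += int((logits.argmax(axis=1) == labels).sum())
                blurred = sigmas > 0
                np.add.at(blur_count, labels[blurred], 1)
                np.add.at(class_count, labels, 1)
                sigma_sum += float(sigmas.sum())
            hist.append({"epoch": epoch, "loss": float(np.mean(losses)),
                         "acc": correct / n, "lr": lr,
                         "mean_sigma": sigma_sum / n,
                         "blur_fraction": blur_count.sum() / n})
            audit.append({"epoch": epoch, "n_total": int(class_count.sum()),
                          "n_blurred": int(blur_count.sum()),
                          **{f"class_{c}_blurred": int(blur_count[c])
                             for c in range(n_classes)},
                          **{f"class_{c}_total": int(class_count[c])
                             for c in range(n_classes)}})
            if verbose:
                print(f"epoch {epoch:3d}  loss {hist[-1]['loss']:.4f}  "
                      f"acc {hist[-1]['acc']:.4f}  lr {lr:g}")
        return TrainingResults(
            spec=self.spec, policy=policy, config=cfg, seed=seed, net=net,
            history=pd.DataFrame(hist), blur_audit=pd.DataFrame(audit),
            class_names=self.class_names,
            exclusion=None if self.exclusion is None else self.exclusion.to_dict())


def mean_ci(values, confidence: float = 0.95):
    """Mean and t-distribution confidence interval over seeds.

    With a single value the CI is undefined and reported as ``(nan, nan)``.
    A zero-variance sample yields a zero-width interval.
    """
    v = np.asarray(values, dtype=np.float64)
    m = float(v.mean())
    if len(v) < 2:
        return m, float("nan"), float("nan")
    sem = stats.sem(v)
    if sem == 0:
        return m, m, m
    half = sem * stats.t.ppf(0.5 + confidence / 2, len(v) - 1)
    return m, m - float(half), m + float(half)


@dataclass
class EnsembleResults:
    """Seed ensemble of :class:`TrainingResults` with CI aggregation."""

    members: list[TrainingResults]

    def __iter__(self):
        return iter(self.members)

    def __len__(self):
        return len(self.members)

    def aggregate(self, metric_fn, name: str = "value") -> pd.DataFrame:
        """Apply ``metric_fn(results) -> float`` per member; mean + 95% CI row."""
        vals = [metric_fn(r) for r in self.members]
        m, lo, hi = mean_ci(vals)
        return pd.DataFrame([{
            "metric": name, "mean": m, "ci_lo": lo, "ci_hi": hi,
            "n_seeds": len(vals), "values": vals,
        }])


def train_seed_ensemble(model: BlurTraining, seeds=range(8),
                        verbose: bool = False) -> EnsembleResults:
    """Refit the model once per seed (the reference protocol uses eight)."""
    members = []
    errors = []
    for s in seeds:
        try:
            members.append(model.fit(seed=int(s), verbose=verbose))
        except Exception as exc:  # report partial failures per seed
            errors.append((int(s), repr(exc)))
    if errors and not members:
        raise RuntimeError(f"all ensemble members failed: {errors}")
    if errors:
        import warnings

        warnings.warn(f"{len(errors)} ensemble member(s) failed: {errors}")
    return EnsembleResults(members)
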