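"""Blur-training policies and the optimizer schedule.

A :class:`BlurPolicy` maps (epoch, batch) to a per-sample blur sigma:

* ``S``    — sharp only, never blurs.
* ``B``    — blurs every sample at a fixed sigma (default 4 px).
* ``B+S``  — blurs exactly ``round(blur_fraction * batch)`` randomly chosen
  samples per batch at a fixed sigma (default: half the batch at sigma 4).
* ``B2S``  — coarse-to-fine curriculum: sigma starts at 4 and decreases by
  one every ``decay_step`` epochs (default 10), reaching 0 — so with the
  reference 60-epoch schedule the final 20 epochs are all-sharp.
* ``B+S_random`` — like B+S but each blurred sample draws sigma uniformly
  from ``sigma_range`` (default [0, 4]).

The optimizer schedule mirrors the torchvision classification reference:
SGD(momentum=0.9, weight_decay=5e-4), lr0=0.01 divided by 10 every third of
the total epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BlurPolicy", "TrainConfig", "sigma_schedule", "lr_at_epoch"]

POLICY_KINDS = ("S", "B", "B+S", "B2S", "B+S_random")

_ALIASES = {
    "s": "S", "b": "B", "b+s": "B+S", "bs": "B+S", "b2s": "B2S",
    "b+s-rand": "B+S_random", "b+s_random": "B+S_random", "bsrand": "B+S_random",
}


@dataclass(frozen=True)
class BlurPolicy:
    """Training-time rule mapping (epoch, batch) -> per-sample blur sigma."""

    kind: str
    sigma: float = 4.0
    sigma_range: tuple[float, float] = (0.0, 4.0)
    blur_fraction: float = 0.5
    decay_step: int = 10

    def __post_init__(self) -> None:
        kind = _ALIASES.get(self.kind.lower(), self.kind)
        if kind not in POLICY_KINDS:
            raise ValueError(f"unknown policy kind {self.kind!r}; "
                             f"expected one of {POLICY_KINDS}")
        object.__setattr__(self, "kind", kind)
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0 <= self.blur_fraction <= 1:
            raise ValueError("blur_fraction must lie in [0, 1]")

    # -- schedule -----------------------------------------------------------
    def sigma_at_epoch(self, epoch: int) -> float:
        """Deterministic sigma component of the rule at this epoch.

        For B2S this is the decayed sigma ``max(0, sigma0 - floor(e/step))``;
        for the other policies it is the fixed training sigma (S: 0).
        """
        if epoch < 0:
            raise ValueError("epoch must be non-negative")
        if self.kind == "S":
            return 0.0
        if self.kind == "B2S":
            return max(0.0, self.sigma - (epoch // self.decay_step))
        return self.sigma

    def schedule_rule(self, epoch: int) -> dict:
        """Describe the per-sample blur rule applied at this epoch."""
        s = self.sigma_at_epoch(epoch)
        if self.kind in ("S", "B", "B2S"):
            return {"mode": "constant", "sigma": s if self.kind != "S" else 0.0,
                    "fraction": 0.0 if self.kind == "S" or s == 0 else 1.0}
        if self.kind == "B+S":
            return {"mode": "mixture", "sigma": s, "fraction": self.blur_fraction}
        return {"mode": "mixture_random", "sigma_range": self.sigma_range,
                "fraction": self.blur_fraction}

    # -- per-batch assignment ----------------------------------------------
    def assign_sigmas(self, epoch: int, labels: np.ndarray,
                      rng: np.random.Generator,
                      exclusion=None) -> np.ndarray:
        """Per-sample sigma for one batch.

        ``exclusion`` (see :mod:`blurlab.zero_shot`) overrides the rule for
        its classes: excluded_type='blurred' means those classes are never
        blurred, 'sharp' means they are always blurred. The nominal mixture
        fraction is then applied among the remaining samples only, so the
        realized blur fraction of non-excluded classes is unchanged.
        """
        n = len(labels)
        sig = np.zeros(n, dtype=np.float64)
        free = np.ones(n, dtype=bool)
        if exclusion is not None:
            excl = np.isin(labels, list(exclusion.excluded_classes))
            free &= ~excl
            if exclusion.excluded_type == "sharp":
                sig[excl] = self.sigma
            # 'blurred' exclusion: sigma stays 0 for those samples

        idx = np.flatnonzero(free)
        if self.kind in ("S",):
            pass
        elif self.kind in ("B", "B2S"):
            sig[idx] = self.sigma_at_epoch(epoch)
        else:  # mixtures
            n_blur = int(round(self.blur_fraction * len(idx)))
            chosen = rng.choice(idx, size=n_blur, replace=False) if n_blur else []
            if self.kind == "B+S":
                sig[chosen] = self.sigma
            else:
                sig[chosen] = rng.uniform(*self.sigma_range, size=n_blur)
        return sig


    def to_dict(self) -> dict:
        return {"kind": self.kind, "sigma": self.sigma,
                "sigma_range": list(self.sigma_range),
                "blur_fraction": self.blur_fraction, "decay_step": self.decay_step}

    @staticmethod
    def from_dict(d: dict) -> "BlurPolicy":
        d = dict(d)
        if "sigma_range" in d:
            d["sigma_range"] = tuple(d["sigma_range"])
        return BlurPolicy(**d)


def sigma_schedule(policy: BlurPolicy, epoch: int) -> dict:
    """The blur rule a batch blurrer applies at ``epoch`` (module-level form)."""
    return policy.schedule_rule(epoch)


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and augmentation hyperparameters.

    The learning rate is piecewise constant:
    ``lr(e) = lr0 * 0.1 ** floor(e / (epochs / 3))`` — i.e. divided by ten at
    each third of training (every 20 epochs in the reference 60-epoch run).
    """

    epochs: int = 60
    batch_size: int = 64
    lr0: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 5e-4
    crop_pad: int = 4      # reflect-pad then random-crop augmentation
    hflip: bool = True
    input_offset: float = 0.5  # inputs are x - offset, keeping [0,1] image units
    input_norm: str = "offset"  # 'offset' or 'standardize' (per-image z-score)

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.input_norm not in ("offset", "standardize"):
            raise ValueError("input_norm must be 'offset' or 'standardize'")

    def lr_at_epoch(self, epoch: int) -> float:
        if not 0 <= epoch < self.epochs:
            raise ValueError(f"epoch {epoch} outside [0, {self.epochs})")
        return self.lr0 * 0.1 ** int(epoch / (self.epochs / 3.0))

    def to_dict(self) -> dict:
        return {"epochs": self.epochs, "batch_size": self.batch_size,
                "lr0": self.lr0, "momentum": self.momentum,
                "weight_decay": self.weight_decay, "crop_pad": self.crop_pad,
                "hflip": self.hflip, "input_offset": self.input_offset,
                "input_norm": self.input_norm}

    @staticmethod
    def from_dict(d: dict) -> "TrainConfig":
        return TrainConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                              for k, v in d.items()})


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate at ``epoch`` under the stepped decay schedule."""
    return cfg.lr_at_epoch(epoch)
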