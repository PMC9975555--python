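"""Internal-representation analyses.

Layer-wise representational similarity between two stimulus conditions
(e.g. sharp vs blurred — the S-B correlation — or high-pass vs low-pass —
the H-L correlation): for each image pair, the Pearson correlation of the
post-ReLU unit-activation vectors is computed across units within a layer,
then summarized over pairs (mean and 25–75% interquartile range). Three
pairing cases are distinguished: the two conditions applied to the *same*
image, to different images of the same class, and to different images of
different classes.

Also here: 2-D t-SNE embeddings of layer activations and first-layer filter
visualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import BandSpec, BlurSpec, bandpass_display, lowpass

__all__ = [
    "PAIRING_CASES", "CorrelationProfile", "capture_activations",
    "build_pairs", "paired_correlation_profile", "sb_profiles", "hl_profiles",
    "embed_2d", "export_first_layer_filters", "pairwise_pearson",
]

PAIRING_CASES = ("same_image", "same_class_different_image", "different_class")

#: default cap on sampled pairs for the different-image cases
DEFAULT_PAIR_BUDGET = 10_000


def capture_activations(model, images: np.ndarray,
                        capture_points: list[str] | None = None) -> dict[str, np.ndarray]:
    """Flattened post-ReLU activation vectors per capture point (plus logits)."""
    return model.activations(images, points=capture_points)


def build_pairs(labels: np.ndarray, case: str, rng=None,
                budget: int = DEFAULT_PAIR_BUDGET) -> np.ndarray:
    """Index pairs (i, j) for one pairing case.

    ``same_image`` enumerates (i, i). The different-image cases enumerate all
    ordered-distinct pairs and subsample uniformly to ``budget`` pairs when
    the enumeration is larger (seeded; pass a Generator or seed).
    """
    labels = np.asarray(labels)
    n = len(labels)
    if case not in PAIRING_CASES:
        raise ValueError(f"unknown pairing case {case!r}; one of {PAIRING_CASES}")
    if case == "same_image":
        idx = np.arange(n)
        return np.stack([idx, idx], axis=1)
    rng = np.random.default_rng(rng)
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    distinct = ii != jj
    same_class = labels[ii] == labels[jj]
    keep = distinct & (same_class if case == "same_class_different_image"
                       else ~same_class)
    pairs = np.stack([ii[keep], jj[keep]], axis=1)
    if len(pairs) > budget:
        pairs = pairs[rng.choice(len(pairs), size=budget, replace=False)]
    return pairs


def pairwise_pearson(a: np.ndarray, b: np.ndarray):
    """Row-wise Pearson r between matching rows of two (P, U) matrices.

    Returns ``(r, valid)`` where ``valid`` marks rows where both vectors had
    non-zero variance (Pearson is undefined otherwise).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    va = (ac * ac).sum(axis=1)
    vb = (bc * bc).sum(axis=1)
    valid = (va > 0) & (vb > 0)
    denom = np.sqrt(va * vb)
    r = np.zeros(len(a))
    r[valid] = (ac * bc).sum(axis=1)[valid] / denom[valid]
    return r, valid


@dataclass
class CorrelationProfile:
    """Per-layer mean paired Pearson correlation with IQR, for one pairing case."""

    case: str
    condition_pair: str
    layers: list[str]
    mean_r: dict[str, float]
    q25: dict[str, float]
    q75: dict[str, float]
    n_pairs: dict[str, int]
    n_skipped: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, layer: str) -> float:
        return self.mean_r[layer]

    def skip_fraction(self) -> float:
        tot = sum(self.n_pairs.values()) + sum(self.n_skipped.values())
        return sum(self.n_skipped.values()) / tot if tot else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "layer": self.layers, "case": self.case,
            "condition_pair": self.condition_pair,
            "mean_r": [self.mean_r[l] for l in self.layers],
            "q25": [self.q25[l] for l in self.layers],
            "q75": [self.q75[l] for l in self.layers],
            "n_pairs": [self.n_pairs[l] for l in self.layers],
            "n_skipped": [self.n_skipped.get(l, 0) for l in self.layers],
        })

    def to_csv(self, path) -> None:
        """Lossless CSV serialization (17 significant digits)."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @staticmethod
    def from_csv(path) -> "CorrelationProfile":
        return CorrelationProfile.from_frame(
            pd.read_csv(path, float_precision="round_trip"))

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "CorrelationProfile":
        layers = list(df["layer"])
        return CorrelationProfile(
            case=str(df["case"].iloc[0]),
            condition_pair=str(df["condition_pair"].iloc[0]),
            layers=layers,
            mean_r=dict(zip(layers, df["mean_r"].astype(float))),
            q25=dict(zip(layers, df["q25"].astype(float))),
            q75=dict(zip(layers, df["q75"].astype(float))),
            n_pairs=dict(zip(layers, df["n_pairs"].astype(int))),
            n_skipped=dict(zip(layers, df["n_skipped"].astype(int))))


def paired_correlation_profile(acts_a: dict[str, np.ndarray],
                               acts_b: dict[str, np.ndarray],
                               pairs: np.ndarray, case: str,
                               condition_pair: str = "",
                               chunk: int = 512,
                               axis: str = "units") -> CorrelationProfile:
    """Correlation profile over layers for given (i, j) activation pairs.

    With the default ``axis='units'``, the Pearson r is computed per pair
    across units within each layer, and the mean and 25/75 percentiles are
    taken over pairs. ``axis='pairs'`` is the alternative reading: r per
    unit across the pair set, summarized over units. Zero-variance vectors
    make r undefined — such pairs (or units) are skipped and counted rather
    than silently zeroed.
    """
    if set(acts_a) != set(acts_b):
        raise ValueError("activation sets must share capture points")
    if axis not in ("units", "pairs"):
        raise ValueError("axis must be 'units' or 'pairs'")
    layers = list(acts_a)
    mean_r, q25, q75, n_pairs, n_skip = {}, {}, {}, {}, {}
    for layer in layers:
        rs = []
        n_bad = 0
        if axis == "pairs":
            # one r per unit, computed across the sampled pairs
            a = acts_a[layer][pairs[:, 0]].T
            b = acts_b[layer][pairs[:, 1]].T
            r, valid = pairwise_pearson(a, b)
            rs.append(r[valid])
            n_bad = int((~valid).sum())
        else:
            for start in range(0, len(pairs), chunk):
                p = pairs[start:start + chunk]
                r, valid = pairwise_pearson(acts_a[layer][p[:, 0]],
                                            acts_b[layer][p[:, 1]])
                rs.append(r[valid])
                n_bad += int((~valid).sum())
        rs = np.concatenate(rs) if rs else np.array([])
        n_pairs[layer] = len(rs)
        n_skip[layer] = n_bad
        if len(rs):
            mean_r[layer] = float(rs.mean())
            q25[layer] = float(np.percentile(rs, 25))
            q75[layer] = float(np.percentile(rs, 75))
        else:
            mean_r[layer] = q25[layer] = q75[layer] = float("nan")
    return CorrelationProfile(case, condition_pair, layers, mean_r, q25, q75,
                              n_pairs, n_skip)


def _condition_profiles(model, images_a: np.ndarray, images_b: np.ndarray,
                        labels: np.ndarray, condition_pair: str,
                        budget: int, seed: int,
                        capture_points=None) -> dict[str, CorrelationProfile]:
    acts_a = capture_activations(model, images_a, capture_points)
    acts_b = capture_activations(model, images_b, capture_points)
    out = {}
    for k, case in enumerate(PAIRING_CASES):
        pairs = build_pairs(labels, case,
                            rng=np.random.SeedSequence([seed, k]), budget=budget)
        out[case] = paired_correlation_profile(acts_a, acts_b, pairs, case,
                                               condition_pair)
    return out


def sb_profiles(model, images: np.ndarray, labels: np.ndarray,
                sigma: float = 4.0, budget: int = DEFAULT_PAIR_BUDGET,
                seed: int = 0, capture_points=None) -> dict[str, CorrelationProfile]:
    """Sharp-vs-blurred (S-B) correlation profiles for all three pairing cases."""
    blurred = lowpass(images, BlurSpec(sigma))
    return _condition_profiles(model, images, blurred, labels,
                               f"sharp_vs_sigma{sigma:g}", budget, seed,
                               capture_points)


def hl_profiles(model, images: np.ndarray, labels: np.ndarray,
                band: tuple[float, float] = (1.0, 2.0), sigma: float = 4.0,
                budget: int = DEFAULT_PAIR_BUDGET, seed: int = 0,
                capture_points=None) -> dict[str, CorrelationProfile]:
    """High-pass (band) vs low-pass (blur) correlation profiles."""
    spec = BandSpec(*band)
    high = bandpass_display(images, spec)
    low = lowpass(images, BlurSpec(sigma))
    return _condition_profiles(model, high, low, labels,
                               f"{spec.name}_vs_sigma{sigma:g}", budget, seed,
                               capture_points)


def embed_2d(activations: np.ndarray, perplexity: float = 30.0,
             iterations: int = 1000, seed: int = 0) -> np.ndarray:
    """t-SNE embedding of activation vectors to 2-D (one row per image)."""
    from sklearn.manifold import TSNE

    x = np.asarray(activations, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("activations must be a 2-D (images x units) array")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate input: all activation vectors are identical")
    n = len(x)
    if n <= perplexity:
        raise ValueError(f"perplexity {perplexity} requires more than "
                         f"{int(perplexity)} samples, got {n}")
    if n < 3 * perplexity:
        warnings.warn(f"only {n} points for perplexity {perplexity}; "
                      "at least 3x perplexity is recommended")
    ts = TSNE(n_components=2, perplexity=perplexity, max_iter=iterations,
              random_state=seed, init="pca")
    return ts.fit_transform(x)


def export_first_layer_filters(model, path=None, scale: int = 8):
    """First-convolution kernels as a normalized RGB tile grid.

    Each filter is mapped symmetrically around zero (so an all-zero filter
    renders mid-gray), tiled into a near-square grid, and optionally written
    as a PNG. Returns the grid as a float array in [0, 1].
    """
    from .nn import Conv2d

    conv = model.net.layers[0]
    if not isinstance(conv, Conv2d):
        raise ValueError("first layer is not convolutional")
    w = conv.w  # (F, C, k, k)
    f, c, k, _ = w.shape
    ncol = int(np.ceil(np.sqrt(f)))
    nrow = int(np.ceil(f / ncol))
    pad = 1
    grid = np.full((nrow * (k + pad) + pad, ncol * (k + pad) + pad, 3), 0.5)
    for i in range(f):
        m = np.abs(w[i]).max()
        tile = 0.5 + (w[i] / (2 * m) if m > 0 else np.zeros_like(w[i]))
        r, col = divmod(i, ncol)
        y, x = pad + r * (k + pad), pad + col * (k + pad)
        grid[y:y + k, x:x + k] = tile.transpose(1, 2, 0)[:, :, :3]
    if path is not None:
        from PIL import Image

        big = np.kron(grid, np.ones((scale, scale, 1)))
        u8 = (np.clip(big, 0, 1) * 255).round().astype(np.uint8)
        Image.fromarray(u8).save(path)
    return grid


def plot_profiles(profiles: dict[str, CorrelationProfile], ax=None, title=""):
    """Mean r per layer with IQR band, one line per pairing case."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for case, prof in profiles.items():
        y = [prof.mean_r[l] for l in prof.layers]
        lo = [prof.q25[l] for l in prof.layers]
        hi = [prof.q75[l] for l in prof.layers]
        ax.plot(prof.layers, y, marker="o", label=case)
        ax.fill_between(prof.layers, lo, hi, alpha=0.2)
    ax.set_ylabel("Pearson r")
    ax.set_ylim(-1, 1)
    ax.axhline(0, color="gray", lw=0.5)
    ax.legend(fontsize=7)
    if title:
        ax.set_title(title)
    return ax
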