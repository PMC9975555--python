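"""Image-manipulation operators used to build training and test stimuli.

All operators act on float arrays in ``[0, 1]`` with shape ``(H, W, 3)``
(single image) or ``(N, H, W, 3)`` (batch), preserve the array shape, and are
deterministic given their parameters (and seed, where one applies).

The Gaussian low-pass filter follows the convention that the kernel width is
tied to the standard deviation: ``k = round(8*sigma + 1)``, incremented by one
when even, so the kernel always has an odd width and covers ±4 sigma.
Band-pass images are differences of two low-pass images; tile manipulations
(jumbling, checkerboard gray occlusion) destroy global configuration while
preserving local content, or vice versa.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import correlate1d

__all__ = [
    "BlurSpec",
    "BandSpec",
    "TileSpec",
    "kernel_width",
    "make_gaussian_kernel",
    "lowpass",
    "bandpass",
    "bandpass_display",
    "tile_manipulate",
    "save_image_set",
]

#: Default gray level for occluded tiles (mid-gray).
GRAY_LEVEL = 0.5

#: Default border handling for the blur convolution.
BORDER_MODE = "reflect"


def kernel_width(sigma: float) -> int:
    """Odd kernel width ``k = round(8*sigma + 1)`` (round-half-up; +1 if even)."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    k = math.floor(8.0 * sigma + 1.0 + 0.5)  # round-half-up
    if k % 2 == 0:
        k += 1
    return max(k, 1)


@dataclass(frozen=True)
class BlurSpec:
    """Gaussian blur parameterized by its standard deviation in pixels.

    ``sigma = 0`` is the identity operator (1x1 kernel).
    """

    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")

    @property
    def kernel_width(self) -> int:
        return kernel_width(self.sigma)


@dataclass(frozen=True)
class BandSpec:
    """Spatial-frequency band isolated as ``lowpass(sigma_lo) - lowpass(sigma_hi)``.

    ``sigma_lo`` may be 0 (identity); the band then contains everything above
    the ``sigma_hi`` cut-off.
    """

    sigma_lo: float
    sigma_hi: float

    def __post_init__(self) -> None:
        if self.sigma_lo < 0:
            raise ValueError("sigma_lo must be non-negative")
        if not self.sigma_lo < self.sigma_hi:
            raise ValueError(
                f"invalid band: need sigma_lo < sigma_hi, got "
                f"({self.sigma_lo}, {self.sigma_hi})"
            )

    @property
    def name(self) -> str:
        def fmt(s: float) -> str:
            return f"{s:g}"

        return f"band {fmt(self.sigma_lo)}-{fmt(self.sigma_hi)}"


@dataclass(frozen=True)
class TileSpec:
    """Tile-grid manipulation: jumbling and/or checkerboard gray occlusion.

    grid : tiles per side (the image side must be divisible by it).
    mode : 'jumble', 'gray_occluder' or 'jumble_and_occluder'.
    permutation_seed : seed for the jumble permutation; tile (0, 0) of the
        checkerboard is always retained (not grayed) so results are
        reproducible.
    row_only : if True the jumble permutes tiles only within each row
        (horizontal scrambling); the default permutes over the full grid.
    """

    grid: int
    mode: str = "jumble"
    permutation_seed: int = 0
    gray: float = GRAY_LEVEL
    row_only: bool = False
    identity_permutation: bool = False  # debug flag: jumble becomes a no-op

    _MODES = ("jumble", "gray_occluder", "jumble_and_occluder")

    def __post_init__(self) -> None:
        if self.grid < 1:
            raise ValueError("grid must be a positive integer")
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}, got {self.mode!r}")


def _gaussian_kernel1d(sigma: float) -> np.ndarray:
    """Normalized 1-D Gaussian sampled at integer offsets over the odd width."""
    k = kernel_width(sigma)
    if sigma == 0 or k == 1:
        return np.ones(1, dtype=np.float64)
    r = (k - 1) // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def make_gaussian_kernel(spec: BlurSpec | float) -> np.ndarray:
    """2-D normalized Gaussian kernel of width ``k = round(8*sigma+1)`` (odd).

    The kernel is separable (outer product of the 1-D profile); ``sigma = 0``
    returns the 1x1 identity kernel. The sum is 1 to within 1e-12.
    """
    if not isinstance(spec, BlurSpec):
        spec = BlurSpec(float(spec))
    k1 = _gaussian_kernel1d(spec.sigma)
    return np.outer(k1, k1)


def _as_batch(img: np.ndarray) -> tuple[np.ndarray, bool]:
    if img.ndim == 3:
        return img[None], True
    if img.ndim == 4:
        return img, False
    raise ValueError(f"expected (H,W,C) or (N,H,W,C) array, got shape {img.shape}")


def lowpass(img: np.ndarray, spec: BlurSpec | float, mode: str = BORDER_MODE) -> np.ndarray:
    """Gaussian low-pass filter, applied per color channel.

    Uses the separable form of the 2-D kernel from :func:`make_gaussian_kernel`
    (mathematically identical, O(k) instead of O(k^2) per pixel). Border
    handling defaults to reflect padding and is configurable via ``mode``
    (any :func:`scipy.ndimage.correlate1d` mode).
    """
    if not isinstance(spec, BlurSpec):
        spec = BlurSpec(float(spec))
    batch, squeeze = _as_batch(np.asarray(img))
    if spec.sigma == 0:
        out = batch.copy()
    else:
        k1 = _gaussian_kernel1d(spec.sigma)
        out = correlate1d(batch.astype(np.float64, copy=False), k1, axis=1, mode=mode)
        out = correlate1d(out, k1, axis=2, mode=mode)
        out = np.clip(out, 0.0, 1.0).astype(batch.dtype, copy=False)
    return out[0] if squeeze else out


def bandpass(img: np.ndarray, band: BandSpec, mode: str = BORDER_MODE) -> np.ndarray:
    """Signed band-pass image ``lowpass(sigma_lo) - lowpass(sigma_hi)``.

    The result is *not* remapped to [0, 1]; use :func:`bandpass_display` for a
    displayable / model-ready version.
    """
    arr = np.asarray(img)
    lo = lowpass(arr.astype(np.float64, copy=False), BlurSpec(band.sigma_lo), mode=mode)
    hi = lowpass(arr.astype(np.float64, copy=False), BlurSpec(band.sigma_hi), mode=mode)
    return lo - hi


def bandpass_display(img: np.ndarray, band: BandSpec, mode: str = BORDER_MODE) -> np.ndarray:
    """Band-pass image remapped for display / model input: ``band + 0.5``, clipped.

    A zero band (e.g. from a constant image) maps to uniform mid-gray.
    """
    out = bandpass(img, band, mode=mode) + 0.5
    return np.clip(out, 0.0, 1.0).astype(np.asarray(img).dtype, copy=False)


def _checkerboard_mask(grid: int) -> np.ndarray:
    """Boolean (grid, grid) mask of tiles to gray out; tile (0,0) is retained."""
    i, j = np.meshgrid(np.arange(grid), np.arange(grid), indexing="ij")
    return (i + j) % 2 == 1


def _tile_permutation(grid: int, seed: int, row_only: bool) -> np.ndarray:
    """Flat permutation of the grid*grid tile indices."""
    rng = np.random.default_rng(seed)
    if row_only:
        perm = np.arange(grid * grid).reshape(grid, grid)
        for r in range(grid):
            perm[r] = perm[r][rng.permutation(grid)]
        return perm.ravel()
    return rng.permutation(grid * grid)


def tile_manipulate(img: np.ndarray, spec: TileSpec) -> np.ndarray:
    """Apply a tile-grid manipulation (jumble / gray occluder / both).

    Jumbling permutes tile positions (tile interiors untouched, so the pixel
    multiset is conserved); the gray occluder replaces the checkerboard tile
    set with uniform gray. The combined mode jumbles first, then occludes.
    The image side must be divisible by ``spec.grid``; anything else is an
    error — there is no silent resizing.
    """
    arr = np.asarray(img)
    batch, squeeze = _as_batch(arr)
    n, h, w, c = batch.shape
    g = spec.grid
    if h != w:
        raise ValueError(f"tile manipulation requires square images, got {h}x{w}")
    if h % g != 0:
        raise ValueError(f"image side {h} is not divisible by grid {g}")
    t = h // g
    # (N, gi, gj, t, t, C) view of the tile grid
    tiles = batch.reshape(n, g, t, g, t, c).transpose(0, 1, 3, 2, 4, 5).copy()

    if spec.mode in ("jumble", "jumble_and_occluder") and not spec.identity_permutation:
        perm = _tile_permutation(g, spec.permutation_seed, spec.row_only)
        flat = tiles.reshape(n, g * g, t, t, c)
        tiles = flat[:, perm].reshape(n, g, g, t, t, c)
    if spec.mode in ("gray_occluder", "jumble_and_occluder"):
        mask = _checkerboard_mask(g)
        tiles[:, mask] = spec.gray

    out = tiles.transpose(0, 1, 3, 2, 4, 5).reshape(n, h, w, c)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# provenance-carrying batch I/O (used by the CLI)

@dataclass
class StimulusProvenance:
    source_id: str
    op: str
    params: dict = field(default_factory=dict)


def save_image_set(out_dir: str | Path, images: np.ndarray, names: list[str],
                   provenance: list[StimulusProvenance] | None = None) -> None:
    """Write a batch of images as PNGs plus a JSON provenance sidecar."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for img, name in zip(images, names):
        u8 = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
        Image.fromarray(u8).save(out / f"{name}.png")
    if provenance is not None:
        side = [{"source_id": p.source_id, "op": p.op, **p.params} for p in provenance]
        (out / "provenance.json").write_text(json.dumps(side, indent=1))
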