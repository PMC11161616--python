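"""Image preprocessing: z-averaging, enhancement, segmentation, feature counts.

Confocal z-stacks are averaged along z into a single 2D grayscale frame,
enhanced by a fixed filter cascade — box filter, order-statistic filter,
global histogram equalization, self-guided edge-preserving smoothing — and
segmented with Otsu's global threshold.  The segmented (binary) image is used
for two things downstream: counting components and enclosed holes (which
calibrates the persistence-diagram noise threshold) and the box-counting
fractal dimension.

Connectivity convention: foreground components are 8-connected, background
holes 4-connected — the standard complementary pair, so a diagonal fiber
crossing cannot simultaneously connect the foreground and split a hole.
A background region touching the image border is never a hole (a void must
be enclosed by fibrin).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage import exposure, filters

__all__ = [
    "EnhanceConfig",
    "FeatureCounts",
    "z_average",
    "enhance",
    "guided_filter",
    "binarize",
    "count_features",
    "read_image",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


class FeatureCounts(NamedTuple):
    n_components: int
    n_holes: int


@dataclass(frozen=True)
class EnhanceConfig:
    """Enhancement cascade parameters.

    Window sizes are odd pixel counts (1 = identity).  ``rank=None`` selects
    the median of the order-statistic window.  ``guided_radius=0`` disables
    the guided filter; ``equalize=False`` skips histogram equalization.
    Defaults follow common practice for this cascade; the upstream image
    environment's exact values are not published, so every knob is explicit
    and overridable.
    """

    k_box: int = 3
    k_os: int = 3
    rank: int | None = None
    equalize: bool = True
    n_bins: int = 256
    guided_radius: int = 4
    guided_eps: float = 1e-4

    def validate(self) -> None:
        for name in ("k_box", "k_os"):
            k = getattr(self, name)
            if k < 1 or k % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1, got {k}")
        if self.rank is not None and not 0 <= self.rank < self.k_os**2:
            raise ValueError("rank must lie in [0, k_os**2)")
        if self.guided_radius < 0 or self.guided_eps <= 0:
            raise ValueError("invalid guided-filter parameters")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def _as_float01(img: np.ndarray, ndim: int) -> np.ndarray:
    a = np.asarray(img, dtype=float)
    if a.ndim != ndim:
        raise ValueError(f"expected a {ndim}D array, got shape {a.shape}")
    if a.size == 0 or not np.all(np.isfinite(a)):
        raise ValueError("image must be non-empty and finite")
    return a


def z_average(stack: np.ndarray) -> np.ndarray:
    """Mean projection over z, min-max rescaled to [0, 1].

    A constant stack maps to an all-zero image (degenerate rescale).
    """
    a = _as_float01(stack, 3)
    mean = a.mean(axis=0)
    lo, hi = mean.min(), mean.max()
    if hi == lo:
        return np.zeros_like(mean)
    return (mean - lo) / (hi - lo)


def guided_filter(img: np.ndarray, radius: int, eps: float) -> np.ndarray:
    """Self-guided filter (guide = image): edge-preserving smoothing.

    Box-filter formulation with window size 2*radius + 1; ``eps`` is the
    regularizer on the local variance (larger -> smoother).
    """
    if radius == 0:
        return np.asarray(img, dtype=float)
    size = 2 * radius + 1
    i = np.asarray(img, dtype=float)
    mean_i = ndimage.uniform_filter(i, size)
    var_i = ndimage.uniform_filter(i * i, size) - mean_i**2
    a = var_i / (var_i + eps)
    b = (1.0 - a) * mean_i
    return ndimage.uniform_filter(a, size) * i + ndimage.uniform_filter(b, size)


def enhance(img: np.ndarray, cfg: EnhanceConfig | None = None) -> np.ndarray:
    """Apply the enhancement cascade in fixed order.

    Box (mean) filter -> order-statistic filter -> histogram equalization ->
    guided filter; the output is clipped to [0, 1].  With every stage at its
    identity setting the input is returned unchanged.
    """
    cfg = cfg or EnhanceConfig()
    cfg.validate()
    a = _as_float01(img, 2)
    if cfg.k_box > 1:
        a = ndimage.uniform_filter(a, cfg.k_box)
    if cfg.k_os > 1:
        rank = cfg.rank if cfg.rank is not None else (cfg.k_os**2) // 2
        a = ndimage.rank_filter(a, rank, size=cfg.k_os)
    if cfg.equalize and a.max() > a.min():
        a = exposure.equalize_hist(a, nbins=cfg.n_bins)
    if cfg.guided_radius > 0:
        a = guided_filter(a, cfg.guided_radius, cfg.guided_eps)
    return np.clip(a, 0.0, 1.0)


def binarize(img: np.ndarray) -> np.ndarray:
    """Global Otsu segmentation; foreground = above-threshold (bright fibrin).

    A constant image has no contrast to threshold and yields an empty mask.
    """
    a = _as_float01(img, 2)
    if a.max() == a.min():
        return np.zeros(a.shape, dtype=bool)
    return a > filters.threshold_otsu(a, nbins=256)


def count_features(mask: np.ndarray) -> FeatureCounts:
    """Count 8-connected foreground components and enclosed 4-connected holes."""
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2D")
    n_comp = int(ndimage.label(m, structure=_STRUCT8)[1])
    bg_labels, n_bg = ndimage.label(~m, structure=_STRUCT4)
    border = np.unique(
        np.concatenate(
            [bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]]
        )
    )
    n_border = int(np.count_nonzero(border))  # label 0 is foreground
    return FeatureCounts(n_comp, n_bg - n_border)


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG as float in [0, 1]; multi-page TIFFs return a z-stack."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        a = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        a = iio.imread(path)
    a = np.asarray(a, dtype=float)
    if a.ndim == 3 and a.shape[-1] in (3, 4):  # RGB(A): luminance average
        a = a[..., :3].mean(axis=-1)
    if np.issubdtype(np.asarray(a).dtype, np.floating) and a.max() > 1.0:
        a = a / (65535.0 if a.max() > 255 else 255.0)
    return np.clip(a, 0.0, 1.0)
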