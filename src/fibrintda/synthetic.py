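"""Synthetic fluorescence-like fibrin-network images with known ground truth.

Real inputs to the pipeline are confocal micrographs of fluorescently labeled
fibrin: bright curvilinear fibers on a dark background, meshed into a
connected network that encloses voids.  No public image set accompanies the
method, so every downstream stage is exercised on images produced here, where
the noiseless binary mask — and therefore the true component and hole
structure — is known by construction.

Fibers are rasterized cubic Bezier curves with endpoints on the image border
(border-to-border fibers intersect each other, which is what creates holes,
mimicking the branch points of a polymerized network without modelling the
polymerization itself).  Isolated bright blobs add disconnected components.
The clean scene is blurred with a Gaussian point-spread function and
corrupted with additive Gaussian noise, as a spinning-disk confocal image
would be.

Condition archetypes mirror the two experimental contrasts the method was
designed to detect: dilution-like cohorts have fewer fibers/components at
unchanged thickness, thrombin-inhibition-like cohorts have thicker fibers and
fewer distinct features.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy import ndimage

__all__ = [
    "FiberFieldParams",
    "ConditionEffect",
    "SyntheticImage",
    "generate_fiber_image",
    "generate_cohort",
    "generate_phantom",
    "save_image",
    "CONDITIONS",
    "SMALL_STUDY",
]

PHANTOM_KINDS = (
    "filled_square",
    "line_segment",
    "ring",
    "checkerboard",
    "sierpinski_carpet",
    "radial_ramp",
)


@dataclass(frozen=True)
class FiberFieldParams:
    """Parameters of one synthetic fibrin field.

    ``fiber_thickness`` is the mean full width of a fiber in pixels,
    ``thickness_spread`` its standard deviation across fibers.  ``waviness``
    scales the random perpendicular displacement of the Bezier control points
    relative to the fiber's chord length (0 = straight fibers).
    """

    image_size: int = 256
    n_fibers: int = 60
    fiber_thickness: float = 2.5
    thickness_spread: float = 0.8
    waviness: float = 0.25
    n_isolated_blobs: int = 40
    background_level: float = 0.08
    fiber_level: float = 0.85
    noise_sigma: float = 0.04
    psf_sigma: float = 0.8
    seed: int = 0

    def scaled_to(self, image_size: int) -> "FiberFieldParams":
        """Rescale the field to another canvas size at constant appearance.

        Border-to-border fiber count and fragment count scale linearly with
        the side length (constant areal coverage for curves), fiber width
        scales with resolution (floored at 1 px).
        """
        s = image_size / self.image_size
        return replace(
            self,
            image_size=image_size,
            n_fibers=max(1, round(self.n_fibers * s)),
            n_isolated_blobs=max(1, round(self.n_isolated_blobs * s)),
            fiber_thickness=max(1.0, self.fiber_thickness * s),
            thickness_spread=self.thickness_spread * s,
        )

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        for name in ("background_level", "fiber_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fiber_level <= self.background_level:
            raise ValueError("fiber_level must exceed background_level")
        if self.n_fibers < 0 or self.n_isolated_blobs < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sigma < 0 or self.psf_sigma < 0:
            raise ValueError("noise_sigma and psf_sigma must be non-negative")
        if self.fiber_thickness <= 0:
            raise ValueError("fiber_thickness must be positive")


@dataclass(frozen=True)
class ConditionEffect:
    """Multiplicative treatment effect applied to a baseline fiber field.

    ``component_factor`` scales the number of fibers and isolated blobs
    (fewer fibers -> fewer components and distinct features);
    ``thickness_factor`` scales fiber width (thicker fibers -> coarser mesh).
    """

    component_factor: float = 1.0
    thickness_factor: float = 1.0
    label: str = "baseline"

    def validate(self) -> None:
        if self.component_factor <= 0 or self.thickness_factor <= 0:
            raise ValueError("effect factors must be positive")
        if self.label == "baseline" and (
            self.component_factor != 1.0 or self.thickness_factor != 1.0
        ):
            raise ValueError("baseline effect must have unit factors")


# Desk-scale study conditions for replicate-level simulations (power and
# type-I-error studies): a 64 px field dense enough to form a connected mesh
# with enclosed holes while keeping isolated fragments that carry the
# component count.  Chosen once to mirror, per unit area, the feature
# densities seen in segmented fibrin micrographs.
SMALL_STUDY = FiberFieldParams(
    image_size=64,
    n_fibers=8,
    fiber_thickness=1.5,
    thickness_spread=0.4,
    n_isolated_blobs=16,
    noise_sigma=0.04,
    psf_sigma=0.8,
)

CONDITIONS: dict[str, ConditionEffect] = {
    "baseline": ConditionEffect(1.0, 1.0, "baseline"),
    "dilution_like": ConditionEffect(0.5, 1.0, "dilution_like"),
    "inhibition_like": ConditionEffect(0.7, 1.8, "inhibition_like"),
}


class SyntheticImage(NamedTuple):
    """A generated grayscale image with its noiseless ground-truth mask."""

    image: np.ndarray
    mask: np.ndarray


# ---------------------------------------------------------------------------
# layout sampling and rasterization
# ---------------------------------------------------------------------------


def _border_point(rng: np.random.Generator, size: int) -> np.ndarray:
    t = rng.uniform(0, 4 * size)
    side, u = int(t // size), t % size
    if side == 0:
        return np.array([0.0, u])
    if side == 1:
        return np.array([size - 1.0, u])
    if side == 2:
        return np.array([u, 0.0])
    return np.array([u, size - 1.0])


def _sample_fiber(rng: np.random.Generator, size: int, waviness: float) -> np.ndarray:
    """Control points (4, 2) of a cubic Bezier spanning the image."""
    for _ in range(32):
        p0, p3 = _border_point(rng, size), _border_point(rng, size)
        chord = np.linalg.norm(p3 - p0)
        if chord >= 0.4 * size:
            break
    d = (p3 - p0) / max(chord, 1e-9)
    normal = np.array([-d[1], d[0]])
    c1 = p0 + d * chord / 3 + normal * rng.normal(0, waviness * chord)
    c2 = p0 + d * 2 * chord / 3 + normal * rng.normal(0, waviness * chord)
    return np.stack([p0, c1, c2, p3])


def _bezier_points(ctrl: np.ndarray, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, c1, c2, p3 = ctrl
    return (
        (1 - t) ** 3 * p0
        + 3 * (1 - t) ** 2 * t * c1
        + 3 * (1 - t) * t**2 * c2
        + t**3 * p3
    )


def _disk_offsets(radius: float) -> np.ndarray:
    r = max(int(math.ceil(radius)), 0)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = yy**2 + xx**2 <= radius**2
    return np.column_stack([yy[keep], xx[keep]])


def _stamp(mask: np.ndarray, pts: np.ndarray, radius: float) -> None:
    size = mask.shape[0]
    px = np.unique(np.round(pts).astype(int), axis=0)
    offs = _disk_offsets(radius)
    all_pts = (px[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    np.clip(all_pts, 0, size - 1, out=all_pts)
    mask[all_pts[:, 0], all_pts[:, 1]] = True


@dataclass
class _Layout:
    """Subject-level random geometry, independent of treatment and noise."""

    fibers: list[np.ndarray]  # control points
    thicknesses: np.ndarray  # per-fiber full width, baseline scale
    blobs: np.ndarray  # (n, 3): y, x, radius


def _sample_layout(
    rng: np.random.Generator, params: FiberFieldParams, n_fibers: int, n_blobs: int
) -> _Layout:
    size = params.image_size
    fibers = [_sample_fiber(rng, size, params.waviness) for _ in range(n_fibers)]
    thick = rng.normal(params.fiber_thickness, params.thickness_spread, size=n_fibers)
    thick = np.clip(thick, 1.0, None)
    blob_r = max(params.fiber_thickness, 1.5)
    # Blobs model disconnected bright fragments, so keep them clear of the
    # fiber mesh (clearance covers fibers rendered up to twice their nominal
    # width) and of each other; fall back to a free random spot if crowded.
    clearance = blob_r + 2.0 * params.fiber_thickness + 2.0
    occupied = np.zeros((size, size), dtype=bool)
    for ctrl in fibers:
        chord = np.linalg.norm(ctrl[-1] - ctrl[0])
        _stamp(occupied, _bezier_points(ctrl, max(int(3 * chord), 8)), clearance)
    centers: list[tuple[float, float]] = []
    margin = 2 * blob_r + 2
    for _ in range(n_blobs):
        placed = False
        for _attempt in range(200):
            y, x = rng.uniform(margin, size - margin, size=2)
            if occupied[int(round(y)), int(round(x))]:
                continue
            if all(
                (y - cy) ** 2 + (x - cx) ** 2 > (4 * blob_r + 2) ** 2
                for cy, cx in centers
            ):
                centers.append((y, x))
                placed = True
                break
        if not placed:  # crowded canvas: accept a possibly overlapping spot
            y, x = rng.uniform(margin, size - margin, size=2)
            centers.append((y, x))
    blobs = np.array([[y, x, blob_r] for y, x in centers]).reshape(-1, 3)
    return _Layout(fibers, thick, blobs)


def _render(
    layout: _Layout,
    params: FiberFieldParams,
    n_fibers: int,
    n_blobs: int,
    thickness_factor: float,
    noise_rng: np.random.Generator,
) -> SyntheticImage:
    size = params.image_size
    mask = np.zeros((size, size), dtype=bool)
    for ctrl, width in zip(layout.fibers[:n_fibers], layout.thicknesses[:n_fibers]):
        chord = np.linalg.norm(ctrl[-1] - ctrl[0])
        pts = _bezier_points(ctrl, max(int(3 * chord), 8))
        _stamp(mask, pts, width * thickness_factor / 2.0)
    for y, x, r in layout.blobs[:n_blobs]:
        _stamp(mask, np.array([[y, x]]), r)
    img = np.where(
        mask, params.fiber_level, params.background_level
    ).astype(float)
    if params.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, params.psf_sigma)
    if params.noise_sigma > 0:
        img = img + noise_rng.normal(0.0, params.noise_sigma, img.shape)
    return SyntheticImage(np.clip(img, 0.0, 1.0), mask)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def generate_fiber_image(params: FiberFieldParams) -> SyntheticImage:
    """Render one fibrin-like field; returns the image and its clean mask.

    Identical ``params`` (including ``seed``) give bit-identical output.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    layout_rng, noise_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    layout = _sample_layout(layout_rng, params, params.n_fibers, params.n_isolated_blobs)
    return _render(
        layout, params, params.n_fibers, params.n_isolated_blobs, 1.0, noise_rng
    )


def generate_cohort(
    base: FiberFieldParams,
    effect: ConditionEffect,
    n_subjects: int,
    seed: int,
) -> list[tuple[SyntheticImage, SyntheticImage]]:
    """Paired (baseline, treated) images for ``n_subjects`` subjects.

    Each subject's fiber layout is drawn once from a subject-level RNG stream
    and shared between arms; the treatment only rescales how many fibers/blobs
    are rendered (``component_factor``) and how thick they are
    (``thickness_factor``).  Noise is drawn from separate per-arm streams, so
    a null effect differs between arms only by noise — the paired design the
    downstream t-test assumes.
    """
    base.validate()
    effect.validate()
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    nf_treat = int(round(base.n_fibers * effect.component_factor))
    nb_treat = int(round(base.n_isolated_blobs * effect.component_factor))
    pairs = []
    for subj_ss in np.random.SeedSequence(seed).spawn(n_subjects):
        layout_ss, noise_b_ss, noise_t_ss = subj_ss.spawn(3)
        layout = _sample_layout(
            np.random.default_rng(layout_ss),
            base,
            max(base.n_fibers, nf_treat),
            max(base.n_isolated_blobs, nb_treat),
        )
        baseline = _render(
            layout, base, base.n_fibers, base.n_isolated_blobs, 1.0,
            np.random.default_rng(noise_b_ss),
        )
        treated = _render(
            layout, base, nf_treat, nb_treat, effect.thickness_factor,
            np.random.default_rng(noise_t_ss),
        )
        pairs.append((baseline, treated))
    return pairs


def generate_phantom(kind: str, size: int = 128) -> np.ndarray:
    """Deterministic test images with known topology / box-counting dimension.

    ``sierpinski_carpet`` requires ``size`` to be a power of 3 (>= 27); the
    other kinds accept any size >= 16.
    """
    if kind not in PHANTOM_KINDS:
        raise ValueError(f"unknown phantom kind: {kind!r}; choose from {PHANTOM_KINDS}")
    if kind == "sierpinski_carpet":
        depth = round(math.log(size, 3))
        if size < 27 or 3**depth != size:
            raise ValueError("sierpinski_carpet needs size = 3**k with k >= 3")
        idx = np.arange(size)
        carpet = np.ones((size, size), dtype=bool)
        for d in range(depth):
            digit = (idx // 3**d) % 3
            carpet &= ~((digit[:, None] == 1) & (digit[None, :] == 1))
        return carpet.astype(float)
    if size < 16:
        raise ValueError("phantom size must be >= 16")
    img = np.zeros((size, size), dtype=float)
    m = max(size // 16, 2)  # margin
    if kind == "filled_square":
        img[:, :] = 1.0  # plane-filling: the square is the full frame
    elif kind == "line_segment":
        img[size // 2, m:-m] = 1.0
    elif kind == "ring":
        yy, xx = np.mgrid[:size, :size] - (size - 1) / 2.0
        r = np.hypot(yy, xx)
        r_out = 0.35 * size
        img[(r <= r_out) & (r >= r_out - max(size // 32, 2))] = 1.0
    elif kind == "checkerboard":
        for i in range(0, size - 2, 4):
            for j in range(0, size - 2, 4):
                img[i : i + 2, j : j + 2] = 1.0
    elif kind == "radial_ramp":
        yy, xx = np.mgrid[:size, :size] - (size - 1) / 2.0
        r = np.hypot(yy, xx)
        img = r / r.max()
    return img


# ---------------------------------------------------------------------------
# I/O: 16-bit TIFF / 8-bit PNG with provenance sidecar
# ---------------------------------------------------------------------------


def save_image(
    img: np.ndarray,
    path: str | Path,
    params: FiberFieldParams | None = None,
    **extra_meta,
) -> None:
    """Write a [0,1] float image as 16-bit TIFF or 8-bit PNG (by extension),
    with a JSON sidecar recording generator parameters for provenance."""
    import imageio.v3 as iio
    import tifffile

    path = Path(path)
    a = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, (a * 65535).round().astype(np.uint16))
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, (a * 255).round().astype(np.uint8))
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    meta = dict(extra_meta)
    if params is not None:
        meta["params"] = asdict(params)
    if meta:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2, sort_keys=True)
        )


def scaled_params(base: FiberFieldParams, effect: ConditionEffect) -> FiberFieldParams:
    """Parameters of the treated arm implied by an effect (for provenance)."""
    return replace(
        base,
        n_fibers=int(round(base.n_fibers * effect.component_factor)),
        n_isolated_blobs=int(round(base.n_isolated_blobs * effect.component_factor)),
        fiber_thickness=base.fiber_thickness * effect.thickness_factor,
    )
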