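"""Seeded synthetic phantoms: gold segmentations, cue maps, superpixels.

These generators emulate the inputs of the agglomerative pipeline — a
gold-standard partition, a graded boundary-probability map, a region
"texture" cue channel, and a watershed oversegmentation — so the whole
training and evaluation stack is exercisable without any downloads.

Geometries:

* ``voronoi`` — a partition of the plane/volume into nearest-seed cells;
  compact, convex-ish regions of comparable size.
* ``tubes`` (3D only) — elongated processes spanning the full z extent with
  smoothly wandering cross-sections, mimicking the thin, tortuous shapes of
  neuronal processes.

The boundary cue is a blurred boundary indicator modulated by a smooth
random *strength field*: real membrane detectors produce graded confidence
that fades in and out along a boundary, and those weak stretches are what
make plain mean-boundary agglomeration err.  The texture cue assigns each
segment a random intensity level drawn from a narrow range and adds strong
pixel noise, so the level of a region is ambiguous at superpixel size but
sharply estimated once regions grow — the scale-dependent evidence that an
agglomerative training loop can exploit and flat training cannot.

A named "pinch" phantom (a process connected through a one-voxel neck) is
included because necks are where sum-based boundary features are weakest —
the dominant real-world failure mode of this family of methods.

All outputs are bit-reproducible given the spec: its seed fixes the
geometry and the strength field, and derived seeds ``seed + 1`` /
``seed + 2 + i`` fix the boundary and texture noise unless overridden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.segmentation import find_boundaries, watershed

from .errors import InputError

__all__ = [
    "PhantomSpec",
    "Phantom",
    "make_gold",
    "make_boundary_cue",
    "make_texture_cue",
    "make_superpixels",
    "make_phantom",
    "make_pinch_gold",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic phantom.

    ``superpixel_spacing`` is the minimum distance (in pixels) between
    watershed markers, i.e. the inverse of the seed density.
    ``boundary_strength`` is the (low, high) range of the smooth strength
    field modulating the boundary indicator; values are clipped to [0, 1],
    so a low end below 0 produces genuinely invisible boundary stretches.
    ``texture_levels`` is the range the per-segment texture intensities are
    drawn from.  Defaults are the study conditions used throughout the test
    suite: a 128x128 image with 12 segments, moderate cue noise, boundary
    strength fading smoothly over ~8-pixel stretches, and superpixels a few
    pixels wide so that segments sit several merge generations above them.
    """

    shape: tuple[int, ...] = (128, 128)
    n_segments: int = 12
    geometry: str = "voronoi"
    blur_sigma: float = 1.0
    noise_sd: float = 0.1
    boundary_strength: tuple[float, float] = (0.1, 1.1)
    strength_corr_length: float = 8.0
    texture_levels: tuple[float, float] = (0.35, 0.65)
    texture_noise_sd: float = 0.25
    superpixel_spacing: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_segments < 2:
            raise InputError("need at least 2 segments")
        if int(np.prod(self.shape)) < self.n_segments:
            raise InputError("more segments than pixels")
        if len(self.shape) not in (2, 3):
            raise InputError("shape must be 2D or 3D")
        if self.geometry not in ("voronoi", "tubes"):
            raise InputError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "tubes" and len(self.shape) != 3:
            raise InputError("tubes geometry is 3D only")
        if min(self.blur_sigma, self.noise_sd) < 0 or self.superpixel_spacing <= 0:
            raise InputError("blur/noise/spacing parameters must be non-negative")


@dataclass
class Phantom:
    gold: np.ndarray
    cues: list[np.ndarray]
    superpixels: np.ndarray
    spec: PhantomSpec


def make_gold(spec: PhantomSpec) -> np.ndarray:
    """Deterministic gold-standard partition into connected segments."""
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "voronoi":
        return _voronoi_gold(spec, rng)
    return _tubes_gold(spec, rng)


def _voronoi_gold(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n_pixels = int(np.prod(spec.shape))
    flat_seeds = rng.choice(n_pixels, size=spec.n_segments, replace=False)
    seeds = np.stack(np.unravel_index(flat_seeds, spec.shape), axis=1)
    grid = np.stack(
        np.meshgrid(*[np.arange(s) for s in spec.shape], indexing="ij"), axis=-1
    ).reshape(-1, len(spec.shape))
    _, nearest = cKDTree(seeds).query(grid)
    return (nearest + 1).reshape(spec.shape).astype(np.int32)


def _tubes_gold(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    # tubes start on a jittered grid and wander smoothly with an amplitude
    # below half the grid spacing, so trajectories never cross and every
    # nearest-tube cell stays connected through z
    nz, ny, nx = spec.shape
    n = spec.n_segments
    side = int(np.ceil(np.sqrt(n)))
    cell_y, cell_x = ny / side, nx / side
    cells = rng.permutation(side * side)[:n]
    base = np.stack(
        [
            (cells // side + 0.5) * cell_y + rng.uniform(-cell_y / 6, cell_y / 6, n),
            (cells % side + 0.5) * cell_x + rng.uniform(-cell_x / 6, cell_x / 6, n),
        ],
        axis=1,
    )
    z = np.arange(nz)[:, None, None]
    amp = rng.uniform(0.1, 0.3, size=(1, n, 2)) * np.array([cell_y, cell_x])
    freq = rng.uniform(1.0, 2.5, size=(1, n, 2))
    phase = rng.uniform(0, 2 * np.pi, size=(1, n, 2))
    centers = base[None, :, :] + amp * np.sin(2 * np.pi * freq * z / nz + phase)
    centers[..., 0] = np.clip(centers[..., 0], 0, ny - 1)
    centers[..., 1] = np.clip(centers[..., 1], 0, nx - 1)
    gold = np.empty(spec.shape, dtype=np.int32)
    grid = np.stack(
        np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij"), axis=-1
    ).reshape(-1, 2)
    for z in range(nz):
        _, nearest = cKDTree(centers[z]).query(grid)
        gold[z] = (nearest + 1).reshape(ny, nx)
    return gold


def _strength_field(spec: PhantomSpec) -> np.ndarray:
    """Smooth random boundary-strength field in ``boundary_strength`` range.

    Part of the underlying ridge (seeded by the spec, not the noise seed).
    """
    lo, hi = spec.boundary_strength
    if lo == hi:
        return np.full(spec.shape, np.clip(lo, 0.0, 1.0))
    rng = np.random.default_rng(spec.seed + 7)
    field = gaussian_filter(rng.normal(0.0, 1.0, spec.shape), spec.strength_corr_length)
    field = (field - field.mean()) / field.std()
    return np.clip(0.5 * (lo + hi) + 0.5 * (hi - lo) * field, 0.0, 1.0)


def make_boundary_cue(
    gold: np.ndarray, spec: PhantomSpec, seed: int | None = None
) -> np.ndarray:
    """Strength-modulated, blurred boundary indicator plus clipped noise.

    At ``noise_sd == 0`` the cue is exactly the blurred (modulated)
    indicator; with the strength field disabled
    (``boundary_strength=(1, 1)``) its ridge of maxima coincides with the
    gold boundaries.  The ``seed`` argument re-draws only the additive
    noise; geometry and strength stay fixed by the spec.
    """
    indicator = find_boundaries(gold, mode="thick").astype(np.float64)
    cue = gaussian_filter(indicator * _strength_field(spec), spec.blur_sigma)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
        cue = cue + rng.normal(0.0, spec.noise_sd, size=cue.shape)
    return np.clip(cue, 0.0, 1.0)


def make_texture_cue(
    gold: np.ndarray, spec: PhantomSpec, seed: int | None = None
) -> np.ndarray:
    """Per-segment random intensity plus strong noise (a cytoplasm stand-in).

    The narrow level range and high noise make region identity ambiguous at
    superpixel size but well-estimated for larger regions.
    """
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    lo, hi = spec.texture_levels
    levels = rng.uniform(lo, hi, size=int(gold.max()) + 1)
    cue = levels[gold]
    if spec.texture_noise_sd > 0:
        cue = cue + rng.normal(0.0, spec.texture_noise_sd, size=cue.shape)
    return np.clip(cue, 0.0, 1.0)


def make_superpixels(cue: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Seeded-watershed oversegmentation of a boundary cue.

    Markers are local minima of the lightly smoothed cue, at least
    ``superpixel_spacing`` apart; each basin is one connected superpixel and
    every pixel is assigned (labels start at 1, no watershed lines).
    """
    smooth = gaussian_filter(cue, 1.0)
    coords = peak_local_max(
        smooth.max() - smooth,
        min_distance=spec.superpixel_spacing,
        exclude_border=False,
    )
    markers = np.zeros(cue.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    return watershed(smooth, markers).astype(np.int32)


def make_phantom(spec: PhantomSpec, n_texture_cues: int = 1) -> Phantom:
    """Gold, cue channels (boundary first), and watershed superpixels."""
    gold = make_gold(spec)
    cues = [make_boundary_cue(gold, spec)]
    for i in range(n_texture_cues):
        cues.append(make_texture_cue(gold, spec, seed=spec.seed + 2 + i))
    superpixels = make_superpixels(cues[0], spec)
    return Phantom(gold=gold, cues=cues, superpixels=superpixels, spec=spec)


def make_pinch_gold(shape: tuple[int, int, int] = (24, 24, 24)) -> np.ndarray:
    """3D two-segment phantom where segment 2 has a one-voxel neck.

    Segment 2 is a dumbbell: two blocks joined by a single-voxel channel in
    z; segment 1 is everything else.  Useful for probing the neck ("pinch")
    failure mode, where boundary evidence between the halves is scarce.
    """
    nz, ny, nx = shape
    if min(shape) < 9:
        raise InputError("pinch phantom needs at least 9 voxels per axis")
    gold = np.ones(shape, dtype=np.int32)
    cy, cx = ny // 2, nx // 2
    lobe = max(2, min(ny, nx) // 4)
    zmid = nz // 2
    gold[: zmid - 1, cy - lobe : cy + lobe, cx - lobe : cx + lobe] = 2
    gold[zmid + 2 :, cy - lobe : cy + lobe, cx - lobe : cx + lobe] = 2
    gold[zmid - 1 : zmid + 2, cy, cx] = 2  # the one-voxel neck
    return gold
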