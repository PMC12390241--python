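"""Numerical resolution phantom with partial-volume edges.

The phantom emulates small structures embedded in a solution-filled container:
the solution signal is 1, the exterior background and the structure interiors
are 0. Partial-volume effects at structure boundaries are produced by
rasterizing on a ``supersample``-times finer grid and block-averaging down to
the final matrix, so edge pixels take fractional values in [0, 1].

Pixel coordinates are continuous, with the center of final-grid pixel (r, c)
at coordinate (r, c). Circles include boundary points (ties -> inside);
squares use half-open intervals so integer-aligned edges rasterize exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .errors import ConfigurationError, GeometryError

__all__ = [
    "StructureSpec",
    "ROI",
    "Phantom",
    "default_structures",
    "generate_phantom",
    "default_rois",
    "make_phantom_with_rois",
]

# Margin rules, in final-grid pixels.
IMAGE_MARGIN = 2.0       # structure bounding box to image edge
PAIR_GAP = 4.0           # minimum gap between structures
SOLUTION_MARGIN = 4.0    # structure bounding box to the solution-region edge

#: Side of the solution container as a fraction of the field of view.
SOLUTION_FRACTION = 0.72


@dataclass(frozen=True)
class StructureSpec:
    """One embedded structure: a circle (``size`` = diameter) or a square
    (``size`` = side), centered at continuous pixel coordinates (row, col)."""

    shape: str
    size: float
    center: tuple[float, float]

    def __post_init__(self):
        if self.shape not in ("circle", "square"):
            raise GeometryError(f"unknown structure shape {self.shape!r}")
        if self.size <= 0:
            raise GeometryError(f"structure size must be > 0, got {self.size}")

    @property
    def half(self) -> float:
        return self.size / 2.0

    def bbox(self) -> tuple[float, float, float, float]:
        """(rmin, rmax, cmin, cmax) in continuous pixel coordinates."""
        r, c = self.center
        h = self.half
        return (r - h, r + h, c - h, c + h)


@dataclass(frozen=True)
class ROI:
    """Rectangular pixel region: rows [row, row+height), cols [col, col+width)."""

    row: int
    col: int
    height: int
    width: int

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row, self.row + self.height),
                slice(self.col, self.col + self.width))


@dataclass
class Phantom:
    """Ideal image W plus the geometry it was generated from.

    ``image`` is the block-averaged rasterization (values in [0, 1]);
    ``solution_fraction_map`` is the block-averaged solution-container mask
    before structures are cut out, used to distinguish exterior background
    (value 0 outside the container) from structure interiors (value 0 inside).
    """

    image: np.ndarray
    n: int
    supersample: int
    structures: list[StructureSpec]
    solution_center: tuple[float, float]
    solution_side: float
    solution_fraction_map: np.ndarray
    signal_roi: ROI | None = None
    background_roi: ROI | None = None

    def structure_window(self, spec: StructureSpec, scale: float = 2.0) -> ROI:
        """Square fitting window of side ``scale`` x structure size, centered
        on the structure and clipped to the image."""
        side = max(4, int(round(scale * spec.size)))
        r0 = int(round(spec.center[0] - side / 2))
        c0 = int(round(spec.center[1] - side / 2))
        r0 = min(max(r0, 0), self.n - side)
        c0 = min(max(c0, 0), self.n - side)
        return ROI(r0, c0, side, side)

    def find_structure(self, shape: str, size: float) -> StructureSpec:
        for s in self.structures:
            if s.shape == shape and math.isclose(s.size, size):
                return s
        raise KeyError(f"phantom has no {shape} of size {size}")


# Frozen default layouts. Centers are stored as fractions of the image side n;
# sizes are absolute pixels (the structures probe resolution in pixel units).
# The 9-structure layout mirrors the standard design: circles of diameter
# 2..40 px plus one 50-px square inside a centered solution container. Below
# n = 384 the two largest structures cannot satisfy the gap invariants, so
# reduced layouts (which keep the representative 20-px circle) are used.
_LAYOUT_FULL = [  # base n = 512
    ("circle", 2, (130, 120)), ("circle", 4, (130, 160)),
    ("circle", 6, (130, 200)), ("circle", 8, (130, 240)),
    ("circle", 10, (130, 290)), ("circle", 20, (220, 140)),
    ("circle", 30, (230, 260)), ("circle", 40, (330, 150)),
    ("square", 50, (340, 330)),
]
_LAYOUT_COMPACT = [  # base n = 128
    ("circle", 2, (28, 26)), ("circle", 4, (28, 40)),
    ("circle", 6, (28, 56)), ("circle", 8, (28, 74)),
    ("circle", 10, (28, 94)), ("circle", 20, (58, 36)),
    ("circle", 30, (50, 66)),
]
_LAYOUT_MICRO = [  # base n = 64
    ("circle", 2, (48, 42)), ("circle", 4, (38, 46)),
    ("circle", 6, (20, 46)), ("circle", 8, (20, 34)),
    ("circle", 10, (20, 18)), ("circle", 20, (40, 26)),
]


def default_structures(n: int) -> list[StructureSpec]:
    """Frozen default structure layout for an n x n phantom."""
    if n >= 384:
        layout, base = _LAYOUT_FULL, 512
    elif n >= 128:
        layout, base = _LAYOUT_COMPACT, 128
    elif n >= 64:
        layout, base = _LAYOUT_MICRO, 64
    else:
        raise GeometryError(f"no default layout for n={n} (need n >= 64)")
    f = n / base
    return [StructureSpec(shape, size, (r * f, c * f))
            for shape, size, (r, c) in layout]


def _pair_gap(a: StructureSpec, b: StructureSpec) -> float:
    """Minimum Euclidean gap between two structure boundaries (>=0 if disjoint)."""
    if a.shape == "circle" and b.shape == "circle":
        d = math.dist(a.center, b.center)
        return d - a.half - b.half
    if a.shape == "square" and b.shape == "square":
        gr = abs(a.center[0] - b.center[0]) - a.half - b.half
        gc = abs(a.center[1] - b.center[1]) - a.half - b.half
        return math.hypot(max(gr, 0.0), max(gc, 0.0)) if (gr > 0 or gc > 0) \
            else max(gr, gc)
    circ, sq = (a, b) if a.shape == "circle" else (b, a)
    dr = max(abs(circ.center[0] - sq.center[0]) - sq.half, 0.0)
    dc = max(abs(circ.center[1] - sq.center[1]) - sq.half, 0.0)
    return math.hypot(dr, dc) - circ.half


def _validate_geometry(n: int, structures: list[StructureSpec],
                       sol_center: tuple[float, float], sol_side: float) -> None:
    for s in structures:
        rmin, rmax, cmin, cmax = s.bbox()
        if (rmin < IMAGE_MARGIN or cmin < IMAGE_MARGIN
                or rmax > n - 1 - IMAGE_MARGIN or cmax > n - 1 - IMAGE_MARGIN):
            raise GeometryError(
                f"structure {s} extends outside the image "
                f"(need >= {IMAGE_MARGIN} px margin on an n={n} grid)")
        sh = sol_side / 2
        if (rmin < sol_center[0] - sh + SOLUTION_MARGIN
                or rmax > sol_center[0] + sh - SOLUTION_MARGIN
                or cmin < sol_center[1] - sh + SOLUTION_MARGIN
                or cmax > sol_center[1] + sh - SOLUTION_MARGIN):
            raise GeometryError(
                f"structure {s} is not inside the solution region "
                f"(side {sol_side:.1f}, margin {SOLUTION_MARGIN} px)")
    for i, a in enumerate(structures):
        for b in structures[i + 1:]:
            gap = _pair_gap(a, b)
            if gap < PAIR_GAP:
                raise GeometryError(
                    f"structures {a} and {b} are too close (gap {gap:.2f} px, "
                    f"need >= {PAIR_GAP})")


def _interval_mask(coords: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # half-open [lo, hi): integer-aligned square edges rasterize exactly
    return (coords >= lo) & (coords < hi)


def _rasterize(n: int, supersample: int, structures: list[StructureSpec],
               sol_center: tuple[float, float], sol_side: float):
    s = supersample
    m = n * s
    # supersampled pixel centers, in final-grid coordinates
    coords = (np.arange(m) + 0.5) / s - 0.5
    sh = sol_side / 2
    sol_r = _interval_mask(coords, sol_center[0] - sh, sol_center[0] + sh)
    sol_c = _interval_mask(coords, sol_center[1] - sh, sol_center[1] + sh)
    solution = np.logical_and.outer(sol_r, sol_c)

    occupied = np.zeros((m, m), dtype=bool)
    for spec in structures:
        rmin, rmax, cmin, cmax = spec.bbox()
        i0 = max(int((rmin - 0.5) * s) - 1, 0)
        i1 = min(int((rmax + 0.5) * s) + 2, m)
        j0 = max(int((cmin - 0.5) * s) - 1, 0)
        j1 = min(int((cmax + 0.5) * s) + 2, m)
        rs = coords[i0:i1, None]
        cs = coords[None, j0:j1]
        if spec.shape == "circle":
            inside = (rs - spec.center[0]) ** 2 + (cs - spec.center[1]) ** 2 \
                <= spec.half ** 2
        else:
            inside = (_interval_mask(rs, spec.center[0] - spec.half,
                                     spec.center[0] + spec.half)
                      & _interval_mask(cs, spec.center[1] - spec.half,
                                       spec.center[1] + spec.half))
        occupied[i0:i1, j0:j1] |= inside

    def block_avg(mask: np.ndarray) -> np.ndarray:
        return mask.reshape(n, s, n, s).mean(axis=(1, 3))

    image = block_avg(solution & ~occupied)
    sol_frac = block_avg(solution)
    return image, sol_frac


def generate_phantom(n: int, supersample: int,
                     structures="paper-default") -> Phantom:
    """Generate the partial-volume phantom.

    Parameters
    ----------
    n : final image side in pixels (>= 64).
    supersample : integer rasterization oversampling factor (>= 1). The
        intermediate grid has side ``n * supersample``; the final image is the
        block average over ``supersample x supersample`` blocks.
    structures : explicit list of :class:`StructureSpec`, or the string
        ``"paper-default"`` for the frozen default layout at this n.
    """
    if n < 64:
        raise GeometryError(f"n must be >= 64, got {n}")
    if supersample < 1:
        raise GeometryError(f"supersample must be >= 1, got {supersample}")
    if isinstance(structures, str):
        if structures != "paper-default":
            raise ConfigurationError(f"unknown layout name {structures!r}")
        structures = default_structures(n)
    structures = list(structures)
    sol_center = ((n - 1) / 2.0, (n - 1) / 2.0)
    sol_side = SOLUTION_FRACTION * n
    _validate_geometry(n, structures, sol_center, sol_side)
    image, sol_frac = _rasterize(n, supersample, structures,
                                 sol_center, sol_side)
    return Phantom(image=image, n=n, supersample=supersample,
                   structures=structures, solution_center=sol_center,
                   solution_side=sol_side, solution_fraction_map=sol_frac)


def _best_box(eligible: np.ndarray, roi_side: int) -> ROI | None:
    """Top-left corner of the roi_side box fully inside ``eligible`` whose
    center is farthest from any ineligible pixel; None if no box fits."""
    n = eligible.shape[0]
    if roi_side > n:
        return None
    windows = sliding_window_view(eligible, (roi_side, roi_side))
    valid = windows.all(axis=(2, 3))
    if not valid.any():
        return None
    dist = ndimage.distance_transform_edt(eligible)
    h = roi_side // 2
    centers = dist[h:h + valid.shape[0], h:h + valid.shape[1]]
    score = np.where(valid, centers, -1.0)
    r0, c0 = np.unravel_index(int(np.argmax(score)), score.shape)
    return ROI(int(r0), int(c0), roi_side, roi_side)


def default_rois(phantom: Phantom, roi_side: int = 32) -> tuple[ROI, ROI]:
    """Place the SNR-measurement ROIs: one solution-interior box (all pixels
    exactly 1 in the noise-free image) and one exterior-background box (all
    pixels 0 and outside the solution container), each maximally distant from
    the nearest edge."""
    if roi_side < 8:
        raise ConfigurationError(f"roi_side must be >= 8, got {roi_side}")
    signal = _best_box(phantom.image == 1.0, roi_side)
    if signal is None:
        raise ConfigurationError(
            f"no {roi_side}x{roi_side} all-solution region exists")
    background = _best_box(phantom.solution_fraction_map == 0.0, roi_side)
    if background is None:
        raise ConfigurationError(
            f"no {roi_side}x{roi_side} exterior-background region exists")
    return signal, background


def make_phantom_with_rois(n: int = 512, supersample: int = 8,
                           structures="paper-default",
                           roi_side: int = 32) -> Phantom:
    """Convenience constructor: phantom plus default ROIs attached."""
    ph = generate_phantom(n, supersample, structures)
    sig, bg = default_rois(ph, roi_side)
    return replace(ph, signal_roi=sig, background_roi=bg)
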