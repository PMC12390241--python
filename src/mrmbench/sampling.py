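"""Variable-density Cartesian undersampling masks.

All patterns fully sample a central calibration disk (default radius 30 index
units around DC) and draw the remaining budget without replacement from the
outside-disk points according to a density rho:

- pattern 1: uniform,
- patterns 2 and 3: Gaussian, rho ∝ exp(-(kx^2 + ky^2) / (2 sigma_s^2)) with
  (kx, ky) normalized so k_max = 1 along each axis; sigma_s = 2 (pattern 2,
  more center-weighted) and sigma_s = 4 (pattern 3, flatter).

The acquired-point count is exactly round(N^2 / AF), with the calibration
disk counted toward the budget, so the acceleration factor equals the true
scan-time reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleAFError

__all__ = ["SamplingMask", "make_sampling_mask", "achieved_af",
           "PATTERN_SIGMAS", "DEFAULT_CENTER_RADIUS"]

DEFAULT_CENTER_RADIUS = 30.0
PATTERN_SIGMAS = {1: None, 2: 2.0, 3: 4.0}


@dataclass
class SamplingMask:
    """Boolean acquisition mask (True = acquired) with its provenance."""

    mask: np.ndarray
    pattern: int
    af: float
    center_radius: float
    sigma_s: float | None
    seed: int | None

    @property
    def n(self) -> int:
        return self.mask.shape[0]

    @property
    def n_acquired(self) -> int:
        return int(self.mask.sum())

    def signature(self) -> int:
        import zlib
        return zlib.crc32(np.packbits(self.mask).tobytes())


def _radii(n: int) -> np.ndarray:
    c = n // 2
    idx = np.arange(n) - c
    return np.hypot(idx[:, None], idx[None, :])


def make_sampling_mask(n: int, af: float, pattern: int,
                       center_radius: float = DEFAULT_CENTER_RADIUS,
                       sigma_s: float | None = None,
                       seed: int | None = 0) -> SamplingMask:
    """Draw an acquisition mask with exact budget round(n^2 / af)."""
    if pattern not in (1, 2, 3):
        raise ValueError(f"pattern must be 1, 2 or 3, got {pattern}")
    if af < 1:
        raise ValueError(f"af must be >= 1, got {af}")
    if sigma_s is None:
        sigma_s = PATTERN_SIGMAS[pattern]

    total = int(round(n * n / af))
    rr = _radii(n)
    disk = rr <= center_radius
    n_disk = int(disk.sum())
    if total < n_disk:
        max_af = n * n / n_disk
        raise InfeasibleAFError(
            f"budget round(n^2/af) = {total} is smaller than the fully "
            f"sampled calibration disk ({n_disk} points); maximum feasible "
            f"AF is {max_af:.2f}", max_feasible_af=max_af)

    mask = disk.copy()
    budget = total - n_disk
    outside = np.flatnonzero(~disk.ravel())
    if budget > len(outside):
        budget = len(outside)  # af == 1 (or nearly): take everything
    if budget > 0:
        rng = np.random.default_rng(seed)
        if pattern == 1:
            chosen = rng.choice(outside, size=budget, replace=False)
        else:
            c = n // 2
            idx = (np.arange(n) - c) / (n / 2.0)  # k in [-1, 1) per axis
            k2 = idx[:, None] ** 2 + idx[None, :] ** 2
            logrho = (-k2.ravel()[outside]) / (2.0 * sigma_s ** 2)
            # Gumbel top-k = weighted sampling without replacement
            keys = logrho + rng.gumbel(size=len(outside))
            chosen = outside[np.argpartition(-keys, budget - 1)[:budget]]
        mask.ravel()[chosen] = True

    assert int(mask.sum()) == total
    return SamplingMask(mask=mask, pattern=pattern, af=af,
                        center_radius=center_radius,
                        sigma_s=None if pattern == 1 else sigma_s, seed=seed)


def achieved_af(mask: SamplingMask) -> float:
    """N^2 over the number of acquired points."""
    count = mask.n_acquired
    if count == 0:
        raise ValueError("mask acquires no points")
    return mask.n ** 2 / count
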