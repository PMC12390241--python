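"""Aggregation of resolution estimates and the lower SNR limit SNR_L.

The estimated resolution beta rises as SNR falls. SNR_L is the SNR at which
the mean beta-versus-SNR curve crosses the voxel-size threshold (1 pixel by
default), found by linear interpolation; below SNR_L the nominal resolution
is no longer preserved. Because SNR_L is a guarantee threshold, the crossing
used is the highest-SNR downward crossing, so beta <= threshold holds for
every larger SNR on the grid. If beta exceeds the threshold even at the top
of the grid the limit is undefined ("NA"); if beta is below the threshold
everywhere the limit lies at or below the smallest grid value ("<=min-grid").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["SNRLCurve", "compute_snr_l", "aggregate_trials"]

NA = "NA"
BELOW_GRID = "<=min-grid"


@dataclass
class SNRLCurve:
    """Per-SNR beta statistics over trials, and the interpolated SNR_L."""

    snr_grid: np.ndarray
    beta_mean: np.ndarray
    beta_var: np.ndarray
    n_trials: np.ndarray
    snr_l: float | str
    voxel_size: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snr": self.snr_grid, "beta_mean": self.beta_mean,
                             "beta_var": self.beta_var,
                             "n_trials": self.n_trials})


def compute_snr_l(snr_grid, beta_means, threshold: float = 1.0):
    """Linear interpolation of the beta-vs-SNR curve at ``threshold``.

    Returns a float, ``"NA"`` (no crossing: beta above threshold at the top
    of the grid), or ``"<=min-grid"`` (beta at or below threshold
    everywhere).
    """
    g = np.asarray(snr_grid, dtype=float)
    b = np.asarray(beta_means, dtype=float)
    if g.shape != b.shape or g.ndim != 1 or len(g) < 2:
        raise ValueError(
            f"snr_grid and beta_means must be equal-length 1-D (>=2), "
            f"got {g.shape} and {b.shape}")
    if not np.all(np.diff(g) > 0):
        raise ValueError("snr_grid must be strictly ascending")
    if not np.all(np.isfinite(b)):
        raise ValueError("beta means must be finite")
    if b[-1] > threshold:
        return NA
    above = np.flatnonzero(b > threshold)
    if len(above) == 0:
        return BELOW_GRID
    i = int(above[-1])  # highest-SNR downward crossing
    frac = (b[i] - threshold) / (b[i] - b[i + 1])
    return float(g[i] + frac * (g[i + 1] - g[i]))


def aggregate_trials(per_trial_betas: dict, snr_grid,
                     threshold: float = 1.0) -> SNRLCurve:
    """Mean and population variance of beta per SNR level, plus SNR_L.

    ``per_trial_betas`` maps each SNR in ``snr_grid`` to its sequence of
    per-trial beta estimates (>= 1 each).
    """
    g = np.asarray(snr_grid, dtype=float)
    missing = [s for s in g if s not in per_trial_betas
               or len(per_trial_betas[s]) == 0]
    if missing:
        raise ConfigurationError(f"missing trials for SNR levels {missing}")
    means = np.array([np.mean(per_trial_betas[s]) for s in g])
    varis = np.array([np.var(per_trial_betas[s]) for s in g])  # population
    ns = np.array([len(per_trial_betas[s]) for s in g])
    snr_l = compute_snr_l(g, means, threshold)
    return SNRLCurve(snr_grid=g, beta_mean=means, beta_var=varis,
                     n_trials=ns, snr_l=snr_l, voxel_size=threshold)
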