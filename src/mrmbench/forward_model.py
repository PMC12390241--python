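"""Centered unitary Fourier encoding, noise injection, and SNR measurement.

The 2-D DFT is unitary (``norm="ortho"``) and centered: the DC coefficient
sits at index (N/2, N/2) for even N. Under this normalization, i.i.d. complex
Gaussian noise of per-channel standard deviation sigma added in k-space
appears in the image domain with the same per-channel sigma, so calibrating
noise to a target image SNR has the closed form sigma_k = S_target / SNR.

SNR is always measured on a magnitude image with the Rayleigh correction
``SNR = sqrt(2 - pi/2) * mean(signal ROI) / std(background ROI)``: the
background of a magnitude image is Rayleigh distributed with standard
deviation sigma * sqrt(2 - pi/2), so the corrected ratio recovers S/sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError
from .phantom import ROI, Phantom

__all__ = [
    "RAYLEIGH_CORRECTION",
    "KSpaceSample",
    "image_to_kspace",
    "kspace_to_image",
    "measure_snr",
    "add_noise_for_target_snr",
]

RAYLEIGH_CORRECTION = math.sqrt(2.0 - math.pi / 2.0)


@dataclass
class KSpaceSample:
    """Centered complex k-space grid with its calibrated noise level."""

    data: np.ndarray
    noise_sigma: float
    target_snr: float  # np.inf for the noise-free case
    seed: int | None

    @property
    def n(self) -> int:
        return self.data.shape[0]


def _check_square(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square 2-D array, got shape {a.shape}")
    return a


def image_to_kspace(image: np.ndarray) -> np.ndarray:
    """Unitary centered 2-D DFT; Parseval-preserving."""
    image = _check_square(image)
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image), norm="ortho"))


def kspace_to_image(kspace: np.ndarray) -> np.ndarray:
    """Inverse of :func:`image_to_kspace`."""
    kspace = _check_square(kspace)
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(kspace), norm="ortho"))


def _roi_slices(roi) -> tuple[slice, slice]:
    if isinstance(roi, ROI):
        return roi.slices
    return tuple(roi)


def measure_snr(magnitude_image: np.ndarray, signal_roi, background_roi) -> float:
    """Rayleigh-corrected SNR of a magnitude image (Eq. above)."""
    mag = np.asarray(magnitude_image)
    sig = mag[_roi_slices(signal_roi)]
    bg = mag[_roi_slices(background_roi)]
    if sig.size == 0 or bg.size == 0:
        raise ValueError("SNR ROIs must be non-empty")
    sd = float(np.std(bg))
    if sd == 0.0:
        raise DegenerateInputError(
            "background standard deviation is zero (noise-free image)")
    return RAYLEIGH_CORRECTION * float(np.mean(sig)) / sd


def add_noise_for_target_snr(kspace, target_snr, phantom: Phantom,
                             seed: int | None = 0) -> KSpaceSample:
    """Add i.i.d. complex Gaussian k-space noise calibrated to a target image
    SNR. ``target_snr`` may be a positive number, ``"infinite"`` or ``inf``
    (no noise added; data returned bit-identical)."""
    data = np.asarray(kspace.data if isinstance(kspace, KSpaceSample) else kspace)
    _check_square(data)
    if isinstance(target_snr, str):
        if target_snr != "infinite":
            raise ValueError(f"unknown target_snr {target_snr!r}")
        target_snr = np.inf
    target_snr = float(target_snr)
    if np.isinf(target_snr):
        return KSpaceSample(data=data.copy(), noise_sigma=0.0,
                            target_snr=np.inf, seed=seed)
    if target_snr <= 0:
        raise ValueError(f"target_snr must be > 0, got {target_snr}")
    if phantom.signal_roi is None:
        raise ValueError("phantom must carry a signal ROI to define S_target")
    s_target = float(np.mean(phantom.image[phantom.signal_roi.slices]))
    sigma = s_target / target_snr
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, data.shape) \
        + 1j * rng.normal(0.0, sigma, data.shape)
    return KSpaceSample(data=data + noise, noise_sigma=sigma,
                        target_snr=target_snr, seed=seed)
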