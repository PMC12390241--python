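"""Zero-filled and L1-wavelet compressed-sensing reconstruction baselines.

The CS problem is

    minimize_x  1/2 || M o (F x - y) ||_2^2  +  lam * || Psi x ||_1

with F the unitary centered DFT, M the boolean acquisition mask, and Psi an
orthonormal Daubechies-4 wavelet transform (4 levels, periodic extension).
Because both F and Psi are unitary the forward operator has unit Lipschitz
constant, so proximal gradient steps of size 1 are admissible and the prox is
exact complex soft-thresholding of the wavelet coefficients. The solver is
monotone FISTA (accelerated proximal gradient with a monotonicity safeguard),
so the recorded objective trace is non-increasing.

k-space data are normalized so the zero-filled magnitude maximum is 1 before
solving; lam is interpreted on that scale and the output is scaled back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pywt

from .errors import NumericalError
from .forward_model import KSpaceSample, image_to_kspace, kspace_to_image
from .sampling import SamplingMask

__all__ = ["ReconResult", "zero_fill_recon", "cs_l1wavelet_recon",
           "wavelet_analysis", "wavelet_synthesis"]

WAVELET = "db4"
LEVELS = 4
MODE = "periodization"


@dataclass
class ReconResult:
    """A complex reconstruction, its magnitude, and how it was produced."""

    image: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    objective_trace: np.ndarray | None = None

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.image)


def _as_kdata(kspace) -> np.ndarray:
    return np.asarray(kspace.data if isinstance(kspace, KSpaceSample) else kspace)


def _as_mask(mask) -> np.ndarray:
    return np.asarray(mask.mask if isinstance(mask, SamplingMask) else mask,
                      dtype=bool)


def wavelet_analysis(x: np.ndarray):
    """Orthonormal db4 decomposition of a complex image -> (coeff array, slices)."""
    ar, sl = pywt.coeffs_to_array(pywt.wavedec2(x.real, WAVELET, mode=MODE,
                                                level=LEVELS))
    if np.iscomplexobj(x):
        ai, _ = pywt.coeffs_to_array(pywt.wavedec2(x.imag, WAVELET, mode=MODE,
                                                   level=LEVELS))
        return ar + 1j * ai, sl
    return ar, sl


def wavelet_synthesis(arr: np.ndarray, slices) -> np.ndarray:
    xr = pywt.waverec2(pywt.array_to_coeffs(arr.real, slices,
                                            output_format="wavedec2"),
                       WAVELET, mode=MODE)
    if np.iscomplexobj(arr):
        xi = pywt.waverec2(pywt.array_to_coeffs(arr.imag, slices,
                                                output_format="wavedec2"),
                           WAVELET, mode=MODE)
        return xr + 1j * xi
    return xr


def zero_fill_recon(kspace, mask) -> ReconResult:
    """Inverse transform of the mask-multiplied k-space."""
    data = _as_kdata(kspace)
    m = _as_mask(mask)
    if data.shape != m.shape:
        raise ValueError(f"kspace {data.shape} vs mask {m.shape} shape mismatch")
    img = kspace_to_image(data * m)
    return ReconResult(image=img, method="zero_fill", params={})


def _soft(arr: np.ndarray, t: float) -> np.ndarray:
    mag = np.abs(arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(mag > t, 1.0 - t / np.maximum(mag, 1e-300), 0.0)
    return arr * scale


def cs_l1wavelet_recon(kspace, mask, lam: float = 2e-3,
                       max_iters: int = 200, tol: float = 1e-6) -> ReconResult:
    """L1-wavelet CS reconstruction by monotone FISTA (see module docstring)."""
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    data = _as_kdata(kspace)
    m = _as_mask(mask)
    if data.shape != m.shape:
        raise ValueError(f"kspace {data.shape} vs mask {m.shape} shape mismatch")

    y = np.where(m, data, 0)
    x0 = kspace_to_image(y)
    scale = float(np.abs(x0).max())
    if scale == 0.0:
        return ReconResult(image=np.zeros_like(x0), method="cs_l1w",
                           params={"lam": lam, "iterations": 0},
                           objective_trace=np.zeros(0))
    y = y / scale

    def objective_parts(Fx, warr):
        data_term = 0.5 * float(np.sum(np.abs(np.where(m, Fx, 0) - y) ** 2))
        return data_term + lam * float(np.sum(np.abs(warr)))

    x = x0 / scale
    warr_x, slices = wavelet_analysis(x)
    Fx = image_to_kspace(x)
    obj_x = objective_parts(Fx, warr_x)

    z = x
    t = 1.0
    trace = [obj_x]
    for it in range(1, max_iters + 1):
        Fz = image_to_kspace(z)
        grad = kspace_to_image(np.where(m, Fz, 0) - y)
        v = z - grad
        warr_u = _soft(wavelet_analysis(v)[0], lam)
        u = wavelet_synthesis(warr_u, slices)
        Fu = image_to_kspace(u)
        obj_u = objective_parts(Fu, warr_u)

        if not math.isfinite(obj_u):
            raise NumericalError("CS objective became non-finite",
                                 trace=np.asarray(trace))
        # monotone safeguard: keep the best iterate seen so far
        if obj_u <= obj_x:
            x_new, obj_new = u, obj_u
        else:
            x_new, obj_new = x, obj_x
        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t * t))
        z = x_new + (t / t_new) * (u - x_new) \
            + ((t - 1.0) / t_new) * (x_new - x)
        if obj_new > obj_x * (1.0 + 1e-9) + 1e-12:
            raise NumericalError("CS objective increased after restart",
                                 trace=np.asarray(trace))
        rel = float(np.linalg.norm(x_new - x)) \
            / max(float(np.linalg.norm(x)), 1e-30)
        x, obj_x, t = x_new, obj_new, t_new
        trace.append(obj_x)
        if rel < tol:
            break

    return ReconResult(image=x * scale, method="cs_l1w",
                       params={"lam": lam, "max_iters": max_iters, "tol": tol,
                               "iterations": len(trace) - 1, "scale": scale},
                       objective_trace=np.asarray(trace))
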