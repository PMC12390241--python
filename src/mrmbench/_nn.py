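"""Minimal numpy neural-network engine for the unrolled reconstruction.

Implements exactly the pieces the scan-specific unrolled network needs —
3x3 same-padding convolutions (im2col + GEMM), ReLU, the residual denoiser,
backpropagation through the alternating denoiser / data-consistency unroll,
and Adam — in float32. Everything is deterministic given the seed: no
threading-dependent reductions, no stochastic layers.

Complex images are carried as two real channels (real, imaginary) through the
denoiser and as complex arrays through the Fourier/data-consistency steps.
Gradients with respect to complex arrays are stored as complex arrays whose
real/imaginary parts are the partial derivatives with respect to the real and
imaginary components; under that convention the adjoint of the unitary FFT is
the unitary inverse FFT.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32
C64 = np.complex64


def fft2c(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x), norm="ortho"))


def ifft2c(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x), norm="ortho"))


# ---------------------------------------------------------------- conv 3x3

try:
    from numba import njit as _njit

    @_njit(cache=True, fastmath=True)
    def _conv3x3_kernel(xp, w, b, y):  # xp: (Cin,H+2,W+2) zero-padded
        cout = w.shape[0]
        cin = w.shape[1]
        h = xp.shape[1] - 2
        wd = xp.shape[2] - 2
        for co in range(cout):
            for r in range(h):
                row = y[co, r]
                for c in range(wd):
                    row[c] = b[co]
                for ci in range(cin):
                    for di in range(3):
                        xr = xp[ci, r + di]
                        w0 = w[co, ci, di, 0]
                        w1 = w[co, ci, di, 1]
                        w2 = w[co, ci, di, 2]
                        for c in range(wd):
                            row[c] += w0 * xr[c] + w1 * xr[c + 1] \
                                + w2 * xr[c + 2]

    @_njit(cache=True, fastmath=True)
    def _conv3x3_dw_kernel(xp, dy, dw, db):
        cout = dy.shape[0]
        cin = xp.shape[0]
        h = dy.shape[1]
        wd = dy.shape[2]
        for co in range(cout):
            s = 0.0
            for r in range(h):
                for c in range(wd):
                    s += dy[co, r, c]
            db[co] = s
            for ci in range(cin):
                for di in range(3):
                    for dj in range(3):
                        acc = 0.0
                        for r in range(h):
                            dyr = dy[co, r]
                            xr = xp[ci, r + di]
                            for c in range(wd):
                                acc += dyr[c] * xr[c + dj]
                        dw[co, ci, di, dj] = acc

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is expected to be present
    _HAVE_NUMBA = False


def _conv3x3_im2col(x, w, b):
    cin, h, wd = x.shape
    cout = w.shape[0]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))     # (Cin,H,W,3,3)
    cols = win.transpose(1, 2, 0, 3, 4).reshape(h * wd, cin * 9)
    y = cols @ w.reshape(cout, cin * 9).T + b
    return np.ascontiguousarray(y.T.reshape(cout, h, wd))


def conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padding 3x3 correlation. x: (Cin,H,W); w: (Cout,Cin,3,3); b: (Cout,)."""
    if _HAVE_NUMBA:
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
        y = np.empty((w.shape[0], x.shape[1], x.shape[2]), dtype=x.dtype)
        _conv3x3_kernel(xp, w, b, y)
        return y
    return _conv3x3_im2col(x, w, b)


def conv3x3_backward(x: np.ndarray, w: np.ndarray, dy: np.ndarray):
    """Gradients of conv3x3: returns (dx, dw, db)."""
    cin, h, wd = x.shape
    cout = w.shape[0]
    if _HAVE_NUMBA:
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
        dw = np.empty_like(w)
        db = np.empty(cout, dtype=w.dtype)
        _conv3x3_dw_kernel(xp, dy, dw, db)
    else:
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))
        cols = win.transpose(1, 2, 0, 3, 4).reshape(h * wd, cin * 9)
        dyf = dy.reshape(cout, h * wd)
        dw = (dyf @ cols).reshape(w.shape)
        db = dyf.sum(axis=1)
    # input gradient = correlation of dy with channel-transposed, flipped kernels
    wb = np.ascontiguousarray(w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
    dx = conv3x3(dy, wb, np.zeros(cin, dtype=w.dtype))
    return dx, dw, db


# ----------------------------------------------------------- residual denoiser

def init_denoiser_params(filters: int, blocks: int, rng: np.random.Generator,
                         channels: int = 2) -> dict:
    """Glorot-uniform initialization of the residual CNN denoiser."""
    def glorot(cout, cin):
        lim = np.sqrt(6.0 / ((cin + cout) * 9.0))
        return rng.uniform(-lim, lim, size=(cout, cin, 3, 3)).astype(F32)

    p = {"in_w": glorot(filters, channels),
         "in_b": np.zeros(filters, dtype=F32),
         "out_w": glorot(channels, filters),
         "out_b": np.zeros(channels, dtype=F32)}
    for i in range(blocks):
        p[f"b{i}_w1"] = glorot(filters, filters)
        p[f"b{i}_b1"] = np.zeros(filters, dtype=F32)
        p[f"b{i}_w2"] = glorot(filters, filters)
        p[f"b{i}_b2"] = np.zeros(filters, dtype=F32)
    return p


def denoiser_forward(p: dict, x: np.ndarray, blocks: int, alpha: float):
    """Residual CNN: entry conv, ``blocks`` residual blocks
    (conv-ReLU-conv, scaled by alpha, with a skip), exit conv, and a global
    skip so zero weights give the identity map. Returns (out, tape)."""
    tape = {"x": x}
    h = conv3x3(x, p["in_w"], p["in_b"])
    for i in range(blocks):
        tape[f"h{i}"] = h
        a = conv3x3(h, p[f"b{i}_w1"], p[f"b{i}_b1"])
        r = np.maximum(a, 0.0)
        tape[f"a{i}"] = a
        tape[f"r{i}"] = r
        c = conv3x3(r, p[f"b{i}_w2"], p[f"b{i}_b2"])
        h = h + F32(alpha) * c
    tape["h_out"] = h
    out = x + conv3x3(h, p["out_w"], p["out_b"])
    return out, tape


def denoiser_backward(p: dict, tape: dict, dout: np.ndarray,
                      blocks: int, alpha: float):
    """Returns (dx, grads) for denoiser_forward."""
    grads = {}
    dh, dw, db = conv3x3_backward(tape["h_out"], p["out_w"], dout)
    grads["out_w"], grads["out_b"] = dw, db
    dx = dout.copy()
    for i in reversed(range(blocks)):
        dc = F32(alpha) * dh
        dr, dw2, db2 = conv3x3_backward(tape[f"r{i}"], p[f"b{i}_w2"], dc)
        grads[f"b{i}_w2"], grads[f"b{i}_b2"] = dw2, db2
        da = dr * (tape[f"a{i}"] > 0)
        dh_in, dw1, db1 = conv3x3_backward(tape[f"h{i}"], p[f"b{i}_w1"], da)
        grads[f"b{i}_w1"], grads[f"b{i}_b1"] = dw1, db1
        dh = dh + dh_in
    dx_in, dw_in, db_in = conv3x3_backward(tape["x"], p["in_w"], dh)
    grads["in_w"], grads["in_b"] = dw_in, db_in
    dx += dx_in
    return dx, grads


# ------------------------------------------------------------- complex glue

def complex_to_channels(x: np.ndarray) -> np.ndarray:
    return np.stack([x.real, x.imag]).astype(F32)


def channels_to_complex(x: np.ndarray) -> np.ndarray:
    return (x[0] + 1j * x[1]).astype(C64)


# ------------------------------------------------------------------ unroll

def unroll_forward(params: dict, y: np.ndarray, mask: np.ndarray,
                   unrolls: int, blocks: int, alpha: float):
    """Alternate the denoiser with the single-coil diagonal data-consistency
    solve for ``unrolls`` iterations, starting from the zero-filled image of
    the masked data y. Returns (x_image, tape)."""
    mu = float(params["mu"])
    x = ifft2c(y).astype(C64)
    steps = []
    for _ in range(unrolls):
        xch = complex_to_channels(x)
        zch, dtape = denoiser_forward(params, xch, blocks, alpha)
        z = channels_to_complex(zch)
        zk = fft2c(z)
        xk = np.where(mask, (y + mu * zk) / (1.0 + mu), zk)
        x = ifft2c(xk).astype(C64)
        steps.append({"dtape": dtape, "zk": zk})
    return x, {"steps": steps, "mu": mu, "y": y, "mask": mask}


def unroll_backward(params: dict, tape: dict, dx: np.ndarray,
                    blocks: int, alpha: float):
    """Backpropagate through unroll_forward. dx is the gradient with respect
    to the final complex image. Returns grads dict (including 'mu')."""
    mu = tape["mu"]
    mask = tape["mask"]
    y = tape["y"]
    grads = None
    dmu = 0.0
    for step in reversed(tape["steps"]):
        g = fft2c(dx)                                   # adjoint of ifft2c
        dxk_dmu = np.where(mask, (step["zk"] - y) / (1.0 + mu) ** 2, 0.0)
        dmu += float(np.sum(g.real * dxk_dmu.real + g.imag * dxk_dmu.imag))
        dzk = np.where(mask, mu / (1.0 + mu), 1.0) * g
        dz = ifft2c(dzk)
        dzch = complex_to_channels(dz)
        dxch, dstep = denoiser_backward(params, step["dtape"], dzch,
                                        blocks, alpha)
        if grads is None:
            grads = dstep
        else:
            for k in grads:
                grads[k] += dstep[k]
        dx = channels_to_complex(dxch)
    # gradient w.r.t. the zero-filled input does not reach any parameter
    grads["mu"] = np.float64(dmu)
    return grads


# -------------------------------------------------------------------- Adam

class Adam:
    """Adaptive moment estimation over a dict of arrays (and scalars)."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(np.asarray(v, dtype=np.float64)
                                   if np.isscalar(v) else v)
                  for k, v in params.items()}
        self.v = {k: np.zeros_like(m) for k, m in self.m.items()}

    def step(self, params: dict, grads: dict) -> dict:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        out = {}
        for k, val in params.items():
            g = np.asarray(grads[k], dtype=self.m[k].dtype)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            upd = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            new = np.asarray(val) - upd.astype(np.asarray(val).dtype)
            out[k] = float(new) if np.ndim(val) == 0 else new
        return out
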