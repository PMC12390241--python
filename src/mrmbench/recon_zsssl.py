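"""Scan-specific zero-shot self-supervised reconstruction.

The acquired k-space points Ω of a single scan are partitioned into three
disjoint subsets Ω = Θ ⊔ Λ ⊔ Γ. An unrolled network — alternating a residual
CNN denoiser with a physics data-consistency (DC) solve — is trained on that
scan alone: each epoch the network reconstructs from y_Θ and is penalized for
mispredicting the held-out k-space samples y_Λ (training loss); a validation
loss predicts y_Γ from a reconstruction based on y_{Ω∖Γ} and drives early
stopping. After training, the full measured k-space y_Ω is passed through the
network to produce the final image.

The DC step solves (EᴴE + μI) x = Eᴴ y + μ z with E = mask ∘ F; for
single-coil Cartesian data the system is diagonal in k-space,
X(k) = (Y(k) + μ Z(k)) / (1 + μ) on acquired k and X(k) = Z(k) elsewhere.
The public :func:`dc_solve` runs conjugate gradients (kept for the multi-coil
extension path); training uses the mathematically identical diagonal form.

Both losses use the mixed norm L(u, v) = ||u−v||₁/||u||₁ + ||u−v||₂/||u||₂,
which is scale invariant, so the k-space normalization (zero-filled magnitude
maximum scaled to 1) does not change the loss landscape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .errors import ConfigurationError, ContractError, NumericalError
from .forward_model import KSpaceSample, kspace_to_image
from .recon_classical import ReconResult
from .sampling import SamplingMask

__all__ = ["SplitMasks", "UnrolledConfig", "TrainingHistory", "ZSSSLModel",
           "split_measurements", "dc_solve", "mixed_norm_loss",
           "unrolled_forward", "train_zs_ssl", "zs_ssl_reconstruct"]


@dataclass
class SplitMasks:
    """The Θ/Λ/Γ partition of the acquired k-space points."""

    theta: np.ndarray
    lam: np.ndarray
    gamma: np.ndarray
    theta_fraction: float
    lam_fraction: float
    gamma_fraction: float
    seed: int | None


@dataclass
class UnrolledConfig:
    """Architecture and training settings of the unrolled network.

    Defaults follow the reference protocol: 10 unrolls of DC + denoising, a
    5-block residual CNN with 64 filters of 3x3 kernels and residual scaling
    alpha = 0.1, Adam at learning rate 5e-4, and early stopping with
    patience 20. ``early_stopping`` selects between ``"best_val"`` (default:
    stop when the validation loss has not improved for ``patience`` epochs
    and restore the best checkpoint) and ``"literal"`` (stop after
    L_train > L_val for ``patience`` consecutive epochs, no checkpointing).
    """

    unrolls: int = 10
    residual_blocks: int = 5
    filters: int = 64
    kernel: int = 3
    scale_alpha: float = 0.1
    learning_rate: float = 5e-4
    dc_weight_init: float = 0.05
    cg_iters: int = 10
    max_epochs: int = 500
    patience: int = 20
    gamma_fraction: float = 0.2
    lam_fraction: float = 0.4
    assign_center_to_theta: bool = True
    early_stopping: str = "best_val"
    seed: int = 0

    def __post_init__(self):
        if min(self.unrolls, self.residual_blocks, self.filters,
               self.max_epochs) < 1 or self.patience < 1:
            raise ConfigurationError("all counts must be positive")
        if self.kernel != 3:
            raise ConfigurationError("only 3x3 kernels are supported")
        if self.early_stopping not in ("best_val", "literal"):
            raise ConfigurationError(
                f"unknown early_stopping {self.early_stopping!r}")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    stop_reason: str = ""
    best_epoch: int | None = None


@dataclass
class ZSSSLModel:
    """Trained parameters plus the context needed for final inference."""

    params: dict
    config: UnrolledConfig
    scale: float
    mask_signature: int


def split_measurements(mask: SamplingMask, gamma_fraction: float = 0.2,
                       lam_fraction: float = 0.4, seed: int | None = 0,
                       assign_center_to_theta: bool = True) -> SplitMasks:
    """Partition the acquired points Ω into Θ ⊔ Λ ⊔ Γ.

    Γ is drawn uniformly at ``gamma_fraction`` of |Ω|; of the remainder, Λ is
    drawn at ``lam_fraction``; the rest is Θ. With
    ``assign_center_to_theta`` (default) the fully sampled calibration disk
    is forced into Θ so the network input always contains the low-frequency
    core; Γ and Λ are then drawn from the outside-disk points only.
    """
    if not (0 < gamma_fraction < 1 and 0 < lam_fraction < 1):
        raise ConfigurationError("fractions must lie in (0, 1)")
    omega = np.asarray(mask.mask, dtype=bool)
    n_omega = int(omega.sum())
    if n_omega == 0:
        raise ConfigurationError("acquisition mask is empty")

    if assign_center_to_theta:
        rr = np.hypot(*np.meshgrid(
            np.arange(omega.shape[0]) - omega.shape[0] // 2,
            np.arange(omega.shape[1]) - omega.shape[1] // 2, indexing="ij"))
        reserved = omega & (rr <= mask.center_radius)
    else:
        reserved = np.zeros_like(omega)
    pool = np.flatnonzero((omega & ~reserved).ravel())

    n_gamma = int(round(gamma_fraction * n_omega))
    n_lam = int(round(lam_fraction * (n_omega - n_gamma)))
    if n_gamma < 1 or n_lam < 1 or n_gamma + n_lam > len(pool) \
            or n_omega - n_gamma - n_lam < 1:
        raise ConfigurationError(
            f"infeasible split: |Ω|={n_omega}, requested |Γ|={n_gamma}, "
            f"|Λ|={n_lam}, drawable pool={len(pool)}")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pool))
    gamma_idx = pool[perm[:n_gamma]]
    lam_idx = pool[perm[n_gamma:n_gamma + n_lam]]

    gamma = np.zeros_like(omega)
    gamma.ravel()[gamma_idx] = True
    lam = np.zeros_like(omega)
    lam.ravel()[lam_idx] = True
    theta = omega & ~gamma & ~lam
    return SplitMasks(theta=theta, lam=lam, gamma=gamma,
                      theta_fraction=float(theta.sum()) / n_omega,
                      lam_fraction=float(lam.sum()) / n_omega,
                      gamma_fraction=float(gamma.sum()) / n_omega,
                      seed=seed)


def dc_solve(z: np.ndarray, y: np.ndarray, subset_mask: np.ndarray,
             mu: float, cg_iters: int = 10, tol: float = 1e-12,
             method: str = "cg") -> np.ndarray:
    """Solve (EᴴE + μI) x = Eᴴ y + μ z with E = subset_mask ∘ F.

    ``method="cg"`` (default) runs conjugate gradients on the normal
    equations; ``method="direct"`` applies the diagonal closed form (exact
    for single-coil Cartesian encoding). A convergence warning is emitted if
    CG does not reach ``tol`` within ``cg_iters``.
    """
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    m = np.asarray(subset_mask, dtype=bool)
    if method == "direct":
        xk = np.where(m, (np.where(m, y, 0) + mu * _nn.fft2c(z)) / (1.0 + mu),
                      _nn.fft2c(z))
        return _nn.ifft2c(xk)

    def A(v):
        return _nn.ifft2c(m * _nn.fft2c(v)) + mu * v

    b = _nn.ifft2c(m * np.where(m, y, 0)) + mu * z
    x = np.zeros_like(b)
    r = b - A(x)
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    b2 = float(np.vdot(b, b).real) or 1.0
    for _ in range(cg_iters):
        if rs / b2 < tol:
            break
        Ap = A(p)
        alpha = rs / float(np.vdot(p, Ap).real)
        x = x + alpha * p
        r = r - alpha * Ap
        rs_new = float(np.vdot(r, r).real)
        p = r + (rs_new / rs) * p
        rs = rs_new
    else:
        if rs / b2 >= tol:
            warnings.warn(f"dc_solve CG did not converge within {cg_iters} "
                          f"iterations (residual {np.sqrt(rs / b2):.2e})")
    return x


def mixed_norm_loss(u: np.ndarray, v: np.ndarray) -> float:
    """L(u, v) = ||u−v||₁/||u||₁ + ||u−v||₂/||u||₂ over complex vectors."""
    u = np.asarray(u).ravel()
    v = np.asarray(v).ravel()
    n1 = float(np.sum(np.abs(u)))
    n2 = float(np.linalg.norm(u))
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("reference vector u must not be identically zero")
    d = u - v
    return float(np.sum(np.abs(d))) / n1 + float(np.linalg.norm(d)) / n2


def _mixed_norm_loss_grad(u: np.ndarray, v: np.ndarray):
    """(loss, dL/dv) with the complex gradient convention of :mod:`._nn`."""
    d = u - v
    n1 = float(np.sum(np.abs(u)))
    n2 = float(np.linalg.norm(u))
    dn1 = float(np.sum(np.abs(d)))
    dn2 = float(np.linalg.norm(d))
    loss = dn1 / n1 + dn2 / n2
    absd = np.abs(d)
    sign = np.where(absd > 0, d / np.where(absd > 0, absd, 1.0), 0.0)
    grad = -sign / n1
    if dn2 > 0:
        grad = grad - d / (dn2 * n2)
    return loss, grad


def _full_params(config: UnrolledConfig, rng: np.random.Generator) -> dict:
    p = _nn.init_denoiser_params(config.filters, config.residual_blocks, rng)
    p["mu"] = float(config.dc_weight_init)
    return p


def unrolled_forward(y_subset: np.ndarray, subset_mask: np.ndarray,
                     params: dict, config: UnrolledConfig) -> np.ndarray:
    """Run the unrolled network on masked k-space data; returns the complex
    image. ``y_subset`` must already be zero off ``subset_mask``."""
    m = np.asarray(subset_mask, dtype=bool)
    y = np.where(m, y_subset, 0).astype(_nn.C64)
    x, _ = _nn.unroll_forward(params, y, m, config.unrolls,
                              config.residual_blocks, config.scale_alpha)
    return x


def _loss_on_subset(params, y_in, in_mask, y_ref, loss_mask, config,
                    want_grad: bool):
    x, tape = _nn.unroll_forward(params, y_in, in_mask, config.unrolls,
                                 config.residual_blocks, config.scale_alpha)
    xk = _nn.fft2c(x)
    u = y_ref[loss_mask]
    v = xk[loss_mask]
    if not want_grad:
        return mixed_norm_loss(u, v), None
    loss, gv = _mixed_norm_loss_grad(u, v)
    gk = np.zeros_like(xk)
    gk[loss_mask] = gv
    dx = _nn.ifft2c(gk)
    grads = _nn.unroll_backward(params, tape, dx, config.residual_blocks,
                                config.scale_alpha)
    return loss, grads


def train_zs_ssl(kspace, mask: SamplingMask,
                 config: UnrolledConfig | None = None,
                 splits: SplitMasks | None = None):
    """Train the scan-specific network on a single (kspace, mask) pair.

    Returns ``(ZSSSLModel, TrainingHistory)``. Each epoch computes
    L_train = L(y_Λ, (F f(y_Θ))|_Λ) (used to update the parameters) and
    L_val = L(y_Γ, (F f(y_{Ω∖Γ}))|_Γ) (used only for stopping).
    """
    config = config or UnrolledConfig()
    data = np.asarray(kspace.data if isinstance(kspace, KSpaceSample) else kspace)
    omega = np.asarray(mask.mask, dtype=bool)
    if data.shape != omega.shape:
        raise ContractError("kspace and mask shapes differ")
    if splits is None:
        splits = split_measurements(mask, config.gamma_fraction,
                                    config.lam_fraction, seed=config.seed,
                                    assign_center_to_theta=
                                    config.assign_center_to_theta)

    y_full = np.where(omega, data, 0)
    scale = float(np.abs(kspace_to_image(y_full)).max())
    if scale == 0.0:
        raise ContractError("measured k-space is identically zero")
    y_full = (y_full / scale).astype(_nn.C64)
    y_theta = np.where(splits.theta, y_full, 0).astype(_nn.C64)
    train_in_mask = splits.theta
    val_in_mask = splits.theta | splits.lam          # Ω ∖ Γ
    y_val_in = np.where(val_in_mask, y_full, 0).astype(_nn.C64)

    rng = np.random.default_rng(config.seed)
    params = _full_params(config, rng)
    opt = _nn.Adam(params, lr=config.learning_rate)
    history = TrainingHistory()

    best_val = np.inf
    best_params = {k: (v.copy() if hasattr(v, "copy") else v)
                   for k, v in params.items()}
    best_epoch = 0
    bad_epochs = 0
    literal_count = 0
    stop_reason = "max_epochs"

    for epoch in range(1, config.max_epochs + 1):
        l_train, grads = _loss_on_subset(params, y_theta, train_in_mask,
                                         y_full, splits.lam, config,
                                         want_grad=True)
        l_val, _ = _loss_on_subset(params, y_val_in, val_in_mask,
                                   y_full, splits.gamma, config,
                                   want_grad=False)
        if not (np.isfinite(l_train) and np.isfinite(l_val)):
            history.stop_epoch = epoch
            history.stop_reason = "non-finite loss"
            raise NumericalError(
                f"non-finite loss at epoch {epoch}", trace=history)
        history.train_loss.append(l_train)
        history.val_loss.append(l_val)

        if l_val < best_val:
            best_val = l_val
            best_epoch = epoch
            best_params = {k: (v.copy() if hasattr(v, "copy") else v)
                           for k, v in params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1

        if config.early_stopping == "best_val":
            if bad_epochs >= config.patience:
                stop_reason = "no validation improvement"
                history.stop_epoch = epoch
                break
        else:  # literal printed rule
            literal_count = literal_count + 1 if l_train > l_val else 0
            if literal_count >= config.patience:
                stop_reason = "train loss above validation loss"
                history.stop_epoch = epoch
                break

        params = opt.step(params, grads)
        params["mu"] = max(float(params["mu"]), 1e-4)
    else:
        history.stop_epoch = config.max_epochs

    history.stop_reason = stop_reason
    if config.early_stopping == "best_val":
        params = best_params
        history.best_epoch = best_epoch
    model = ZSSSLModel(params=params, config=config, scale=scale,
                       mask_signature=mask.signature())
    return model, history


def zs_ssl_reconstruct(kspace, mask: SamplingMask, model: ZSSSLModel,
                       config: UnrolledConfig | None = None) -> ReconResult:
    """Final inference: pass the entire measured k-space through the trained
    network. ``mask`` must be the acquisition mask used for training."""
    config = config or model.config
    if mask.signature() != model.mask_signature:
        raise ContractError("mask does not match the one used for training")
    data = np.asarray(kspace.data if isinstance(kspace, KSpaceSample) else kspace)
    omega = np.asarray(mask.mask, dtype=bool)
    y = (np.where(omega, data, 0) / model.scale).astype(_nn.C64)
    x = unrolled_forward(y, omega, model.params, config)
    image = (x * model.scale).astype(np.complex128)
    return ReconResult(image=image, method="zs_ssl",
                       params={"config": config, "scale": model.scale})
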