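"""k-space partitioning, data consistency, losses, and scan-specific training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mrmbench as mb
from mrmbench.errors import ConfigurationError, ContractError
from mrmbench.recon_zsssl import (_full_params, _loss_on_subset,
                                  _mixed_norm_loss_grad)

TINY = dict(unrolls=3, residual_blocks=1, filters=4, max_epochs=25,
            patience=8)


@pytest.fixture(scope="module")
def mask128():
    return mb.make_sampling_mask(128, 4, 2, center_radius=8, seed=0)


# ------------------------------------------------------------ split masks

@settings(max_examples=15, deadline=None)
@given(seed=st.integers(0, 2 ** 20))
def test_split_is_exact_partition(seed):
    mask = mb.make_sampling_mask(128, 4, 2, center_radius=8, seed=3)
    sp = mb.split_measurements(mask, 0.2, 0.4, seed=seed)
    omega = mask.mask
    assert not np.any(sp.theta & sp.lam)
    assert not np.any(sp.theta & sp.gamma)
    assert not np.any(sp.lam & sp.gamma)
    assert np.array_equal(sp.theta | sp.lam | sp.gamma, omega)
    assert sp.theta.sum() > 0 and sp.lam.sum() > 0 and sp.gamma.sum() > 0


def test_split_counts_and_center_assignment(mask128):
    sp = mb.split_measurements(mask128, 0.2, 0.4, seed=1)
    n_omega = mask128.n_acquired
    assert sp.gamma.sum() == round(0.2 * n_omega)
    assert sp.lam.sum() == round(0.4 * (n_omega - sp.gamma.sum()))
    idx = np.arange(128) - 64
    rr = np.hypot(idx[:, None], idx[None, :])
    disk = mask128.mask & (rr <= mask128.center_radius)
    assert np.all(sp.theta[disk])


def test_split_infeasible_fraction_rejected(mask128):
    with pytest.raises(ConfigurationError):
        mb.split_measurements(mask128, 0.999, 0.4, seed=0)
    with pytest.raises(ConfigurationError):
        mb.split_measurements(mask128, 0.2, 1.5, seed=0)


# ------------------------------------------------------------- dc_solve

def test_dc_full_mask_mu_zero_is_inverse(rng):
    y = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
    x = mb.dc_solve(np.zeros((32, 32), complex), y, np.ones((32, 32), bool),
                    mu=0.0, cg_iters=10)
    assert np.abs(x - mb.kspace_to_image(y)).max() < 1e-8


def test_dc_prior_dominated_limit(rng):
    z = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
    y = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
    m = rng.random((32, 32)) < 0.3
    x = mb.dc_solve(z, y, m, mu=1e8, cg_iters=10)
    assert np.linalg.norm(x - z) / np.linalg.norm(z) < 1e-6


def test_dc_cg_matches_diagonal_closed_form(rng):
    for _ in range(20):
        z = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        y = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        m = rng.random((32, 32)) < 0.4
        mu = float(rng.uniform(0.01, 2.0))
        cg = mb.dc_solve(z, y, m, mu, cg_iters=10)
        direct = mb.dc_solve(z, y, m, mu, method="direct")
        assert np.linalg.norm(cg - direct) / np.linalg.norm(direct) < 1e-6


# ------------------------------------------------------------ mixed loss

def test_mixed_norm_loss_hand_values():
    assert mb.mixed_norm_loss([1, 2j], [1, 2j]) == 0.0
    assert mb.mixed_norm_loss([1, 2], [0, 0]) == pytest.approx(2.0, abs=1e-12)
    assert mb.mixed_norm_loss([1, 0], [0, 1]) \
        == pytest.approx(2 + np.sqrt(2), abs=1e-12)
    with pytest.raises(ValueError):
        mb.mixed_norm_loss([0, 0], [1, 1])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(c=st.floats(0.01, 100.0), flip=st.booleans())
def test_mixed_norm_loss_scale_invariant(c, flip):
    rng = np.random.default_rng(7)
    u = rng.normal(size=16) + 1j * rng.normal(size=16)
    v = rng.normal(size=16) + 1j * rng.normal(size=16)
    if flip:
        c = -c
    assert mb.mixed_norm_loss(c * u, c * v) \
        == pytest.approx(mb.mixed_norm_loss(u, v), rel=1e-9)


def test_mixed_norm_loss_gradient_matches_finite_difference(rng):
    u = rng.normal(size=8) + 1j * rng.normal(size=8)
    v = rng.normal(size=8) + 1j * rng.normal(size=8)
    _, g = _mixed_norm_loss_grad(u, v)
    eps = 1e-6
    for i in (0, 3):
        for part in (1.0, 1j):
            vp = v.copy()
            vp[i] += eps * part
            vm = v.copy()
            vm[i] -= eps * part
            fd = (mb.mixed_norm_loss(u, vp) - mb.mixed_norm_loss(u, vm)) / (2 * eps)
            an = g[i].real if part == 1.0 else g[i].imag
            assert an == pytest.approx(fd, rel=1e-4)


# ------------------------------------------------------- unrolled network

def test_zero_weights_reduce_to_repeated_dc(rng):
    """With all conv weights zero the denoiser is the identity, so the
    unroll reduces to repeated DC applied to the zero-filled image."""
    cfg = mb.UnrolledConfig(unrolls=3, residual_blocks=2, filters=4, seed=0)
    params = _full_params(cfg, np.random.default_rng(0))
    for k, v in params.items():
        if k != "mu":
            params[k] = np.zeros_like(v)
    n = 32
    m = rng.random((n, n)) < 0.5
    y = ((rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))) * m
         ).astype(np.complex64)
    out = mb.unrolled_forward(y, m, params, cfg)
    x = mb.kspace_to_image(y)
    mu = params["mu"]
    for _ in range(cfg.unrolls):
        x = mb.dc_solve(x, y, m, mu, method="direct")
    assert np.abs(out - x).max() < 1e-5


@pytest.mark.parametrize("n", [64, 128])
def test_unrolled_forward_shapes(n, rng):
    cfg = mb.UnrolledConfig(unrolls=2, residual_blocks=1, filters=4, seed=1)
    params = _full_params(cfg, np.random.default_rng(1))
    m = rng.random((n, n)) < 0.4
    y = ((rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))) * m
         ).astype(np.complex64)
    out = mb.unrolled_forward(y, m, params, cfg)
    assert out.shape == (n, n)
    assert np.iscomplexobj(out)


def test_unrolled_forward_deterministic(rng):
    cfg = mb.UnrolledConfig(unrolls=2, residual_blocks=1, filters=4, seed=5)
    params = _full_params(cfg, np.random.default_rng(5))
    m = rng.random((64, 64)) < 0.4
    y = ((rng.normal(size=(64, 64)) + 1j * rng.normal(size=(64, 64))) * m
         ).astype(np.complex64)
    a = mb.unrolled_forward(y, m, params, cfg)
    b = mb.unrolled_forward(y, m, params, cfg)
    assert np.array_equal(a, b)


def test_training_loss_gradients_match_finite_differences():
    """Analytic backprop through the full unrolled training loss agrees with
    central finite differences on representative parameter entries."""
    cfg = mb.UnrolledConfig(unrolls=2, residual_blocks=1, filters=3,
                            max_epochs=1, seed=0)
    rng = np.random.default_rng(2)
    n = 16
    mask = rng.random((n, n)) < 0.5
    mask[6:10, 6:10] = True
    y = ((rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))) * mask
         ).astype(np.complex64)
    lam_mask = mask & (rng.random((n, n)) < 0.3)
    theta = mask & ~lam_mask
    y_theta = np.where(theta, y, 0).astype(np.complex64)
    params = _full_params(cfg, np.random.default_rng(1))
    _, grads = _loss_on_subset(params, y_theta, theta, y, lam_mask, cfg, True)

    def loss_at(p):
        return _loss_on_subset(p, y_theta, theta, y, lam_mask, cfg, False)[0]

    eps = 1e-3
    checked = 0
    for key in ("in_w", "b0_w1", "out_w", "out_b", "mu"):
        g = np.asarray(grads[key])
        if key == "mu":
            pp = dict(params)
            pp["mu"] = params["mu"] + eps
            pm = dict(params)
            pm["mu"] = params["mu"] - eps
            fd = (loss_at(pp) - loss_at(pm)) / (2 * eps)
            assert float(g) == pytest.approx(fd, rel=0.05, abs=1e-4)
            checked += 1
            continue
        flat = np.argmax(np.abs(g))  # largest-magnitude entry: robust to fp32
        idx = np.unravel_index(flat, g.shape)
        pp = dict(params)
        pp[key] = params[key].copy()
        pp[key][idx] += eps
        pm = dict(params)
        pm[key] = params[key].copy()
        pm[key][idx] -= eps
        fd = (loss_at(pp) - loss_at(pm)) / (2 * eps)
        assert float(g[idx]) == pytest.approx(fd, rel=0.05, abs=1e-4)
        checked += 1
    assert checked == 5


# ---------------------------------------------------------------- training

@pytest.fixture(scope="module")
def trained_small():
    ph = mb.make_phantom_with_rois(64, 4, roi_side=8)
    k = mb.image_to_kspace(ph.image)
    ks = mb.add_noise_for_target_snr(k, 20, ph, seed=4)
    mask = mb.make_sampling_mask(64, 2, 2, center_radius=4, seed=4)
    cfg = mb.UnrolledConfig(seed=4, **TINY)
    model, hist = mb.train_zs_ssl(ks, mask, cfg)
    return ph, ks, mask, cfg, model, hist


def test_history_lengths_and_stop_epoch(trained_small):
    _, _, _, cfg, _, hist = trained_small
    assert len(hist.train_loss) == len(hist.val_loss) == hist.stop_epoch
    assert hist.stop_epoch <= cfg.max_epochs


def test_training_improves_validation_loss(trained_small):
    _, _, _, _, _, hist = trained_small
    assert hist.val_loss[-1] <= hist.val_loss[0]
    assert min(hist.val_loss) < hist.val_loss[0]


def test_training_deterministic_given_seed(trained_small):
    ph, ks, mask, cfg, _, hist = trained_small
    _, hist2 = mb.train_zs_ssl(ks, mask, cfg)
    assert hist2.train_loss == hist.train_loss
    assert hist2.val_loss == hist.val_loss
    assert hist2.stop_epoch == hist.stop_epoch


def test_reconstruct_magnitude_and_mask_contract(trained_small):
    ph, ks, mask, cfg, model, _ = trained_small
    rec = mb.zs_ssl_reconstruct(ks, mask, model)
    assert np.array_equal(rec.magnitude, np.abs(rec.image))
    other = mb.make_sampling_mask(64, 2, 2, center_radius=4, seed=99)
    with pytest.raises(ContractError):
        mb.zs_ssl_reconstruct(ks, other, model)


def test_literal_early_stopping_rule_runs():
    ph = mb.make_phantom_with_rois(64, 4, roi_side=8)
    k = mb.image_to_kspace(ph.image)
    ks = mb.add_noise_for_target_snr(k, 20, ph, seed=6)
    mask = mb.make_sampling_mask(64, 2, 2, center_radius=4, seed=6)
    cfg = mb.UnrolledConfig(seed=6, unrolls=3, residual_blocks=1, filters=4,
                            max_epochs=15, patience=3,
                            early_stopping="literal")
    _, hist = mb.train_zs_ssl(ks, mask, cfg)
    assert hist.stop_epoch <= 15
    if hist.stop_reason == "train loss above validation loss":
        tail = [t > v for t, v in zip(hist.train_loss[-3:],
                                      hist.val_loss[-3:])]
        assert all(tail)


def test_full_sampling_reconstruction_is_near_identity():
    """At AF=1 the data fully determine the image: the trained network's
    output stays within 5% NRMSE of the inverse transform."""
    ph = mb.make_phantom_with_rois(64, 4, roi_side=8)
    k = mb.image_to_kspace(ph.image)
    ks = mb.add_noise_for_target_snr(k, 30, ph, seed=8)
    mask = mb.make_sampling_mask(64, 1, 2, center_radius=4, seed=8)
    cfg = mb.UnrolledConfig(seed=8, **TINY)
    model, _ = mb.train_zs_ssl(ks, mask, cfg)
    rec = mb.zs_ssl_reconstruct(ks, mask, model)
    ref = mb.kspace_to_image(ks.data)
    nrmse = np.linalg.norm(rec.image - ref) / np.linalg.norm(ref)
    assert nrmse <= 0.05
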