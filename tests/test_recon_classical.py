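"""Zero-filled and L1-wavelet CS reconstruction correctness."""

import numpy as np
import pytest

import mrmbench as mb
from mrmbench.recon_classical import wavelet_analysis, wavelet_synthesis


@pytest.fixture(scope="module")
def toy_problem():
    """16x16 undersampled CS instance with a known sparse-ish target."""
    rng = np.random.default_rng(5)
    x = np.zeros((16, 16), complex)
    x[4:10, 4:10] = 1.0
    x[12, 12] = 2.0
    k = mb.image_to_kspace(x) + 0.01 * (rng.normal(size=(16, 16))
                                        + 1j * rng.normal(size=(16, 16)))
    mask = rng.random((16, 16)) < 0.55
    mask[7:10, 7:10] = True
    return k, mask


def test_wavelet_transform_is_orthonormal(rng):
    x = rng.normal(size=(64, 64)) + 1j * rng.normal(size=(64, 64))
    arr, sl = wavelet_analysis(x)
    assert np.sum(np.abs(arr) ** 2) == pytest.approx(np.sum(np.abs(x) ** 2),
                                                     rel=1e-10)
    assert np.abs(wavelet_synthesis(arr, sl) - x).max() < 1e-10


def test_zero_fill_full_mask_is_inverse_transform(small_phantom, small_kspace):
    full = np.ones((128, 128), bool)
    rec = mb.zero_fill_recon(small_kspace, full)
    assert np.abs(rec.image - small_phantom.image).max() < 1e-10
    assert np.array_equal(rec.magnitude, np.abs(rec.image))


def test_zero_fill_zero_kspace_is_zero():
    rec = mb.zero_fill_recon(np.zeros((32, 32), complex), np.ones((32, 32), bool))
    assert np.abs(rec.image).max() == 0.0


def test_zero_fill_undersampling_degrades_nrmse(small_phantom, small_kspace):
    w = small_phantom.image
    full = mb.zero_fill_recon(small_kspace, np.ones((128, 128), bool))
    m = mb.make_sampling_mask(128, 4, 2, center_radius=8, seed=0)
    under = mb.zero_fill_recon(small_kspace, m)
    err = lambda r: np.linalg.norm(r.magnitude - w) / np.linalg.norm(w)
    assert err(under) > err(full)


def test_cs_lam0_full_mask_recovers_inverse(small_kspace, small_phantom):
    full = np.ones((128, 128), bool)
    rec = mb.cs_l1wavelet_recon(small_kspace, full, lam=0.0, max_iters=50)
    assert np.abs(rec.image - small_phantom.image).max() < 1e-6


def test_objective_trace_is_monotone(toy_problem):
    k, mask = toy_problem
    rec = mb.cs_l1wavelet_recon(k, mask, lam=2e-3, max_iters=150)
    tr = rec.objective_trace
    assert len(tr) >= 2
    assert np.all(np.diff(tr) <= 1e-9 * np.abs(tr[:-1]) + 1e-12)


def test_final_objective_matches_overiterated_reference(toy_problem):
    """The returned objective agrees (1e-6 relative) with an independent
    long-run proximal-gradient solver started from three different points."""
    k, mask = toy_problem
    rec = mb.cs_l1wavelet_recon(k, mask, lam=2e-3, max_iters=1500, tol=0.0)
    lam = 2e-3
    y = np.where(mask, k, 0)
    scale = float(np.abs(mb.kspace_to_image(y)).max())
    yn = y / scale

    def objective(x):
        arr, _ = wavelet_analysis(x)
        r = np.where(mask, mb.image_to_kspace(x), 0) - yn
        return 0.5 * float(np.sum(np.abs(r) ** 2)) \
            + lam * float(np.sum(np.abs(arr)))

    def accel_prox(x0, iters=4000):
        # plain (non-monotone) accelerated proximal gradient, written
        # independently of the solver under test
        x = x0
        z = x0
        t = 1.0
        for _ in range(iters):
            g = mb.kspace_to_image(np.where(mask, mb.image_to_kspace(z), 0) - yn)
            arr, sl = wavelet_analysis(z - g)
            mag = np.abs(arr)
            arr = arr * np.where(mag > lam, 1 - lam / np.maximum(mag, 1e-300), 0)
            x_new = wavelet_synthesis(arr, sl)
            t_new = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
            z = x_new + ((t - 1) / t_new) * (x_new - x)
            x, t = x_new, t_new
        return objective(x)

    rng = np.random.default_rng(0)
    inits = [np.zeros((16, 16), complex),
             mb.kspace_to_image(yn),
             rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))]
    refs = [accel_prox(x0) for x0 in inits]
    assert max(refs) - min(refs) < 1e-6 * abs(min(refs))
    assert rec.objective_trace[-1] == pytest.approx(min(refs), rel=1e-6)


def test_subgradient_optimality_at_solution(toy_problem):
    """At the optimum, wavelet coefficients of the negative data-gradient lie
    in the L1 subdifferential: |g_i| <= lam where x_i = 0 and
    g_i = -lam * sign(x_i) where x_i != 0 (to tolerance)."""
    k, mask = toy_problem
    lam = 2e-3
    rec = mb.cs_l1wavelet_recon(k, mask, lam=lam, max_iters=4000, tol=0.0)
    x = rec.image / rec.params["scale"]
    y = np.where(mask, k, 0) / rec.params["scale"]
    grad = mb.kspace_to_image(np.where(mask, mb.image_to_kspace(x), 0) - y)
    garr, _ = wavelet_analysis(grad)
    xarr, _ = wavelet_analysis(x)
    on = np.abs(xarr) > 1e-6
    # active coefficients: gradient balances lam * sign
    resid = garr[on] + lam * xarr[on] / np.abs(xarr)[on]
    assert np.abs(resid).max() < 1e-4
    assert np.abs(garr[~on]).max() < lam + 1e-4


def test_large_lam_drives_coefficients_to_zero(toy_problem):
    k, mask = toy_problem
    rec = mb.cs_l1wavelet_recon(k, mask, lam=10.0, max_iters=100)
    arr, _ = wavelet_analysis(rec.image / rec.params["scale"])
    small = mb.cs_l1wavelet_recon(k, mask, lam=2e-3, max_iters=100)
    arr_s, _ = wavelet_analysis(small.image / small.params["scale"])
    assert np.sum(np.abs(arr) > 1e-8) < np.sum(np.abs(arr_s) > 1e-8)


def test_cs_beats_zero_fill_on_phantom(small_phantom, small_kspace):
    ph = small_phantom
    m = mb.make_sampling_mask(128, 4, 2, center_radius=8, seed=2)
    ks = mb.add_noise_for_target_snr(small_kspace, 15, ph, seed=2)
    zf = mb.zero_fill_recon(ks, m)
    cs = mb.cs_l1wavelet_recon(ks, m, lam=2e-3, max_iters=100, tol=1e-5)
    err = lambda r: np.linalg.norm(r.magnitude - ph.image) / np.linalg.norm(ph.image)
    assert err(cs) < err(zf)


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        mb.zero_fill_recon(np.zeros((8, 8), complex), np.ones((16, 16), bool))
    with pytest.raises(ValueError):
        mb.cs_l1wavelet_recon(np.zeros((8, 8), complex), np.ones((16, 16), bool))
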