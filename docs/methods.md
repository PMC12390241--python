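# Methods

`mrmbench` quantifies how undersampling, noise, and the choice of
reconstruction algorithm degrade the *effective* spatial resolution of MR
microscopy images. Matrix size alone does not determine resolution: iterative
and learned reconstructions trade noise suppression against smoothing, so the
package measures resolution directly, by blur fitting against a known ideal
image, and summarizes each operating point by the lowest SNR at which nominal
resolution survives.

## Phantom and forward model

The simulation object is a 2-D partial-volume phantom: a solution-filled
container (signal 1) with embedded zero-signal structures — circles of
diameter 2–40 px and a 50 px square — surrounded by zero background. The
phantom is rasterized on a grid `supersample` times finer (default 8, i.e. a
4096² intermediate image for the 512² default) and block-averaged down, so
edge pixels carry fractional values and every reconstruction sees realistic
partial-volume edges. Circles include their boundary (ties rasterize inside);
squares use half-open intervals so integer-aligned edges are exact.

Structure coordinates are a frozen package default (the layout is part of
reproducibility, not a free parameter): nine structures for matrices of 384 px
and larger, with reduced seven- and six-structure layouts for 128 px and 64 px
matrices where the two largest structures cannot satisfy the spacing
invariants (≥ 4 px gaps, ≥ 4 px clearance to the container edge). All layouts
keep the 20 px circle, the representative structure for resolution fitting.
The container is a centered square covering 0.72 of the field of view, which
leaves room for background ROIs in the image corners.

k-space is the unitary centered 2-D DFT of the phantom (DC at index (N/2,
N/2)). Unitarity gives noise calibration a closed form: complex Gaussian
noise of per-channel standard deviation σ added in k-space arrives in the
image domain with the same σ, so a target image SNR of `s` requires
σ = S_target / s, with S_target the mean ideal signal over the signal ROI
(1 by construction). SNR is always measured on magnitude images with the
Rayleigh correction `SNR = sqrt(2 − π/2) · mean(signal ROI) / std(background
ROI)`; the background of a magnitude image is Rayleigh-distributed with
standard deviation σ·sqrt(2 − π/2), so the corrected ratio recovers S/σ.
Monte-Carlo checks in the test suite confirm the calibration lands within a
few percent of the nominal levels 4–100.

## Sampling masks

All masks fully sample a central calibration disk (radius 30 index units at
N = 512) and draw the remaining budget without replacement from outside-disk
points with probability ∝ ρ: uniform (pattern 1) or Gaussian
ρ ∝ exp(−(k_x² + k_y²)/(2σ_s²)) with (k_x, k_y) normalized to [−1, 1] per
axis and σ_s = 2 (pattern 2) or σ_s = 4 (pattern 3). Pattern 2 is therefore
the most center-weighted of the three. The acquired-point count is exactly
round(N²/AF), with the disk counted toward the budget, so the nominal
acceleration factor equals the true scan-time reduction. Weighted sampling
without replacement uses the Gumbel top-k construction, which is exact and
deterministic given the seed.

At reduced matrix sizes the calibration radius scales with N
(round(30·N/512)); keeping the absolute radius would make AF ≥ 6 infeasible
at N = 128 and starve the self-supervised data split of drawable points.

## Reconstruction methods

**Zero-filling** — inverse transform of the masked k-space; the
artifact-laden baseline.

**L1-wavelet compressed sensing** — minimizes
½‖M∘(Fx − y)‖² + λ‖Ψx‖₁ with Ψ an orthonormal Daubechies-4 decomposition
(4 levels, periodic extension) and λ = 2×10⁻³ on data normalized so the
zero-filled magnitude maximum is 1 (λ is meaningless without a stated data
scale). Both F and Ψ are unitary, so proximal gradient steps of size 1 are
admissible and the prox is exact complex soft-thresholding. The solver is
monotone FISTA; the objective trace is non-increasing by construction and is
checked against an independently coded over-iterated accelerated proximal
solver from multiple initializations (1e-6 relative agreement on toy
problems). Defaults: 200 iterations, stop at relative iterate change 1e-6.
The large simulation grids use 80-100 iterations with tolerance 1e-5: near
the beta = 1 crossings the fitted resolution changes by only ~1-2% beyond 80
iterations, far inside the stochastic spread of the estimate.

**Zero-shot self-supervised unrolled reconstruction** — a scan-specific
method: no external training data, only the one scan's k-space. The acquired
set Ω is partitioned Ω = Θ ⊔ Λ ⊔ Γ (defaults: Γ = 20% of Ω, Λ = 40% of the
remainder, Θ the rest; the calibration disk is forced into Θ so the network
input always contains the low-frequency core). The network alternates a
residual CNN denoiser with a data-consistency (DC) solve for a fixed number
of unrolls; reference architecture: 10 unrolls, 5 residual blocks
(conv–ReLU–conv, output scaled by α = 0.1, skip connection), 64 filters of
3×3 kernels, a global skip around the denoiser, two real channels carrying
the complex image. DC solves (EᴴE + μI)x = Eᴴy + μz with E = mask∘F and a
single learnable μ (initialized 0.05, kept ≥ 1e-4); for single-coil
Cartesian data the system is diagonal in k-space, X(k) = (Y + μZ)/(1 + μ) on
acquired k and Z elsewhere. The public `dc_solve` runs conjugate gradients
(the multi-coil extension path; on this diagonal system CG is exact within
two iterations) and is tested against the closed form; training uses the
mathematically identical diagonal form.

Each epoch minimizes L_train = L(y_Λ, (F f(y_Θ))|_Λ) by Adam (learning rate
5×10⁻⁴) and monitors L_val = L(y_Γ, (F f(y_{Ω∖Γ}))|_Γ), where
L(u, v) = ‖u−v‖₁/‖u‖₁ + ‖u−v‖₂/‖u‖₂ — a scale-invariant mixed norm, so the
input normalization (zero-filled magnitude maximum scaled to 1) does not
change the loss landscape. The validation loss predicts the held-out Γ
samples from a reconstruction that used Ω∖Γ — the only self-consistent
reading of the loss pair. Early stopping defaults to best-validation
checkpointing with patience 20; the literal alternative rule (stop once
L_train > L_val for 20 consecutive epochs) is available but not the default,
because it can trigger spuriously in epoch 20 when the training loss sits
above the validation loss from the start. Final inference passes the entire
measured k-space through the trained network.

The network, backpropagation through the unrolls, and Adam are implemented
in numpy/numba (float32; im2col fallback without numba), which keeps every
forward and backward pass deterministic given the seed — the training
histories and reconstructions are bit-reproducible, and the analytic
gradients are verified against central finite differences in the test suite.

## Resolution estimation

The noise-free phantom is the ideal image W. A candidate blur
C(σ) = W * G(σ) is computed with a normalized Gaussian kernel
(replicate-edge handling; truncation at 8σ, beyond which a normalized
Gaussian contributes nothing at double precision — verified against a
brute-force wide-kernel convolution to 1e-6). The estimator minimizes the
sum of squared errors between the reconstruction magnitude and C(σ) over a
fitting window — by default a square of twice the structure diameter
centered on the structure, so each structure can be scored separately — and
reports spatial resolution β = 2σ (a Sparrow-criterion-style convention: two
points closer than β merge into a single plateau of the fitted PSF). The
reconstruction is first normalized by its mean over the signal ROI; no
amplitude or offset parameters are fitted. The SSE is unimodal in σ on
blur-recovery instances (checked on a grid), so a coarse geometric pre-scan
plus bounded scalar refinement finds the optimum; search bounds default to
[0.01, 20] px and boundary hits are flagged rather than raised. A numerically
zero SSE short-circuits to σ = lower bound (the reconstruction already equals
the ideal image). Recovery tests confirm σ within 2% for σ₀ ∈ {0.5, 1, 2, 4}.

Why β grows as SNR falls even for fully sampled data: the magnitude of a
noisy complex image is Rician, which lifts the dark structure interiors
toward σ√(π/2); matching that lift pushes the SSE optimum toward larger
blur. This is a property of magnitude MR images, not an estimator artifact.

For fits against an upsampled reference (factor f, e.g. bilinear doubling
before fitting small structures), the native-grid blur is σ′ = σ/f and the
resolution is 2σ′ · pixel size. Line profiles (bilinear interpolation along
a segment) support structure-visibility analyses on arbitrary images.

## SNR_L and the simulation grid

For each method × AF × pattern cell, β is estimated over seeded trials per
SNR level (reference grid 4, 6, 8, 10, 15, 20, 30, 50, 100; 10 trials; both
mask and noise redrawn per trial) and summarized by per-SNR mean and
population variance. SNR_L is the SNR at which the mean β-versus-SNR curve
crosses 1 px (the voxel size), linearly interpolated. Because SNR_L is a
guarantee threshold, the highest-SNR downward crossing is used when sampling
noise makes the curve locally non-monotone, so β ≤ 1 px holds for every
larger grid SNR. "NA" means β exceeds 1 px even at the top of the grid;
"<=min-grid" means resolution is preserved everywhere on it. In ordering
comparisons, NA sorts above any numeric limit (no crossing anywhere on the
grid is strictly worse than some crossing).

Seeds are derived per cell from a base seed and the cell coordinates (CRC
mixing, 31-bit); mask and noise seeds do not depend on the method, so
methods are compared on identical data. Grids are resumable: completed cells
persist as JSON records and are skipped on re-run.

## What the synthetic data does and does not emulate

The phantom reproduces partial-volume edges, calibrated Rician magnitude
statistics, variable-density Cartesian undersampling, and the
noise–acceleration–reconstruction interaction — the mechanisms the
resolution statistic responds to. It does not emulate anatomical texture,
B0/B1 inhomogeneity, eddy-current deviations of prospective sampling,
multi-coil encoding, or 3-D phase-encode geometry. Passing tests therefore
demonstrate correctness of the estimator and reconstructions under the
stated noise model, and transfer of the quantitative SNR_L values to real
acquisitions only to the extent those effects are secondary.

## Problem sizes used by the shipped runs

Chosen so the full suite and the acceptance script each run on a single CPU:

- Acceptance script (`scripts/acceptance.py`): full 512-px protocol for the
  CS branch — pattern 2, nine SNR levels, 10 trials per level, AF ∈ {2, 4},
  CS at 100 iterations (see above), β from the 20 px circle.
- Test suite: the CS lower-limit checks re-run the 512-px protocol with 3
  trials per level; the pattern comparison runs at 512 px with 2 trials on
  the upper SNR grid (at 128 px no pattern attains a β = 1 crossing, so the
  comparison is undefined there); the fully sampled baseline uses 10 trials
  at 512 px.
- The self-supervised branch runs a reduced protocol: 128-px phantom,
  calibration radius 8, 3 trials, coarse SNR grids, and a reduced network
  (5 unrolls, 2 residual blocks, 8 filters, ≤ 150 epochs). This preserves
  the method ordering (ZS-SSL < CS < zero-filled in β at matched cells) and
  the β–SNR trends, but a network and training schedule this small does not
  reach the reference architecture's resolution limits, so the reduced
  protocol's SNR_L values sit above the full-scale ones — the corresponding
  acceptance check documents this rather than hiding it.

## Known limitations

- Single-coil, 2-D Cartesian encoding only; the CG data-consistency path is
  the hook for a multi-coil extension, not a tested feature.
- The unrolled-network training at reference scale (512 px, 64 filters,
  hundreds of epochs) is impractical on one CPU; the package implements it
  faithfully but ships desk-scale defaults for its own test runs.
- SNR_L carries no confidence interval; it inherits the sampling noise of
  the β means it interpolates.
- The blur model is an isotropic Gaussian; anisotropic point-spread
  functions (e.g. from strongly anisotropic sampling) are fitted only in an
  average sense.
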