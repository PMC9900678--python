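# Methods

This note records the modeling assumptions, numerical choices and open
design decisions behind the package, in the spirit of a simulation study's
methods section. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Forward model

**Physics.** Light propagation is modeled by the frequency-domain diffusion
approximation on a 2D disk: −∇·(D∇Φ) + (μa − iω/c)Φ = S₀ with
D = 1/(3(μa + μs′)). The diffusion approximation is valid when scattering
dominates absorption (μs′ ≫ μa), which holds across the sampled property
ranges except at the extreme low-scattering corner (μs′ → 0.05 mm⁻¹); data
generated there are kept, since a learned reconstructor should see the
model's full behavior envelope.

**Units.** Lengths in mm, time in ns: ω = 2π·f·10⁻³ rad/ns for f in MHz,
and c = 299.792458/n mm/ns with tissue refractive index n = 1.4 by default
(configurable). With these units ω/c is commensurate with μa, as it must
be.

**Boundary and source model.** Robin condition Φ + 2AD ∂Φ/∂n = 0 with
A = 1 (no refractive-index mismatch correction; A is a configuration
field). Each source is an isotropic unit point load placed one transport
length 1/μs′ (background) radially inside its rim position — the standard
reduction of a collimated surface source. Detectors read the nodal complex
fluence at the other m−1 rim positions; amplitude = |Φ|, phase = arg Φ ∈
(−π, π].

**Discretization.** Linear (P1) triangles. The disk is meshed from
concentric node rings triangulated by Delaunay (exact for a convex domain);
inclusion circles carry their own node rings (≥ 12 edges) so property
discontinuities fall on element edges. When the acquisition layout m is
known, all ring node counts are rounded to multiples of m with a rim node
at every acquisition angle and a mesh node at every source point: sources
and detectors are then represented exactly, and the node set is mirror
symmetric about every source axis, which keeps homogeneous-disk
measurement rows symmetric to ≪ 1%. Assembly uses exact integrals of
linearly interpolated coefficients (third-order shape-function products for
the mass term), and one sparse complex LU factorization per phantom is
reused for all m sources and m adjoint solves.

**Verification.** The solver is checked against the 2D infinite-medium
kernel Φ = (1/2πD)·K₀(kr), k = √((μa − iω/c)/D), with a *centred* source:
at mid-radii (10–20 mm from the source of an 80 mm disk) the boundary's
influence is negligible and agreement is within 5% at moderate resolution,
improving under refinement. A rim source sits ~2 mm under the boundary,
where the Robin condition suppresses the field by far more than 5% within
10–20 mm — that configuration tests the boundary model, not the kernel, so
the kernel oracle deliberately uses the interior source. Reciprocity holds
to machine precision because the discrete operator is symmetric.

## Synthetic phantoms and datasets

Study conditions (all uniform draws): diameter 60–150 mm; modulation
frequency 10–100 MHz; background μa ∈ [0.005, 0.03] mm⁻¹ and
μs′ ∈ [0.05, 3] mm⁻¹; one or two circular inclusions (44:55 mix) with radii
2.5–15 mm (clamped to fit with a 2 mm rim margin and ≥ 1 mm separation),
centers uniform over the admissible disk, and per-coefficient contrast
uniform in [1.2, 4]× background — spanning barely-visible to strongly
absorbing/scattering lesions. Ground truth is rasterized on the phantom's
bounding square at 64×64 by pixel-centre membership (no anti-aliasing);
pixels outside the disk are zero.

Measurement noise is 15% relative: amplitudes are scaled by (1 + ε),
ε ~ N(0, 0.15²) i.i.d.; phases receive additive noise with standard
deviation 0.15×std(phase) over the sample, since phase is an angle and has
no natural multiplicative scale. Noise is applied to raw (physical) data.
Min-max normalization statistics for the two input channels and the two
target channels are computed on the 85% training split only and applied
frozen (with clipping to [0, 1]) to validation and test.

What the generator does **not** emulate: instrument calibration errors,
detector responsivity differences, fiber-coupling variability, non-circular
lesions, 3D effects and model mismatch between data generation and
inversion beyond mesh differences. Passing tests therefore demonstrate the
pipeline's behavior under the stated simulation conditions, not clinical
performance.

Dataset meshes use a target edge of diameter/16 (≈ 200–600 nodes): forward
accuracy at that resolution is a few percent at the boundary, well below
the injected 15% noise, and keeps a 2000-sample generation run at about a
minute of CPU.

## Tikhonov–Newton baseline

The measurement vector stacks log-amplitude and phase (the real and
imaginary parts of log Φ at the detectors), the standard well-scaled
parameterization in FD-DOT. The Jacobian with respect to nodal (μa, μs′)
is assembled by the adjoint method — dΦ_sd/dp = −Φ_s'·(∂K/∂p)·Φ_d with the
detector adjoint field obtained from the same LU factorization — and is
exact for the discrete model (finite-difference agreement to ~10⁻⁸ on
coarse meshes). The D-channel sensitivity maps to both coefficients via
∂D/∂μa = ∂D/∂μs′ = −3D².

Each Newton step solves the stacked least-squares system [J; λL] with
L = I; λ defaults to 0.1·√(max diag JᵀJ) from the first iteration and stays
fixed. Steps are damped by halving (≤ 10 times) until the data misfit
decreases, so the objective sequence is non-increasing by construction;
iteration stops at `max_iter` (10), at a relative objective drop below
10⁻⁴, or when no halving helps ("stalled" status). Properties are clipped
to small positive floors after each step. Nodal results are interpolated
to the 64×64 raster barycentrically. The inversion mesh is deliberately
coarser than (and distinct from) the data-generation mesh to avoid inverse
crimes.

## The reconstruction network

**Architecture.** Input (2, m, m−1): normalized amplitude and phase as two
channels of an image whose rows are sources and columns detector offsets.
Modules:

* *feature*: two 3×3, 8-channel convolutions (each conv → batch norm →
  ReLU);
* *efficient* (×2): four parallel blocks of 1×1 → 3×3 → 5×5 same-padded
  conv-BN-ReLU stages, concatenated on channels; the two modules are joined
  by a concatenation skip;
* *escalate*: a 2×2 stride-2 valid convolution branch (BN+ReLU) and a 2×2
  stride-2 max-pool branch, concatenated to exactly 24 channels at spatial
  size ⌊m/2⌋×⌊n/2⌋ — the only spatial reduction before reconstruction;
* *encompass*: flatten → dense 64 → 128 → 256 → 4096, each with BN+ReLU;
* *output*: the 4096 vector reshaped to one 64×64 code map, then a 5×5
  convolution to the two property channels with a final BN affine.

A parameter-free 2× nearest-neighbor *upsample* module supports cyclic
weight-shared reuse of the second efficient module (upsample → efficient →
pool per extra cycle, adding computation but no parameters, `n_cycles`
configurable). The default is a single pass: on the scaled-down problem
sizes used here the extra cycles quadruple the convolution cost without a
measurable benefit at fixed epochs, and parameter counts are unaffected
either way.

**Width reconciliation.** The published per-layout trainable counts pin
down the architecture tightly: the layout-dependent count differences
factor uniquely as 64·24·Δ(⌊m/2⌋⌊n/2⌋), fixing one 2× reduction, 24
escalate channels and a 64-unit first dense layer; subtracting the dense
chain leaves exactly 69,124 trainable parameters and 402 batch-norm
channels for the convolution stack. `reconcile_widths` enumerates the
block widths meeting both budgets exactly and selects deterministically
(widest narrowest layer, then fewest multiply-accumulates, then
lexicographic): efficient widths (5, 5, 2) and (46, 34, 2), an 8-channel
escalate convolution, and a 5×5 output convolution with BN. The resulting
totals — 1,258,308 / 1,310,532 / 1,642,308 trainable and 9,892
nontrainable — are asserted in the test suite.

**Training.** Adam (lr 10⁻³, β₁ = 0.5, β₂ = 0.999), batch 64, decoupled
weight decay 10⁻⁴, 20 epochs, MSE on normalized targets; He-uniform
initialization; batch-norm momentum 0.1. One non-default choice: the final
BN affine is initialized to the training targets' per-channel mean and
standard deviation. Without it the first ~10³ Adam steps are spent
rescaling the output distribution (the entire 20-epoch budget at these
problem sizes); with it, optimization starts at the constant-mean predictor
and spends its steps on structure. The affine remains fully trainable.

**Capacity note.** Both property maps derive from a single 64×64 code via
one 5×5 convolution, so the two output channels are constrained to share
spatial structure — appropriate for phantoms whose μa and μs′ lesions are
co-located, and the reason arbitrary uncorrelated channel pairs cannot be
memorized exactly (the memorization test uses channel-coupled targets).

**Engine.** Layers are implemented in numpy (float32, channels-last;
convolution as per-tap GEMM over an im2col buffer). Every layer keeps its
forward caches on a stack, so shared modules may be applied repeatedly and
backpropagated in reverse order. Gradients are validated against central
finite differences in float64. Max-pool gradients split ties evenly, which
matters only for the upsample→pool cycle where window entries are equal by
construction.

## Metrics

MSE, PSNR = 10 log₁₀(max²(x_true)/MSE) dB, and a *global* SSIM — one
mean/variance/covariance triple per image, c₁ = (0.01)², c₂ = (0.02)² on
the [0, 1] scale, sample statistics (ddof = 1). With these conventions the
global value coincides (to 10⁻⁶) with a uniform-window reference
implementation whose window spans the whole image, which the tests use as
an external oracle. Per-sample evaluation maps each channel pair to [0, 1]
by the ground-truth image's min–max range before SSIM/PSNR; physical-unit
MSE is reported alongside. The per-split report carries mean/min/max
aggregates, including the maximum per-sample SSIM used as the headline
comparison statistic.

## Problem sizes

The scaled-down study run by `scripts/acceptance.py` and the acceptance
test uses 2000 samples (85/10/5 split), the 16×15 layout, 15% noise and the
full 20-epoch recipe — one fifth of the full study's 10,000 samples, chosen
so the entire pipeline (generation ≈ 1 min, training ≈ 12 min on one core)
completes in a single sitting while leaving the training recipe untouched.
Unit tests use far smaller meshes and datasets, sized only to make their
assertions sharp.

## Known limitations

* 2D geometry and circular inclusions only; no time-domain or CW modes.
* The diffusion approximation degrades at low μs′/μa ratios; no transport
  correction is applied.
* The TR baseline uses a fixed λ and identity regularization; no spatial
  priors or λ scheduling.
* Detector readings are point samples (no aperture integration).
* Training at these scaled-down sizes underfits relative to the full
  10,000-sample study; reported aggregates should be read accordingly.
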