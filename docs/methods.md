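# Methods

## The hand space and stimulation model

The stimulus domain is a 2D Cartesian hand space spanning ±12 arbitrary
units on both axes. The x-axis (between-digit dimension) is divided into
6 equal segments of width 4 — D1, D2, D3, D4, D5, Palm from `x_min` to
`x_max` — and the y-axis (within-digit dimension) into 3 equal segments of
width 8 — P1 (distal), P2 (proximal), Palm. Segments are half-open
intervals; the right edge of the space belongs to the last segment, so
every coordinate has exactly one label. The orientation (D1 at `x_min`,
P1 at `y_min`) is a recorded convention used consistently everywhere.
Profiles are evaluated on a 41×41 endpoint-inclusive grid (odd, so the
origin is a grid point); the resolution is configurable.

A phase-encoded run steps through the locations of one dimension in
forward or backward order, 8 s per location at TR 2 s, for 8 cycles —
192 time-bins for a between-digit run, 96 for a within-digit run. A
location's aperture is an axis-aligned band covering its segment and the
full orthogonal extent, because the paradigm stimulates the phalanges of
one digit together (between-digit) or one phalanx row of all digits
together (within-digit). The sub-second on/off microstructure of the
tactile stimulation within a block is not modelled; each block is a
constant-on boxcar at TR resolution.

## pRF models and the forward model

Per voxel, neuronal sensitivity over hand space is either a Gaussian
ellipse (centre x₀, y₀; widths σ_x, σ_y; amplitude β_e ≥ 0) or a
difference-of-Gaussians (DoG) ellipse: the excitatory Gaussian minus an
inhibitory Gaussian with widths (σ_x+σ_d, σ_y+σ_d) and amplitude β_i ≥ 0,
giving centre-surround structure. Widths are σ values (not FWHM) and are
bounded to [0.5, 24] units; σ_d to [0, 24]; centres to the space.

The neuronal drive at time-bin t is the mean of the profile over the
active aperture's grid points. Normalizing by the active-point count
makes between- and within-digit runs comparable in amplitude. Note a
geometric consequence of band apertures: integrating over the full
orthogonal axis weights the surround by its full width, so a DoG whose
inhibitory *volume* exceeds the excitatory volume (suppression index
SI > 1) can produce a net-negative drive at its own preferred location.
This is faithful to the paradigm, and it is why surround strength is
summarized by the volume-ratio SI rather than by the profile peak.

Hemodynamics maps drive to BOLD through one of two interchangeable models:

- **Double-gamma HRF** (default; linear): canonical kernel (peak ~5 s,
  undershoot ~15 s, ratio 1/6), normalized to unit net integral so a
  sustained unit drive settles at gain 1. Because the drive is piecewise
  constant per TR, the kernel is pre-convolved with a TR-wide box on a
  10 ms grid and sampled at TR, making the TR-resolution convolution
  exact.
- **Balloon model** (nonlinear, biophysical): the
  signal–flow–volume–deoxyhemoglobin ODE system integrated by Euler steps
  at 10 ms and sampled at TR. Defaults are the standard hemodynamic prior
  means used in dynamic causal modelling (κ = 0.64 s⁻¹, γ = 0.32 s⁻¹,
  τ = 2.0 s, α = 0.32, E₀ = 0.4, V₀ = 0.02), under which its impulse
  response correlates 0.95 with the double-gamma kernel at TR 2. The
  Balloon path exists for fidelity checks; estimation uses the linear
  kernel, which is what makes simulate/fit consistency exact.

Both the generator and the estimator call the *same* forward model, so a
fit to noiseless self-generated data must reproduce the series to
numerical tolerance (verified: r > 0.999 with exact parameter recovery).

## Synthetic data

The generator emulates the target acquisition: 1-mm voxel strip with
digit identity monotone along the anatomical axis, four runs
(between/within × forward/backward), i.i.d. Gaussian noise per TR plus a
linear drift (AR(1) optional). Both dimensions are simulated by default
because a 2D pRF is not identifiable from one dimension alone: a
between-digit aperture spans the full y-extent, so (y₀, σ_y) enter its
drive only as a multiplicative gain confounded with β_e.

Default layout: 6 digit blocks × 20 voxels; centres at the segment centre
with 0.5-unit jitter (clipped so the generating digit never changes);
y-centres near 0 with 1.5-unit jitter; widths log-normal around
σ_x = 2.5, σ_y = 4 (sd 0.25 log-units) — an elliptical pRF elongated
along the within-digit axis, matching the regime of interest; β_e = 1,
baseline 0. Noise is set either directly or via temporal SNR
(std(signal)/noise_sd); recovery benchmarks use SNR 2, a realistic 7 T
single-voxel regime. Participant ensembles for overlap statistics place
each participant's digit territories on a shared strip (20 voxels per
digit), displacing territory centres between participants by Gaussian
jitter; each voxel joins the nearest centre, so per-participant maps
always partition the strip.

What the generator does **not** emulate: spatial noise correlations,
physiological (cardiac/respiratory) noise, motion, hemodynamic
variability across voxels, and anatomical geometry beyond a strip.
Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the stated noise model, not robustness to all
properties of real 7 T data.

## Phase encoding

Reference 0 is a boxcar responding to the first TR of each cycle,
circularly convolved over the cycle with a single-gamma kernel (shape 6,
scale 1 s; peak ~5 s — the paradigm fixes no kernel, this is exposed in
the API). References k = 1..(cycle/TR)−1 are circular shifts by k TRs;
winner-take-all assignment maximizes Pearson correlation, ties broken
toward the smaller lag (deterministic). Voxels whose maximum correlation
does not exceed 0.25 are excluded; the threshold applies to the per-voxel
maximum. Zero-variance voxels are excluded with a logged warning.

Backward lags are mapped into the forward convention as
(C − lag) mod C (C the cycle length) and combined with the forward lag by
circular mean — lags are phases, and arithmetic averaging breaks at the
wrap-around. Because references are onset-locked while the backward
reversal maps block *centres* onto block centres, the combined lag sits
up to half a block after the forward lag; this offset is constant across
voxels, so digit windows (lag ÷ 8 s) and lag ordering are unaffected.
Noiseless digit recovery is exact (100%) and per-digit mean lags are
strictly monotone along the hand.

## Estimation: MAP + Laplace evidence

Full variational inference is replaced by MAP optimization with a Laplace
approximation to the log model evidence — the same model-comparison
semantics (evidence differences ≈ log Bayes factors, |ΔF| < 3
indeterminate) at far lower implementation risk.

Bounds are enforced by smooth reparameterization so the optimum is
interior and the Hessian there is meaningful: centres via
`mid + half·tanh(u)`, widths via logistic maps onto their ranges,
amplitudes via `exp(u)`. Priors (on the natural scale, with
change-of-variable terms included in the latent-space posterior):
centres N(0, 12²) — sd half the space range, centred on the origin;
log-widths N(log 4, 1²) (around the segment width); σ_d half-normal(6);
log β_e N(0, 2²); log β_i N(−1.5, 2²); per-run baseline and drift
N(0, 10²); log noise-sd N(0, 2²). The noise sd is a free parameter with
a Gaussian likelihood.

Fitting one voxel: a coarse grid search over (x₀, y₀, isotropic σ) —
11 × 5 × 4 nodes by default, one least-squares solve for amplitude,
per-run baseline and drift per node, amplitude constrained non-negative
(a node whose unconstrained amplitude is negative is scored at β = 0;
otherwise surround-dominated data seeds fits at the anti-phase location)
— then L-BFGS in two stages: shape/amplitude/trend parameters with the
noise scale fixed, then joint refinement. The staging matters on
near-noiseless data, where letting the noise scale collapse first freezes
the shape parameters in a local optimum. DoG fits run a deterministic
two-start (weak- and strong-surround seeds) and keep the better optimum.

Free energy: F = log-posterior at the MAP + (d/2)·log 2π − ½·log det H,
with H the numerical (central-difference) Hessian of the negative log
posterior in latent coordinates, eigenvalues floored at 1e-8 before the
log-determinant. The posterior model probability against an
intercept+drift-only null is sigmoid(F_model − F_null). Forward and
backward runs are fit jointly with run-specific baselines and drifts.

Everything is deterministic: the same series always yields the same fit.

Calibration, measured by the test suite: pure-noise voxels pass the
0.95 posterior-probability screen in ≤ 5% of 200 replicates;
Gaussian-generated data essentially never receives a dog verdict (the
extra DoG parameters are unidentifiable there, so ΔF sits in the
indeterminate band — the evidence penalizes unused complexity);
DoG-generated data with β_i/β_e ≥ 0.5 is flagged dog-or-indeterminate in
≥ 80% of voxels.

Known limitation: for strongly surround-dominated voxels (SI well above
1) the DoG *parameter* posterior is multimodal and the optimizer can land
in a mirrored mode with poor parameter recovery even though the
model-comparison verdict is correct. Hemodynamic parameters are fixed
during fitting; joint neuronal+hemodynamic estimation is out of scope at
this problem size.

## Somatotopy statistics

**Dice / MDR.** Digit maps are voxel sets; Dice = 2|A∩B|/(|A|+|B|)
(undefined, and an error, for two empty sets — empty digit maps must be
excluded upstream). The Dice matrix orders (participant, digit) rows
digit-major so same-digit blocks are contiguous. The map dominance ratio
is the mean intradigit block Dice over the mean interdigit block Dice,
using cross-participant entries only in both — same-participant entries
are excluded (the diagonal is 1 by definition and would inflate the
numerator). Zero interdigit overlap returns an infinite sentinel with a
warning. The permutation null shuffles digit labels independently within
each participant, preserving per-participant map sizes;
p = (1 + #{null ≥ observed}) / (1 + N) is never exactly zero.

**Suppression index.** SI = β_i(σ_x+σ_d)(σ_y+σ_d) / (β_e σ_x σ_y), the
inhibitory-to-excitatory Gaussian volume ratio; invariant to common
amplitude rescaling; requires a DoG fit with β_e > 0.

**Volumes, distances, coverage.** A voxel's digit for volume/overlap
statistics is the x-segment of its fitted pRF centre (a flag allows
phase-encoding labels instead); only voxels with posterior model
probability > 0.95 enter summary statistics. Relative volumes are label
fractions (sum 1). Peak distances take each digit's highest-free-energy
voxel and normalize 3D anatomical distances from the D1 peak by the
D1→Palm distance. Coverage maps sum profiles per participant (negative
DoG surrounds floored at 0 — display semantics only), scale to max 1,
average across participants, and rescale to max 1.

**Correlations and paired tests.** Width–volume relations use Pearson r
with a seeded percentile bootstrap CI over paired resamples (5000 by
default). The paired test reports the paired t statistic with a wild
bootstrap null over participants: differences are centred, multiplied by
Rademacher signs per resample, and re-studentized. The wild bootstrap is
used instead of naive case resampling because at n = 9 participants the
resampled-t null is markedly heavy-tailed (measured type-I ≈ 0.02 at
α = 0.05), while the wild null is calibrated (measured type-I within
[0.03, 0.07] over 1000 replicates) and still reaches p = 1/(1+B) for
large effects. Averaging hierarchy for per-digit pRF widths: voxels →
participant → group.

## Problem sizes used by the verification suite

Parameter recovery: 60 voxels (10 per digit) at SNR 2, four runs.
Model recovery: 18 voxels per generating model. Null calibration:
200 pure-noise fits; 200 replicate label-free Dice matrices at 199
permutations; 1000 paired-test replicates at 1000 bootstrap samples.
The acceptance script uses the same computations at comparable sizes,
all seeded from its `--seed` argument.
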