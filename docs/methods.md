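# Methods

This note records the models implemented in `hiergrad`, their
assumptions, the defaults and why, and what the synthetic generator
does and does not emulate.

## Connectivity gradients

A scan's connectome is the N × N Pearson correlation of parcel
timeseries. Sparsification keeps, per row, the k = round(density·(N−1))
largest strictly positive off-diagonal entries (density 0.10 by
default; ties at the retention boundary drop the larger column index
first; the diagonal never counts). The sparsified matrix is left
asymmetric; symmetry is restored by taking the cosine similarity of
sparsified row profiles, which also confines entries to [0, 1] since
retained entries are positive.

Diffusion embedding uses the anisotropic normalization
W′ = D^−α W D^−α with α = 0.5 (half-density correction: the embedding
is less sensitive to node degree than the raw random walk, without
fully factoring density out as α = 1 would). The Markov matrix
P = D₁⁻¹W′ is diagonalized through the symmetric conjugate
S = D₁^−1/2 W′ D₁^−1/2, so eigenvalues are real by construction and
the trivial stationary eigenvector (λ = 1) is discarded exactly.
Components are the right eigenvectors of P normalized against the
stationary eigenvector (unit norm under the stationary distribution).

**Component scaling.** Two conventions are implemented and recorded in
the result's provenance: λ/(1−λ) (the default, matching the common
diffusion-map implementation's `diffusion_time = 0` convention) and
plain λ (diffusion time t = 1). The choice is irrelevant to template
alignment, parcel-wise contrasts, spin tests, and PLS (all are
invariant to positive per-component rescaling within a scan), but it
matters for the *gradient range*: λ/(1−λ) amplifies the component
exactly when the spectral gap closes, which is what lets a genuine
loss of segregation appear as range compression. Under the t = 1
convention the range is nearly insensitive to the strength of the
hierarchy (λ₁ sits close to 1 for any sparse affinity), and planted
compression is invisible; this was established numerically during
design and is why λ/(1−λ) is the default.

Degenerate eigenvalue pairs (gap < 1e−10) are flagged; alignment
proceeds by |r| regardless. Group templates come from the element-wise
mean connectome put through the identical affinity + embedding
procedure; the principal/secondary templates are components 1 and 2,
oriented so the largest-magnitude parcel is positive. Per-scan
alignment is greedy without replacement: the principal template claims
the component with maximal |Pearson r|, the secondary the best
remaining; negative correlations flip the component's sign; |r| below
0.1 sets a warning flag, never an error.

## Group statistics

The paired drug contrast fits, per parcel,
`gradient ~ condition + covariates + (1 | subject)` by REML. For a
single random intercept the REML criterion is a one-dimensional
function of the variance ratio ψ = σᵤ²/σₑ²; for fixed ψ the GLS
estimate and profiled σₑ² are closed-form via per-cluster Woodbury
inversion, so the fitter is a deterministic bounded scalar
minimization (statsmodels MixedLM is the cross-check oracle in the
tests, not the implementation — one LME per parcel plus Monte-Carlo
batteries need the speed, and the closed-form route reproduces the
paired t-test exactly in the one-scan case). Degrees of freedom use
the residual method (n − p), recorded per parcel. Continuous
covariates are centered; categorical covariates are one-hot with the
first sorted level dropped. Cohen's d is the paired d of per-subject
condition means (mean difference / SD of differences). FDR control is
Benjamini–Hochberg step-up at q = 0.05.

The two-group contrast (for large single-visit cohorts) is ordinary
least squares per parcel, vectorized across parcels, with the group
term's Wald t and either FDR or an uncorrected p < 0.001 mode; a
categorical covariate level present in only one group raises a
confound warning.

The compression summary reports the (min, max) range of the
cohort-mean principal gradient per condition, the MP/PL range ratio,
the cross-condition Pearson R, and mean shifts per network. The
related diagnostic `significance_gradient_coupling` correlates |t|
with the placebo-mean gradient; the convention (|t|, not a thresholded
map) is labeled because alternatives exist.

## Spin test

Rotation nulls operate at parcel level: a uniform random rotation is
applied to left-hemisphere centroids and its x-mirrored image
(M R M, M = diag(−1, 1, 1)) to the right; each parcel takes the value
of the nearest original centroid (great-circle distance, within
hemisphere), i.e. a permutation with replacement that preserves
spatial autocorrelation. Subcortical parcels have no spherical
coordinates and are excluded from spinning and from the correlations.
The first map argument is spun against the fixed second map (the
asymmetry is intentional and documented at the call site). P-values
use the add-one rule p = (1 + #{null ≥ r_obs})/(1 + n_perm), one-sided
on r by default (the 95th-percentile criterion) with a two-sided |r|
option; the default n_perm is 10,000.

## PLS prediction

Predictors are full parcel-wise gradient maps, one row per subject
(scan-level maps averaged within subject). X columns and y are
z-scored with training-set statistics only; inside leave-one-out each
fold standardizes on its own training subjects — the left-out row
never touches the fold's standardization or fit (verified by mutation
testing). Fitting is NIPALS deflation (scikit-learn backend);
predictions with j < k components use Bⱼ = Wⱼ(Pⱼᵀ Wⱼ)⁻¹ qⱼᵀ from a
single k-component fit, so LOO over all component counts costs one
fit per fold. k is selected by minimal LOO RMSE with ties toward
smaller k; the study-replication default is k = 2. Explained variance
is reported both for y (incremental R² per component) and X (score ×
loading energy), since conventions differ. Cross-condition transfer
reuses the training standardization on the other condition's maps.

## PET kinetics

Both models assume one-tissue kinetics for target and reference with a
common (never observed) plasma input, and decay-corrected frames.

The SRTM forward model is
C_t(t) = R1·C_r(t) + (k2 − R1·k2a)·(C_r ∗ e^(−k2a·t)), k2a = k2/(1+BPnd),
evaluated by FFT convolution on a uniform fine grid (dt = 0.01 min,
trapezoid end-correction; halving dt moves fitted BPnd < 0.5%) through
a piecewise-linear continuous curve anchored at (0, 0), then averaged
over frames. The basis-function fit solves the linear subproblem in
(R1, φ = k2 − R1·k2a) on a grid of 100 log-spaced k2a ∈ [0.01, 1]
min⁻¹ and then refines the best k2a by a bounded search between its
grid neighbors (the raw grid's ~4.8% spacing would otherwise consume
most of the 2% BPnd accuracy budget). BPnd at the grid boundary sets a
warning; BPnd < −0.5 is rejected as non-physical.

Logan reference analysis regresses ∫₀ᵗC_t/C_t on
[∫₀ᵗC_r + C_r/k2′]/C_t over frames with mid-time ≥ t* (default 20 min
for the 60-min scan; ≥ 4 frames required; running integrals by
trapezoid with a linear rise before the first mid-time). With the
correct reference clearance k2′ this relation is exactly linear for
one-tissue kinetics at *all* t — the slope is the DVR and
DVR = BPnd + 1 — so the default t* mainly guards against early-frame
integration error. Without k2′ the clearance term is omitted with a
warning; the slope is then biased for fast-clearing references. Under
5% frame noise the Monte-Carlo DVR bias measures slightly *positive*
(~+0.7% of DVR) in this setting, because 1/C_t noise scatters Logan
points along rays through the origin against the negative intercept;
the textbook downward attenuation requires integral noise to dominate.

ΔDA = BPnd(PL) − BPnd(MP), with a percent mode
100·(PL − MP)/PL; healthy-adult oral-stimulant regimes correspond to
10–20% D2R reductions, which is what the synthetic target tables
plant.

## Synthetic generator: what it emulates

Defaults are the study conditions: 438 parcels, 471 timepoints/scan, 3
scans per condition, 38 subjects, paired PL/MP design, planted MP/PL
hierarchy-spread ratio 0.6, timeseries noise σ = 0.05, 22 PET frames
over 60 min.

**Atlas.** Cortical centroids are a randomly rotated Fibonacci lattice
(quasi-uniform; nearest-neighbor spacing CV < 0.5), hemispheres split
by the x sign, ~10% of parcels subcortical without centroids, 12
network labels by bands of the latent axis.

**Cohort.** Each parcel carries (a) a hierarchy latent h and (b) fixed
transverse coordinates (its sphere centroid, weighted 0.4). Latents
are rank-uniform — an even grid on [−1, 1] ordered by the centroid z
coordinate — because a latent-density gap wider than the top-10%
neighborhood would disconnect the affinity graph. Subjects perturb the
latents by a small affine map (scale SD 0.05, shift SD 0.05) plus
parcel-level jitter (SD 0.02); each condition rescales them by its
spread. A scan is an independent draw of a Gaussian process across
parcels with covariance exp(−dist/ℓ), ℓ = 0.5, where dist combines
hierarchy and transverse distance, plus white noise.

The transverse geometry is essential, not decorative: the rank-based
top-10% sparsification makes the pipeline almost exactly scale-free
for any purely one-dimensional latent model (a uniform rescaling of h
leaves every retention decision, hence the embedding, unchanged up to
negligible reweighting — verified numerically during design). With
fixed local structure present, compressing the hierarchy reallocates
each parcel's strongest edges between along-hierarchy and local
neighbors, the spectral gap of the Markov matrix widens, and the
λ/(1−λ)-scaled gradient range shrinks. The transverse weight and
kernel length-scale were fixed by a one-off design experiment so that
the measured range ratio responds approximately one-to-one to the
planted spread ratio near the study's compression level (0.6); with
these frozen defaults the recovered ratio is ~0.63 ± 0.02 at 100
parcels and ~0.65 at 438.

**Targets.** y = Xw + ε with X the subject latent maps, noise scaled
to a chosen planted R². D1R couples to the hierarchy axis itself
(w = u, the smooth structured regime a 2-component PLS can recover);
D2R(PL) uses unstructured weights; D2R(MP) plants a uniform 10–20%
reduction per subject.

**Smooth maps.** Gaussian fields on the sphere with great-circle
exponential kernel (default length-scale 0.5 rad), for spin-test
calibration; subcortical entries are NaN.

**Reference TAC.** Gamma-variate C(t) = A(t/tp)^a e^{a(1−t/tp)} with
a = 0.7, tp = 12 min: a cerebellum-like curve that clears to ~20% of
peak by scan end. (An early-peaking gamma would decay to numerical
zero inside the window and make late-frame ratios meaningless.)

**What the generator does not emulate**, hence what passing tests do
not show about real data: hemodynamic response and autocorrelated fMRI
noise spectra, head motion and scrubbing, scanner and session effects,
network topology beyond one hierarchy axis plus isotropic local
geometry, trait-like stability of the secondary gradient (the human
finding that the *secondary* gradient predicts D1R has no synthetic
counterpart — the demo couples targets to the axis the generator
actually plants), voxel-level PET kinetics, plasma-input physiology,
and count-statistics PET noise.

## Numerical choices and degenerate inputs

Retention ties break deterministically (larger column dropped first);
rows without positive off-diagonal entries, constant timeseries,
disconnected affinity graphs, constant maps, zero-variance targets and
singular designs all raise named errors rather than propagating NaNs.
Eigenvalues requested outside (0, 1) refuse to embed. Centroids are
renormalized only when their norm deviates by more than 1e−12
(byte-stable round-trips otherwise). The orchestrator hashes the
analysis-relevant config (output directory excluded) into every output
table and is bit-reproducible for fixed inputs and seed.

## Problem sizes used in the validation batteries

Recovery batteries run at 100 parcels (compression: 50 replicates of
38 × 3 × 2 scans; spin calibration: 500 replicates × 1000 rotations;
PLS sanity: 200 permutations at n = 38) and at the full 438 parcels
where a single scan suffices (planted-axis recovery, 20 replicates);
kinetic recovery uses 200 noisy replicates on the 22-frame schedule.
These sizes keep the full suite's Monte-Carlo sampling error well
inside each criterion's tolerance band.

## Known limitations

The LME's residual-method degrees of freedom overstate precision for
between-subject terms (the within-subject drug term, the quantity of
interest, is calibrated — type-I error ≈ 0.05 in simulation). The
spin test assumes parcels tile the sphere reasonably uniformly;
strongly non-uniform parcellations would need area weighting. Logan
without k2′ is biased and only offered with a warning. The
compression range ratio is specific to the λ/(1−λ) scaling convention;
under t = 1 scaling ranges are insensitive to segregation strength by
construction.
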