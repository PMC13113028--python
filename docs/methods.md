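# Methods

## Model overview

The package composes three layers into a condition-to-comfort map
g*(v, N, Δt):

1. an **energy-transfer stimulus**: the friction energy a rotating,
   translating brush delivers to the skin in one stroke;
2. **Stevens' psychophysical power law** mapping stimulus energy to
   perceived magnitude;
3. a **bell-shaped comfort function** mapping perceived magnitude to a
   comfort value in (0, 1].

### Energy model

Skin friction follows a power law in the normal load, f = μN^m, with
the load exponent m in the 0.67–0.72 range reported for skin
tribology; the default is m = 0.7 and μ = 0.25 (nylon brush). The full
per-stroke energy budget is

    E = f·v₁·Δt  +  (2/3)·f·r·ω·Δt  +  N²l/(2Y₁A)  +  f²l/(AY₂)

(translation, rotation over ωΔt/2π revolutions at (4/3)πfr per
revolution, and normal/tangential elastic deformation of the skin).
The deformation terms are orders of magnitude below the friction terms
for elastic skin at the forces considered (≈5·10⁻⁶ J vs ≈10⁻¹ J at
1 N), and the brush rim speed is taken equal to the stroke speed
(v₂ = rω = v₁), giving the simplified stimulus used everywhere
downstream:

    E = (4/3)·v·μN^m·Δt.

Units are SI internally (m/s, N, s, J). All user-facing files and CLI
flags carry speed in mm/s and are converted exactly once at ingestion;
the model's natural operating range is therefore v ∈ [0.02, 0.05] in
m/s-scaled units for 20–50 mm/s strokes.

### Stevens layer

S = k·(I − I₀)^n with the absolute threshold I₀ = 0: contact with the
brush is the only stimulus source, so every nonzero condition is
suprathreshold. Calibration is ordinary least squares on base-10
logarithms, lg S = lg k + n·lg I; k is recovered as 10^intercept. The
calibration design is an 8 × 8 grid of forces
{0.1, 0.5, 1, 2, 3, 4, 5, 6} N and speeds 10–80 mm/s at Δt = 10 s (64
conditions); noiseless ratings generated from k = 2.88, n = 1.52
regress back to slope 1.52 and intercept 0.459 (lg 2.88).

Ratings of 0 ("no sensation") cannot be log-transformed and are
excluded from the fit with a logged warning; Stevens' law is a
suprathreshold model, so this is a domain restriction, not data
cleaning. Raw VAS scores (0–10 scale) are normalised by the scale
maximum 10. Pooled fitting is the default; a per-group (per-subject)
mean-slope variant is provided.

The extended condition-level model introduces sensitivity indices x
(speed) and y (force):

    S = c₀ · v^x · N^{m·y} · Δt^n,    c₀ = k·(4/3·μ)^n.

The printed form of this model absorbs the outer Stevens exponent into
x and y (they are not raised to n again); the implementation follows
that form exactly. c₀ evaluates to 0.5422 (≈ 0.54) for the default
constants. Two-decimal reference values derived elsewhere from the
rounded 0.54 differ from this package's exact-arithmetic results in
the fourth decimal; all internal oracles use exact arithmetic.

### Comfort function

    g(S) = exp(−π·|S^b − μ′|^a),   μ′ = (ln 2/π)^(1/a),  σ = 1/√(2π).

The constants μ′ and σ are *derived*, not free: requiring max g = 1
and g(0) = 0.5 fixes them, since exp(−π·μ′^a) = exp(−ln 2) = 1/2.
The peak sits at S* = (ln 2/π)^(1/(a·b)) ≈ 0.485 for the fitted
(a, b) = (1.04, 2.01). The base expression (S^b − μ′)^a is only real
for non-integer a when the base is non-negative; the implementation
uses |S^b − μ′|^a, a sign-symmetric decay that preserves the bell
shape. With a = 2, b = 1 the function reduces exactly to a Gaussian
with σ = 1/√(2π) rescaled to peak 1.

Numerical note: the identity (S*)^b = μ′ holds to machine rounding
only; with a < 1 the fractional power amplifies that rounding, so the
peak value is exact to ~1e-9 rather than 1e-15 for a < 1. Tests assert
accordingly.

## Parameter fitting

(x, y, a, b) are estimated from (N, v, g) observations by bounded
nonlinear least squares (scipy `least_squares`, trust-region
reflective) in which the model structure itself is the physics
constraint; (k, n, μ, m) stay fixed at their calibrated values. A
misprint elsewhere labels the SSE formula "R-square"; the package
reports both statistics with their standard definitions, SSE = Σ(ĝ−g)²
and R² = 1 − SSE/SST.

Design choices:

* **Bounds**: x, y ∈ (0, 10]; a ∈ [0.5, 3]; b ∈ [0.5, 4].
* **Multistart**: the SSE landscape has a wide plateau — large x or y
  push the surface to the neutral 0.5 everywhere — where local search
  stalls. The fitter therefore draws ≥ 64 Latin-hypercube candidates,
  pre-screens them by raw SSE, and polishes the best `n_starts`
  (default 8). Ties are broken towards the lexicographically smallest
  parameter vector, making the fit deterministic and invariant to
  observation order.
* **Seeding**: default seed 20221104 (arbitrary, documented); every
  RNG in the package flows from an explicit seed.
* The calibration design for the comfort surface is a 6 × 7 grid of
  forces 0.5–3 N (step 0.5) and speeds 20–50 mm/s (step 5), Δt = 10 s
  (42 conditions). Identifiability of the full 4-parameter set from
  this grid is not guaranteed — parameters can trade off — so the
  4-free-parameter claim tested is *surface* recovery (pointwise to
  1e-4), while exact index recovery (to 2 dp) is asserted for the
  2-free case with (a, b) fixed.

## Optimisation

The objective is (G − g*(v, N))² with G = 1 and Δt = 10 s (the
calibration stroke duration; configurable). A printed variant of this
objective circulates with constants (2.51, exponent 1.53, outer
square) inconsistent with the fitted model; the package defines the
objective through the fitted model itself.

PSO: 40 particles, 200 iterations, inertia w = 0.729,
c1 = c2 = 1.49445 (constriction-equivalent), positions clipped to the
box, deterministic given the seed. The global-best trace is monotone
non-increasing by construction and is cross-checked against a dense
grid search in the tests.

Because comfort depends on (v, N) only through S, the minimiser is the
1-D iso-comfort ridge S(v, N) = S*. It crosses the feasible box
(v ∈ [0.02, 0.05], N ∈ [0.5, 3]), so the attainable minimum is ≈ 0,
consistent with (and below) the reported optimum value 0.0018. Any
single reported (v, N) optimum is one of infinitely many minimisers;
`extract_iso_comfort_ridge` samples the full set by bracketed
root-solving of N at each v (S is strictly increasing in N). At
v = 0.04, the ridge force is N ≈ 1.896 under exact arithmetic.

## HRV metrics

Time domain: SDNN (population-n denominator by default, configurable
to n−1), RMSSD, and pNN50 with the strict inequality |ΔRR| > 50 ms.
Frequency domain: the RR tachogram is resampled to an even 4 Hz grid
by cubic-spline interpolation; Welch's method (120 s segments, 50%
overlap, constant detrend) estimates the PSD; LF = 0.04–0.15 Hz and
HF = 0.15–0.40 Hz band powers are trapezoid-integrated;
LFnorm + HFnorm = 100 by construction. The estimator (FFT vs AR vs
Lomb) and windowing are a free choice in this setting; Welch with
these Task-Force-conventional bands is the documented default. At
least 60 s of data are required for the spectral metrics.

## Synthetic data

The generators define the study conditions; they are pure functions of
(spec, seed).

* **VAS ratings**: noiseless rating = Stevens response to the
  simplified energy, rescaled so the strongest grid condition marks 10;
  additive Gaussian noise on the 0–10 scale (sd = 10 × `noise_sd`),
  clipped and rounded to the VAS resolution (default 0.1). The default
  `noise_sd` = 0.05 on the comfort scale is a placeholder — real
  inter-subject rating variance is unknown. The max-rescaling offsets
  the log-log intercept by lg(max S) while leaving the slope intact;
  intercept-recovery checks therefore run on unrescaled responses.
  The default 0.1-step rounding also quantises the weakest conditions
  toward 0, visibly distorting a log-log fit — realistic, and the
  reason calibration-quality studies need either finer marks or
  stronger minimum stimuli.
* **Comfort surfaces**: g_obs = clip(g*(cond) + N(0, noise_sd), 0, 1)
  over the 42-condition grid.
* **RR series**: RRᵢ = mean + A_lf·sin(2π·0.1·tᵢ) +
  A_hf·sin(2π·0.25·tᵢ) + white noise, amplitudes chosen so total
  variance matches the SDNN target (10% to noise by default) and the
  sinusoid variances have the requested LF/HF ratio. This additive
  two-sinusoid model exercises the HRV estimators; it is not a
  physiological cardiac model — no respiratory coupling, no
  non-stationarity, no ectopy — so passing round trips validate the
  estimators, not claims about real recordings. Likewise the rating
  generators draw i.i.d. Gaussian noise; real raters drift, adapt and
  differ systematically, so recovery results bound estimator quality
  under the stated noise model only.

## Problem sizes and limitations

The test suite and acceptance script run the designs at their natural
sizes (64- and 42-condition grids, 8 040 objective evaluations per PSO
run, 5-minute synthetic RR recordings), with replicate counts of 20–200
for statistical properties; everything completes in seconds.

Known limitations: parameters are calibrated for one brush material
and body region and are not transferable without recalibration; the
comfort function is symmetric in |S^b − μ′| (no asymmetric
discomfort); the fitted optimum is a ridge, so force/speed preference
along it must come from a second criterion (e.g. cleaning efficacy),
which is out of scope.
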