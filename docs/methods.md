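# Methods

## Model

A pulsed field gradient echo attenuates the signal of a species with
diffusion coefficient `D` as `S_i = S_0 exp(−b_i D)`, with

- rectangular gradient pulses: `b = γ² G² δ² (Δ − δ/3)`,
- half-sine pulses: `b = γ² G² δ² (Δ − δ/4)` with the effective gradient
  `G = (2/π) · G_peak`.

Units are strictly SI internally (T m⁻¹, s, m² s⁻¹, rad s⁻¹ T⁻¹); the
table reader and CLI convert G cm⁻¹ (1 G cm⁻¹ = 0.01 T m⁻¹). γ defaults to
the ¹H value (2.675 221 874 4 × 10⁸ rad s⁻¹ T⁻¹) and is overridable — the
expressions are nucleus-agnostic. Spatial gradient non-uniformity is
accommodated by replacing `G²` with a user-supplied power series
`Σ c_k (G²)^k`; no calibration coefficients are shipped because they are
probe-specific.

The model is a *single* exponential throughout. Multiexponential or
distribution fitting, peak picking, baseline correction and reference
deconvolution are out of scope; inputs are peak-amplitude decay tables.

## Sampling schemes

Gradients run from `κ·G_max` to `G_max` in `N` steps, equally spaced in `G`
(linear) or in `G²` (quadratic). In exponent units,

- linear: `ε_i = [κ + (i−1)(1−κ)/(N−1)]² · ε_max`
- quadratic: `ε_i = [κ² + (i−1)(1−κ²)/(N−1)] · ε_max`

Both start at `κ²·ε_max` and end at `ε_max`. κ defaults to 0.05; values
outside the common experimental range [0.05, 0.25] trigger a warning but
are allowed, since κ is a coherence-selection compromise, not a hard
constraint.

## Cramér–Rao resolution and the shape function

For Gaussian amplitude noise of standard deviation `σ_S` and the NMR
convention `SNR = S_0/(2σ_S)`, the lower bound on the diffusion resolution
of a two-parameter fit is

    R_D = 2·SNR·sqrt((A·C − B²)/A)

with `A, B, C` the `e^(−2ε)`-weighted sums over the schedule. `R_D` is
exactly linear in SNR, and `A·C − B² ≥ 0` by Cauchy–Schwarz (the
discriminant is clipped at 0 against rounding). `N = 1` is underdetermined
and returns 0 with a warning.

The relative resolution `f = R_D/(SNR·sqrt(N−1))` depends almost only on
`ε_max`, and is approximated by `f = a·ε_max·exp(−b·ε_max^c)`. The
parameters are fitted by **unweighted** nonlinear least squares (the
residuals are not normally distributed, so error bars on (a, b, c) would be
misleading) on exact CRLB values pooled over N ∈ {10, 17, 37, 65, 101,
197} and an `ε_max` grid of **0.1–3.0, step 0.05**, at κ = 0.05, from the
initial guess (0.7, 0.7, 0.8). The grid is confined to the rise-and-turnover
region of `f`: this is the regime the approximation is meant to serve, and
extending the grid deep into the tail (`ε_max` ≫ 3) lets the tail dominate
the pooled fit and drags the parameters away from values that describe the
useful region. At these settings the fit reproduces
(a, b, c) ≈ (0.70, 0.68, 0.80) linear and (0.65, 0.59, 0.90) quadratic.

Worst-case relative error of the approximation against the exact CRLB over
`ε_max ∈ [0.25, 3]`, N ∈ [10, 197] is ≈10% (at the extreme corner N=10,
`ε_max`=3); typical errors are a few percent.

The optimum sampling depth is the closed-form argmax
`ε_max* = (1/(b·c))^(1/c)` (from `d/dx [a x e^(−b x^c)] = 0`),
cross-checked by a grid search; for the linear-sampling fit it is ≈ 2.14 —
sample the decay roughly two e-folds deep. The per-`ε_max` slope of `R_D`
against the raw increment count peaks slightly later (≈ 2.2) because the
largest-N schedules peak at marginally deeper `ε_max` than the pooled
shape; the difference is well inside practical tolerance.

Note that `R_D` grows as `sqrt(N−1)`, not `N−1`: regressing CRLB values on
`sqrt(N−1)` at fixed small `ε_max` gives R² > 0.999, while regression on
`N−1` leaves visible curvature.

## Monte Carlo verification

`mc_resolution` builds the table `e^(−ε_i)` (true α = β = 1), adds Gaussian
noise of sd `1/(2·SNR)` per replicate, refits `α·e^(−βε)`, and reports
`R_D = 1/sd(β)` over the ensemble with a bootstrap standard error; the mean
per-fit `σ_β` is reported alongside as a diagnostic of the covariance-based
error (they agree to a few percent for SNR ≥ 50). Replicate noise streams
are spawned from a single seed so that replicate *i* is identical no matter
the total ensemble size; fits that fail to converge are counted, and more
than 1% failures aborts the run.

Fits run in the amplitude domain only (log-domain fitting would break on
noisy points that dip negative). Initial guesses come from an
amplitude-weighted log-linear regression on points above 3σ, falling back
to (max S, 1). Convergence: relative parameter tolerance 1e-10, ≤ 200
iterations. Ensemble fitting uses a vectorized Gauss–Newton solver with
step-halving that matches `scipy.optimize.curve_fit` to ~1e-8 (asserted in
the tests), keeping 10⁴–10⁵-replicate ensembles to seconds.

## Noise titration and the SNR ceiling

`titrate_noise` takes one measured decay of intrinsic noise SNR `snr_0`,
adds Gaussian noise of variance `s0²/4·(1/snr_t² − 1/snr_0²)` to reach each
target level `snr_t`, refits, and averages `R_D = β/σ_β` over (by default)
100 additions per level. `fit_snr_lim` then fits the single-parameter model

    R_D(snr) = SNR_eff(snr; SNR_lim) · sqrt(N−1) · f(ε_max)

and warns when the fitted ceiling is outside the titrated range (knee not
bracketed).

Two statistical facts matter when interpreting titrations:

1. `β/σ̂_β` with `σ̂_β` estimated from k = N−2 residual degrees of freedom
   is inflated on average by `E[1/sqrt(χ²_k/k)]` (≈ 1.084 at k = 10); the
   low-SNR limb of a titration therefore sits ~8% above the raw CRLB line
   for a 12-point decay. The tests assert against the inflated line.
2. The non-noise error of a *single* measured decay is one realization of
   a random contamination on only N points; the high-SNR plateau (and hence
   a fitted `SNR_lim`) varies by tens of percent between realizations.
   Parameter-recovery tests for `fit_snr_lim` therefore use titrations
   generated around the effective-SNR model itself
   (`simulate_titration_from_model`, scatter `0.28·value/sqrt(additions)`,
   the single-fit relative spread at 10 dof), where recovery bias is ~1%.

## Synthetic data

The generator produces exactly what the theory assumes: single-exponential
decays with additive, homoscedastic Gaussian amplitude noise of sd
`s0/(2·SNR)`, optionally plus an independent Gaussian floor `s0/(2·SNR_lim)`
emulating non-noise error sources. It does **not** emulate systematic,
non-random distortions (convection-induced decay shape changes, unwanted
coherence pathways, gradient miscalibration), peak overlap, or
heteroscedastic noise. Passing tests therefore validate the statistical
machinery under the stated noise model, not robustness to systematic
experimental artefacts — the latter enter only through the single lumped
parameter `SNR_lim`.

## DOSY spectrum construction

Each fitted peak contributes
`s0 · gauss(freq; ppm, σ_freq) · gauss(D; D̂, σ_D)` on a (chemical shift ×
diffusion) grid; the diffusion Gaussian is evaluated in linear `D` (σ_D is
a standard error in `D`), on a default log-spaced axis covering
[min D/10, max D·10] with 256 points. Gaussians are normalized to unit
apex, so an isolated peak's matrix maximum equals its fitted amplitude —
the display convention here; `normalization="area"` switches to unit-area
diffusion Gaussians (the diffusion integral of a height-normalized peak is
`s0·σ_D·sqrt(2π)`). The frequency lineshape is a stand-in Gaussian of
user-set width, since reconstructing the processed 1-D spectrum is out of
scope. Exported matrices list ppm descending, per NMR display convention.

## Problem sizes

Default analysis sizes: 354 pooled points for the shape regression
(6 N-values × 59 `ε_max` values); 10⁴ replicates per Monte Carlo cell
(bootstrap standard error ≈ 0.7%); 100 additions per titration level.
These are the sizes at which the reported agreement figures were measured;
all are parameters of the public API.
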