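# Methods notes

This note records the model, the numerical choices behind it, and what the
synthetic-data tests do and do not establish.

## Count model and its assumptions

A pixel's recorded count is `n_ic = g·n_oe + N_read + N_q + Δ` with
independent terms: Poisson photoelectrons `n_oe` (mean λ, absorbing quantum
efficiency and dark current — the two are never resolved separately), read
noise `N_read = σ_TL·Q(R; Λ_TL)` defined through the Tukey-Lambda quantile
function of a uniform variable R, quantization error `N_q` uniform on
(−1/2, 1/2) for the fixed unit ADU step, and a constant offset Δ.  The model
assumes one global parameter set for the whole chip; per-pixel gain/offset/
noise maps are out of scope.  The read-noise location is fixed at zero and
its shape must satisfy Λ_TL > −1/2 for a finite variance
`s²_TL = σ²_TL·(2/Λ²)·(1/(1+2Λ) − Γ(1+Λ)²/Γ(2Λ+2))` (logistic limit
σ²π²/3 at Λ = 0).

The PMF is obtained by treating `n_ic` as a lattice variable: the product CF
is inverted as `p(n) = (1/π)∫₀^π Re[Φ(k)e^(−ikn)] dk` at integer n, with the
CDF as the running sum.  Two approximations are inherited from this
construction and worth keeping in mind:

* The CF that is inverted is the *continuous* model CF truncated to one
  period.  The dropped aliases `Φ(k + 2πj)` are negligible whenever the
  read-noise CF has decayed by `k = 2π` (true for any realistic σ_TL ≳ 1
  ADU: at the reference TL(0.055, 1.310) the alias magnitude is ~1e−4), but
  in the degenerate no-read-noise, unit-gain limit only the quantization
  sinc factor suppresses them.  There the tabulated PMF differs from the
  exact Poisson law by a total variation of ~4e−3 at λ = 5, shrinking with
  λ (4e−4 at λ = 50).  No continuous-density correction is attempted; the
  inversion is implemented exactly as the lattice formula states.
* Only integer counts are evaluated even though Δ need not be integer; the
  support is the integer lattice around the mean.

## Quadrature

Both integrals use the trapezoidal rule on uniform grids.

* Fourier grid: `n_k = 2001` points on [0, π].  The Euler-Maclaurin
  endpoint terms vanish (the integrand has zero derivative at k = 0 and a
  negligible one at π for any model with read noise), so the k-error is far
  below the alias floor.
* R grid: `n_r = 20001` points on [0, 1], with the evaluation points
  clipped into [ε, 1−ε], ε = 1/(2n_r), because the quantile diverges at the
  endpoints for Λ ≤ 0.  Clipping the *evaluation points* while keeping the
  full-interval trapezoid weights perturbs the result by O(1/n_r²) only; a
  grid truncated to [ε, 1−ε] would instead lose O(ε) of the integral.  The
  grid is denser than the k grid on purpose: near R = 0, 1 the quantile
  varies fastest and the integrand `exp(ikσQ(R))` oscillates rapidly at
  large k; 2001 points leave ~1e−4 per-count errors in the dark-frame PMF,
  while 20001 points bring it to ~1e−5 against an exact quantile-inversion
  oracle — indistinguishable from exact for a 1e6-sample χ² test.  The
  read-noise CF does not depend on λ, is computed once per camera and
  cached, so the cost is a one-off ~2 s.

## Support selection and cleanup

The automatic support is centred at `round(gλ + Δ)` with half-width
`max(10, 8·std + B)` where `B` bounds the read-noise tail: the hard bound
σ/Λ for Λ > 0 (the TL distribution is then compactly supported, and that
bound exceeds 8 standard deviations at small λ — at the reference
parameters it is 23.8 ADU), and the 1e−9 quantile magnitude for Λ ≤ 0
(heavy tails).  Inversion artefacts (tiny negative values) are clipped to
zero; the table is renormalized when the raw mass is within [0.999, 1.001]
and flagged otherwise.  Likelihood code floors the PMF at 1e−300 before
logs.

Summed-count tail probabilities for regions use the n-fold CF power for
n ≤ 64 pixels and a continuity-corrected moment-matched normal tail above
(the CF-power quadrature degrades with n while the CLT error is then below
1e−3).

## Calibration estimators

* **Offset**: mean of all cap-on pixels; standard error reported.
* **Gain**: unweighted ordinary least squares of per-pixel temporal
  variance on offset-subtracted temporal mean, pooling all intensity
  levels into one regression (the photon-transfer plot is a single line).
  Heteroscedasticity weighting is deliberately omitted.
* **Read noise (PPCC)**: empirical quantiles of offset-subtracted dark
  counts at plotting positions `u_j = (j − 0.5)/m` are correlated with the
  unscaled theoretical quantiles for each candidate shape on a grid over
  [−1, 1] with step 0.005, refined once at step 0.0005 around the coarse
  optimum (matching three-decimal reporting precision); the scale is the
  least-squares slope of the QQ line at the optimum, its intercept a
  diagnostic expected near 0.  Integer quantization of real dark counts is
  neglected during the fit, inflating the recovered scale by
  ~`(1/24)/s²_TL` (≈0.9% at the reference camera) — well inside the
  estimator scatter.  Frames beyond 1e6 pixels are subsampled (seeded)
  before sorting; ties keep sorted order.  Multiple dark frames are fitted
  independently and averaged.
* **Consistency check**: the photon-transfer intercept should equal
  `d = s²_TL + 1/12`; at the reference read-noise parameters this is 4.78
  ADU² (the read-noise variance alone is 4.70).

## Truncated background fit

Candidate truncation points descend through the empirical count percentiles
100, 97.5, …, 50.  At each, λ_bg is the MLE of the truncated likelihood
(evaluated from the count histogram — identical to the per-pixel product,
orders of magnitude faster), and a Pearson χ² test with count-value bins
merged to expected ≥ 5 and dof = bins − 2 decides acceptance at
`p_GoF = 0.01`; the first (largest) passing candidate wins, so pure
background keeps all its data while contaminated tiles truncate below the
signal mode.  The 1-D maximization first scans a 25-point geometric λ grid
seeded with the moment estimate `(mean − Δ)/g` — the log-likelihood is a
flat floor wherever the model support misses the data, which strands a
blind bounded search — then refines between the best grid point's
neighbours to 1e−4 absolute.  The descent aborts below a 100-pixel floor;
unconverged fits are flagged, never silently dropped.  On calibrated pure
background the GoF p-value is uniform to good approximation (measured mean
0.48 over 40 simulated tiles), so ~1% of clean tiles will fail all
candidates by construction at p_GoF = 0.01.

## Thresholding and segmentation choices

"Above the threshold" is strict (`count > t` with t the smallest support
count whose upper tail is ≤ p_binarize), which makes the a-priori bound on
the white fraction exact; because counts are integers the realized
false-positive rate sits below the nominal level (≈0.74% at the nominal 1%
for the reference background).  Gap bridging is a closing restricted to
horizontal and vertical runs of ≤ `allowedGapLength` black pixels flanked
by white; bridging pixels transmit 8-connectivity but are excluded from
region pixel counts and summed counts, keeping region statistics honest.
With a tile map, each tile is binarized with its own threshold and regions
are scored with the model of the tile containing their centroid.  The
region significance default `p_seg = 0.01` parallels `p_binarize`; note
that any single white pixel clears it by construction, so `p_seg` only
discriminates for multi-pixel regions or when set below `p_binarize`.

## Synthetic camera

The simulator draws `n_oe ~ Poisson(λ)`, read noise through the quantile
transform, and *rounds* `g·n_oe + N_read + Δ` to the nearest integer:
sampling a uniform quantization error and rounding the total would be
equivalent in distribution, and rounding once avoids double-counting the
quantization term.  Counts are clipped at 0 like a real ADC (never active
at realistic offsets near 100 ADU).  Scenes place rectangle/disc/line
primitives (or arbitrary masks) with per-object signal means; overlaps
take the maximum mean, and an exposure scale multiplies every mean.

What the simulator does *not* emulate: optical point-spread blur,
photobleaching, pixel-to-pixel parameter heterogeneity, or correlated
(fixed-pattern) noise.  Passing recovery tests therefore demonstrates the
estimators are correct under the stated noise model, not that the model
captures every artefact of a physical sensor; on real data the calibration
residuals (PPCC score, GoF p-values, intercept consistency) are the guard
rails.

## Study conditions used in tests and the acceptance script

Reference camera g = 0.81 ADU/e⁻, Δ = 100.10 ADU, TL(0.055, 1.310) read
noise; background levels 102.6 (moderate) and 0.335 (sub-photoelectron)
photoelectrons/pixel.  Problem sizes: white-wall calibration 10 intensity
levels (λ 50–500) × 200 frames of 64×64 pixels; cap-on frame 1412×1412
(the full sensor format); PPCC samples 1e5; background tiles 64×64 with 10
seeds and, for the contaminated case, 10% signal pixels at 5× background;
false-positive control 20 images of 256×256.  These sizes reproduce the
reported precisions while keeping a full run in tens of seconds.

## Known limitations

* Single global parameter set; no per-pixel calibration maps.
* The truncation schedule and gap-bridging rule are reasonable published-
  style choices where the source procedure is underspecified; both are
  isolated behind small functions for easy substitution.
* The lattice inversion's alias error makes the no-read-noise limit
  slightly inexact (see above); irrelevant for calibrated cameras.
* EMCCD cameras (multiplicative gain register, Gaussian read noise) are
  not modelled.
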