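# Methods

This note records the models implemented in `flimcal`, the assumptions they
make, and the design choices taken where more than one reasonable
construction exists.

## Two-state phasor model

A fluorescence decay measured at angular modulation frequency ω = 2πf is
summarized by its phase lifetime τ_φ and modulation lifetime τ_M, or by the
phasor

    G = M cos Φ,   S = M sin Φ,
    Φ = arctan(ω τ_φ),   M = 1 / sqrt(1 + (ω τ_M)²).

The default frequency is 40 MHz (`ModulationSettings`); all times are in
ns, frequencies in MHz. Mono-exponential decays lie on the universal
semicircle (G − ½)² + S² = ¼; intensity mixtures combine phasors linearly,
so a two-state sensor traces the chord between its apo and sat phasors.

The projection coordinate along that chord,

    a = (dG·dG_max + dS·dS_max) / (dG_max² + dS_max²),

is returned **unclamped**: noisy points beyond the extremes yield a < 0 or
a > 1, which downstream quality control should be able to see. Clamping
happens only at the concentration-conversion step, where out-of-range
pixels are flagged (0 ok, 1 below range, 2 saturated, 3 masked) and
saturated pixels carry a +inf sentinel in the float map — TIFF has no flag
semantics, so the flag image travels as a separate uint8 channel.

Because the two states differ in detected brightness, the line fraction
overweights the brighter state. With R the bound/free brightness ratio
(0.836 in vitro for this sensor), the molecular bound fraction is

    F = a / (R(1 − a) + a),

with inverse a = FR / ((1 − F) + FR). For R = 1 the correction vanishes.
Negative unclamped a can make the denominator non-positive; such values
come back NaN rather than raising, since they occur pixelwise in noisy
images.

Phase angles are computed with atan2 so an unphysical S < 0 is detectable
and rejected instead of silently wrapped. Geometric comparisons in phasor
space use an absolute tolerance of 1e-9.

## Hill calibration

Measured fractions over a ladder of known free-calcium concentrations L
are fitted with

    F(L) = F_min + (F_max − F_min) / ((K_d/L)^n + 1)

by bounded nonlinear least squares (`scipy.optimize.least_squares`, TRF).
Choices:

* K_d and n are parameterized on the log scale so positivity holds by
  construction; this mirrors a bounded solver without depending on a
  specific one. n is bounded to [0.1, 10].
* F_min ∈ [0, 0.5] and F_max ∈ [0.5, 1] are free parameters by default
  (the calibration equation includes them); `pin_extremes=True` fixes them
  at 0/1 for sensors known to saturate fully.
* The fit is unweighted in fraction space; replicates enter as individual
  points.
* 95% confidence intervals come from the Jacobian-based covariance with
  Student-t quantiles, delta-method-transformed for the log-scale
  parameters.
* Fewer than four distinct concentrations raise an underdetermined error.

Endpoints can come from two sources, selected explicitly: *in-vitro* (mean
phasor at the lowest and highest concentration of a calibration series, or
known lifetime pairs) or *in-situ* (`estimate_extremes_from_timelapse`,
which takes the median phasor of the lowest-phase-lifetime 5% band of the
post-saturation frames as the bound endpoint and of the highest 95% band of
the baseline frames as the free endpoint; percentiles configurable). The
in-situ estimate is band-selected and therefore sits roughly one noise
standard deviation beyond the true endpoint — adequate for anchoring a
timelapse whose final frames are driven to saturation, but an in-vitro
series is preferred when available.

The measurable range takes the mean bound fraction of the zero-calcium
replicates plus its 95% CI half-width (t-distribution, mean of n
replicates) as the lowest resolvable fraction, the saturating-buffer mean
minus its half-width as the highest, and pushes both through the Hill
inverse. Wider replicate scatter therefore *narrows* the range; zero
scatter is reported as degenerate rather than as an infinitely precise
range.

## TCSPC decay model

Photon arrival times over a window [0, t_max] follow

    p(t) = ε/t_max + f₁ F(t; τ₁, σ, μ) + f₂ F(t; τ₂, σ, μ),  ε + f₁ + f₂ = 1,

where F is an exponential decay convolved with a Gaussian instrument
response of center μ and width σ. F is implemented as the
exponentially-modified-Gaussian probability density

    F(t; τ, σ, μ) = 1/(2τ) · exp(σ²/2τ² − (t−μ)/τ) · erfc((σ/τ − (t−μ)/σ)/√2),

which integrates to one over the real line, so p integrates to one over the
window whenever the pulse sits well inside it (μ − 5σ > 0 and
t_max ≫ τ₂). An equivalent prefactor convention that carries a factor
σ√(2π) appears in some write-ups; the density normalization is used here so
that ε, f₁, f₂ are genuine mixture probabilities. Numerical stability for
σ/τ up to ~10 comes from the scaled complementary error function
(`erfcx`), which turns the product of a huge exponential and a vanishing
erfc into a plain Gaussian factor; the far right tail switches to the
direct form where erfc → 2.

Fitting minimizes the Pearson chi-squared Σ(obs − exp)²/exp between the
histogram and the binned model expectation:

* (ε, f₁, f₂) live on the probability simplex via a softmax
  parameterization, so the sum constraint holds by construction; τ₁, τ₂
  and σ are log-parameterized; μ is free.
* Low-count tail bins are pooled from the right until each pooled bin has
  expected count ≥ 1. The pooling is computed once from the initial
  parameter estimate and held fixed, so the least-squares residual vector
  keeps a constant shape.
* Up to 8 deterministic multi-starts guard against local optima. For the
  default two-component fit the starts are anchored on a single-component
  pre-fit: a two-component model fitted to near-mono-exponential data has a
  genuine degeneracy in which a τ → 0 spike component trades against the
  IRF center μ, and the mono pre-fit (which cannot form a spike) pins
  (ε, σ, μ) in the correct basin before the component time constants are
  spread around its τ. Ties between starts break by lower chi-squared,
  then smaller τ₁. The returned model is canonically ordered τ₁ ≤ τ₂.
* The component count is fixed at two plus uniform noise;
  `n_components=1` selects the mono-exponential sub-case (f₂ = 0). When
  the data are known to be mono-exponential — as in the synthetic recovery
  studies below — the sub-case is the matching configuration and avoids
  the spike degeneracy entirely.
* Fits require a configurable minimum photon count (default 10⁴; ≥10⁵ is
  the usual imaging guidance).

The empirical lifetime of a histogram is the count-weighted mean arrival
time corrected for the fitted IRF offset and the mean of the uniform
background (t_max/2):

    L = ⟨t⟩ − (μ + ε t_max / 2).

It is invariant to count rescaling. Note its expectation is
(1 − ε)τ − εμ minus a window-truncation term — slightly below τ — so
*differences* of empirical lifetimes between conditions are the robust
read-out, as the small bias cancels. Frame averages weight each frame's
lifetime by its intensity: ⟨L⟩ = Σ I_k L_k / (n⟨I⟩).

Time-domain phasors are the count-weighted cosine/sine transforms of the
histogram at the modulation frequency, referenced to a zero-time offset
(typically the IRF center). Foreground masking defaults to Otsu's
threshold on the intensity image, with a rank-based quantile alternative
that is invariant to monotone intensity rescaling; constant images return
an all-background mask with a warning.

## Photophysics

Quantum yield: integrated emission I_em versus absorbance A is fitted
through the origin for a dilution series of the sample and of a reference
dye (rhodamine, QY 0.85), with every absorbance ≤ 0.05 so the relation
stays linear; QY_s = QY_ref · s_s/s_r with s the emission-per-absorbance
slope. Some write-ups define the slope in the inverted direction
(absorbance per emission) while keeping the same ratio formula; the
emission-per-absorbance direction used here is the dimensionally consistent
one. The reported sd propagates the sample slope's standard error, matching
the convention of quoting sample-limited uncertainty against a
well-characterized reference.

Extinction coefficient: alkali denaturation frees the chromophore, whose
absorbance at 462 nm with ε = 46,000 M⁻¹cm⁻¹ gives the protein
concentration by Beer–Lambert; the native spectrum divided by c·l yields
ε(λ) and its maximum. The result is invariant to common dilution of both
spectra.

Brightness ratio: per state, detected brightness is modeled as
ε_max · QY · ∫êx(λ)X(λ)dλ · ∫êm(λ)D(λ)dλ with êx, êm the peak-normalized
state spectra, X the excitation band (source profile × filter) and D the
detection band (detector profile × filter); R = B_sat/B_apo. This is an
overlap-integral approximation: it assumes the detected signal factorizes
into an excitation efficiency and a collection efficiency. Spectral
integrals use the trapezoid rule at 1 nm default resolution with top-hat
band edges clipped exactly (no discretization error at filter edges);
profile normalization constants cancel in the ratio.

## Synthetic data

The generators produce the study conditions the analysis assumes, as pure
functions of their parameters and an integer seed:

* `gen_calibration_series`: bound fractions from a Hill truth over a
  concentration ladder; phasors on the mixing line plus isotropic Gaussian
  noise in (G, S). Default ladder: 0 plus 10 log-spaced points from 10 nM
  to 39 µM (the "0–39 µM in 11 steps" design cannot be literally
  log-spaced through zero; 10 nM sits well below the sensor's measurable
  floor, so the zero anchor and the decade coverage are both preserved).
  Default noise sd 0.003 in phasor units and 3 replicates, the scatter and
  replication of a plate-based in-vitro calibration.
* `gen_tcspc_histogram`: per photon, uniform background with probability
  ε, otherwise a Gaussian(μ, σ) IRF draw plus an Exponential(τ_j) draw;
  out-of-window arrivals are redrawn rather than wrapped (wrapping is
  available conceptually for short windows but is not the default since
  the 25 ns default window at 80 MHz-type spacing makes wrap-around mass
  negligible).
* `gen_ca_timelapse`: elliptical regions with per-region concentration
  programs (baseline, optional oscillation, final saturation step,
  emulating a maximal-response addition at the end of a live-cell run);
  per-pixel phasor noise scales as 1/√(photon budget) — the shot-noise
  behavior of phasor estimates — and detected intensity scales with the
  state-dependent brightness (1 − F) + F·R.
* `gen_spectra`: sum-of-Gaussians spectra for photophysics fixtures.

What the generators do **not** emulate: realistic organelle morphology,
optical point-spread functions, detector afterpulsing or dead time,
pile-up, autofluorescence backgrounds with structure, or photobleaching.
Passing closed-loop tests therefore demonstrates the correctness of the
estimators under the stated noise models, not robustness to every artifact
of real microscopy data.

## Problem sizes and numerical checks

The recovery studies use 11 concentrations × 3 replicates for
calibrations and 5×10⁵ photons per histogram at 10 ps binning over 25 ns
for TCSPC — sizes at which the estimators are comfortably in their
asymptotic regime while keeping a full test run in seconds. Measured over
hundreds of seeded simulations at these sizes, the fitted K_d has a
relative sd near 2% and the Hill coefficient an absolute sd near 0.044;
the paired empirical-lifetime difference recovers the generating
separation to better than 0.02 ns in every one of 40 seed pairs checked.
Because the estimators are stochastic, fixed-tolerance recovery checks in
the test suite are evaluated on the median over a small fixed batch of
seeds rather than a single draw.

## Known limitations

* The brightness-ratio model is an overlap-integral approximation; a
  measured R on the actual instrument supersedes it.
* The IRF is strictly Gaussian; measured-IRF deconvolution and vendor raw
  formats are out of scope (the pipeline consumes decoded histograms and
  images).
* The in-situ endpoint estimator is percentile-band based and inherits a
  small noise-dependent bias toward the extremes.
* Calcium buffering by the sensor itself, kinetic (on/off) modeling, and
  per-organelle contrast differences are not modeled.
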