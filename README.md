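# flimcal

Quantitative calcium imaging from fluorescence lifetime data.

Lifetime-based calcium biosensors toggle between a calcium-free (apo) and a
calcium-bound (sat) state with different fluorescence lifetimes. Unlike
intensity read-outs, the lifetime is insensitive to expression level and
illumination, so a calibrated sensor reports *absolute* calcium
concentrations. `flimcal` implements the full quantitative path for such a
two-state sensor, for both frequency-domain (phase/modulation) and
time-domain (TCSPC) FLIM:

* **Phasor geometry.** A decay measured at modulation frequency
  ω = 2πf maps to the phasor G = M cos Φ, S = M sin Φ with
  Φ = arctan(ωτ_φ) and M = 1/√(1 + (ωτ_M)²). Mixtures of the two sensor
  states fall on the straight segment between the apo and sat phasors; the
  projection coordinate *a* along that segment weights the states by
  detected intensity.
* **Brightness correction.** The molecular bound fraction is
  F = a / (R(1−a) + a), where R is the detected brightness of the bound
  state relative to the free state (0.836 for this sensor's in-vitro
  settings).
* **Hill calibration.** F(L) = F_min + (F_max − F_min) / ((K_d/L)^n + 1)
  fitted by bounded nonlinear least squares over a ladder of known free
  Ca²⁺ concentrations L, giving K_d, the Hill coefficient n, confidence
  intervals, and the measurable concentration range. Inverting the fit
  converts phasor images into nM concentration maps with below-range /
  saturated / masked flags.
* **TCSPC decay model.** Arrival times follow
  p(t) = ε/t_max + f₁F(t; τ₁, σ, μ) + f₂F(t; τ₂, σ, μ), each component an
  exponential convolved with a Gaussian instrument response (center μ,
  width σ), fitted by Pearson chi-squared. The *empirical lifetime*
  L = ⟨t⟩ − (μ + ε·t_max/2) summarizes a histogram nonparametrically after
  removing the IRF offset and the uniform background.
* **Photophysics.** Relative quantum yield from origin-forced dilution
  regressions, extinction coefficients via the denatured-chromophore
  Beer–Lambert method, and the theoretical two-state brightness ratio R
  from spectra and instrument profiles.
* **Synthetic data.** Seeded generators for every input — calibration
  ladders, photon histograms, heterogeneous concentration timelapses with a
  final saturation step — so the whole pipeline is testable end to end.

## Worked example

Calibrate from a simulated in-vitro ladder and read the affinity back
(`examples/01_calibrate_in_vitro.py`):

```python
import flimcal as fc

truth = fc.synthetic.paper_like_hill("37C")          # Kd 209 nM, n 1.53
ends = fc.synthetic.paper_like_endpoints("37C")      # apo/sat phasors, R 0.836
series = fc.synthetic.gen_calibration_series(
    truth, ends, replicates=3, phasor_noise_sd=0.003, seed=1
)
result = fc.fit_hill(series, ends=ends)
print(result.params)
```

which prints

```
fitted Kd     = 207.8 nM   (truth 209 nM, 95% CI 199-217)
fitted Hill n = 1.584      (truth 1.53)
```

The fitted K_d is the calcium concentration at half-saturation of the
sensor; the confidence interval comes from the Jacobian-based covariance of
the bounded fit. `examples/` holds one short script per capability
(concentration maps, TCSPC fitting, photophysics, reporting), each printing
the numbers it computes and what they mean.

A thin command-line layer mirrors the same stages:

```sh
flimcal simulate calibration --seed 1 --out sim/
flimcal calibrate sim/calibration_series.csv --out fit/
flimcal convert --g G.tif --s S.tif --calibration-json fit/calibration.json --out maps/
flimcal tcspc-fit histogram.csv --out decay/
```

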