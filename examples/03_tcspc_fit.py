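"""Fit a TCSPC photon-arrival histogram and estimate the empirical lifetime.

Samples 5e5 photon arrivals from the Gaussian-IRF decay model (a 2.5 ns
decay through a 0.1 ns-wide IRF centered at 1.0 ns, with 0.5% uniform
background), fits the model by Pearson chi-squared, and computes the
empirical lifetime: the mean arrival time corrected for the fitted IRF
offset and background.
"""

import flimcal as fc

truth = fc.DecayModel.mono(tau_ns=2.5, sigma_ns=0.1, mu_ns=1.0, eps=0.005)
hist = fc.synthetic.gen_tcspc_histogram(
    truth, n_photons=500_000, t_max_ns=25.0, bin_width_ns=0.01, seed=4
)

model, diag = fc.fit_decay(hist, n_components=1)
life = fc.empirical_lifetime(hist, model)

print(f"fitted tau   = {model.tau1_ns:.3f} ns   (truth 2.500)")
print(f"fitted IRF   = mu {model.mu_ns:.3f} ns, sigma {model.sigma_ns:.3f} ns")
print(f"background   = {model.eps * 100:.2f} %   (truth 0.50 %)")
print(f"chi-squared  = {diag['chi2']:.0f} on {diag['dof']} pooled bins")
print(f"empirical lifetime = {life:.3f} ns")
print("The empirical lifetime is slightly below tau because the uniform")
print("background and the finite window trim the mean arrival time.")

# averaging several frames weights each frame's lifetime by its intensity
frames = fc.FrameSeries(intensities=[900.0, 1100.0, 600.0],
                        lifetimes_ns=[2.49, 2.51, 2.40])
print(f"intensity-weighted mean lifetime = "
      f"{fc.intensity_weighted_lifetime(frames):.3f} ns")
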