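"""Convert a phasor timelapse into calcium-concentration images.

Simulates a mitochondria-like scene: two organelle regions with different
resting calcium (one oscillating), a shot-noise-limited photon budget, and
a final frame driven to saturation (the maximal-response step used to
anchor in-situ calibration).  The phasor stacks are then converted
pixelwise to [Ca2+] maps with the published calibration.
"""

import numpy as np

import flimcal as fc

calib = fc.CalibrationResult(
    params=fc.synthetic.paper_like_hill("37C"),
    ci95={},
    endpoints=fc.synthetic.paper_like_endpoints("37C"),
    residual_norm=0.0,
    converged=True,
)

scene = fc.synthetic.SceneSpec(
    shape=(64, 64),
    regions=(
        fc.synthetic.Region(center=(20, 20), axes=(10, 7), baseline_nM=150.0),
        fc.synthetic.Region(center=(44, 40), axes=(8, 12), baseline_nM=600.0,
                            oscillation_period=6, oscillation_amplitude_nM=800.0),
    ),
    n_frames=10,
    photon_budget=1e4,
)

g, s, intensity, truth = fc.synthetic.gen_ca_timelapse(scene, calib, seed=2)
ca, flags = fc.phasor_image_to_ca_map(g, s, calib)

print("frame  region1 median (truth)    region2 median (truth)")
m1 = scene.regions[0].mask(scene.shape)
m2 = scene.regions[1].mask(scene.shape)
for k in range(scene.n_frames - 1):  # last frame is the saturation step
    print(f"{k:5d}  {np.median(ca[k][m1]):8.0f} nM ({truth[k][m1].mean():5.0f})"
          f"      {np.median(ca[k][m2]):8.0f} nM ({truth[k][m2].mean():5.0f})")
sat = flags[-1] == 2
print(f"saturation frame: {sat.mean():.0%} of pixels flagged saturated")
print("Median region concentrations track the generating truth; the flag")
print("channel marks pixels outside the invertible range of the Hill fit.")
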