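"""Quantum yield, extinction coefficient, and the two-state brightness ratio.

Three bench computations that feed the calibration: the relative quantum
yield from origin-forced dilution regressions, the extinction coefficient
by alkali denaturation (Beer-Lambert at 462 nm with the free-chromophore
epsilon of 46,000 / M / cm), and the theoretical detected-brightness ratio
R of the calcium-bound vs calcium-free state on a given instrument.
"""

import numpy as np

import flimcal as fc
from flimcal.photophysics import InstrumentProfile, StatePhotophysics

# --- quantum yield: sample emits 41.1/85 as much per unit absorbance as
# the rhodamine reference (QY 0.85)
a = np.array([0.008, 0.018, 0.031, 0.044])
reference = fc.DilutionSeries(a450=a, i_em=0.85 * 1e4 * a, label="reference")
sample = fc.DilutionSeries(a450=a, i_em=0.411 * 1e4 * a, label="apo")
qy, qy_sd = fc.quantum_yield(sample, reference)
print(f"quantum yield = {qy * 100:.1f} % +/- {qy_sd * 100:.2f}")

# --- extinction coefficient: denatured A(462) = 0.046 at 1 cm -> 1 uM protein
denatured = fc.synthetic.gen_spectra([462.0], [25.0], [0.046], kind="absorbance")
native = fc.synthetic.gen_spectra([476.0], [24.0], [0.0309], kind="absorbance")
eps_max, lam = fc.extinction_coefficient(
    fc.AbsorbanceMeasurement(native, denatured, path_length_cm=1.0)
)
print(f"extinction coefficient = {eps_max:,.0f} /M/cm at {lam:.0f} nm")

# --- brightness ratio R on a GFP-type filter set
instrument = InstrumentProfile(excitation_filter=(440.0, 500.0),
                               emission_filter=(500.0, 560.0))


def state(ex_peak, em_peak, eps, qy):
    return StatePhotophysics(
        excitation=fc.synthetic.gen_spectra([ex_peak], [18.0], [1.0], kind="excitation"),
        emission=fc.synthetic.gen_spectra([em_peak], [20.0], [1.0], kind="emission"),
        eps_max=eps, qy=qy,
    )


apo = state(474, 515, 29_300, 0.411)
sat = state(476, 517, 30_900, 0.259)
r = fc.intensity_ratio(apo, sat, instrument)
print(f"brightness ratio R = {r:.3f}")
print("R < 1 means the calcium-bound state is dimmer; the calibration uses")
print("R to convert the intensity-weighted line fraction into the true")
print("fraction of calcium-bound sensors.")
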