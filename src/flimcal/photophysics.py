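"""Protein photophysics: quantum yield, extinction coefficient, and the
theoretical two-state brightness ratio.

Quantum yield is measured relative to a reference dye by comparing, for a
dilution series of each, the slope of integrated emission versus absorbance
at the excitation wavelength (regression forced through the origin, all
absorbances kept below 0.05 so inner-filter effects are negligible):

    QY_sample = QY_ref * s_sample / s_ref,   s = d(I_em)/d(A).

The extinction coefficient uses the denatured-chromophore method: alkali
denaturation frees the chromophore, whose absorbance at 462 nm with a known
epsilon of 46,000 M^-1 cm^-1 gives the protein concentration by
Beer-Lambert; the native spectrum divided by (c * l) then yields
epsilon(lambda) and its maximum.

The two-state brightness ratio R predicts the detected intensity of the
calcium-bound state relative to the calcium-free state on a given
instrument, from each state's extinction coefficient, quantum yield and
peak-normalized spectra weighted by the excitation and detection profiles:

    B = eps_max * QY * int ex_hat(l) X(l) dl * int em_hat(l) D(l) dl
    R = B_sat / B_apo.

Any common normalization of the instrument profiles cancels in the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "Spectrum",
    "DilutionSeries",
    "AbsorbanceMeasurement",
    "InstrumentProfile",
    "StatePhotophysics",
    "quantum_yield",
    "extinction_coefficient",
    "intensity_ratio",
]

#: extinction coefficient of the free (denatured) cyan chromophore at 462 nm
DENATURED_EPS_462 = 46_000.0  # M^-1 cm^-1
DENATURED_WAVELENGTH = 462.0  # nm


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-resolved curve (excitation, emission, absorbance, ...)."""

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = "emission"

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)
        if w.ndim != 1 or w.size != v.size:
            raise ValueError("wavelengths and values must be matching 1-D arrays")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")

    def at(self, wavelength_nm: float) -> float:
        """Linear interpolation at one wavelength (0 outside the grid)."""
        return float(
            np.interp(wavelength_nm, self.wavelengths_nm, self.values, left=0.0, right=0.0)
        )

    def peak(self) -> tuple[float, float]:
        """(wavelength, value) at the spectrum maximum."""
        i = int(np.argmax(self.values))
        return float(self.wavelengths_nm[i]), float(self.values[i])

    def normalized(self) -> "Spectrum":
        """Peak-normalized copy."""
        vmax = float(np.max(self.values))
        if vmax <= 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return Spectrum(self.wavelengths_nm, self.values / vmax, self.kind)


@dataclass(frozen=True)
class DilutionSeries:
    """Absorbance / integrated-emission pairs of a dilution ladder.

    a450 : absorbance at the excitation wavelength (OD, each <= 0.05 so the
    emission/absorbance relation stays linear); i_em : integrated emission.
    """

    a450: np.ndarray
    i_em: np.ndarray
    label: str = "sample"

    def __post_init__(self) -> None:
        a = np.asarray(self.a450, dtype=float)
        i = np.asarray(self.i_em, dtype=float)
        object.__setattr__(self, "a450", a)
        object.__setattr__(self, "i_em", i)
        if a.size != i.size or a.size < 3:
            raise ValueError("need >= 3 matched dilutions")
        if np.any(a > 0.05 + 1e-12):
            raise ValueError("absorbance must stay <= 0.05 for linearity")
        if np.any(a < 0):
            raise ValueError("absorbance must be non-negative")


@dataclass(frozen=True)
class AbsorbanceMeasurement:
    """Native and denatured absorbance spectra of one protein sample."""

    native_spectrum: Spectrum
    denatured_spectrum: Spectrum
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        if not self.path_length_cm > 0:
            raise ValueError("path length must be positive")


@dataclass(frozen=True)
class InstrumentProfile:
    """Excitation and detection response of the microscope.

    Each band may be given as a measured Spectrum or as (lo, hi) edges of an
    ideal top-hat filter.  The source/detector profiles default to flat.
    """

    excitation_filter: object  # Spectrum | (lo, hi)
    emission_filter: object  # Spectrum | (lo, hi)
    source_profile: Optional[Spectrum] = None
    detector_profile: Optional[Spectrum] = None


@dataclass(frozen=True)
class StatePhotophysics:
    """Photophysics of one sensor state: spectra, eps_max and QY."""

    excitation: Spectrum
    emission: Spectrum
    eps_max: float
    qy: float


def _origin_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of y = s*x through the origin, with its SE."""
    sxx = float(np.sum(x * x))
    if sxx <= 0:
        raise ValueError("degenerate abscissa: all zero")
    s = float(np.sum(x * y) / sxx)
    resid = y - s * x
    dof = max(x.size - 1, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    return s, se


def quantum_yield(
    sample: DilutionSeries,
    reference: DilutionSeries,
    qy_ref: float = 0.85,
) -> tuple[float, float]:
    """Relative quantum yield from two origin-forced dilution regressions.

    Fits integrated emission against absorbance (through the origin) for the
    sample and the reference; the ratio of emission-per-absorbance slopes,
    scaled by the reference quantum yield, is the sample quantum yield.  The
    returned sd propagates the sample slope's standard error.

    Returns ``(qy, qy_sd)`` as fractions (0.411 for 41.1%).
    """
    s_sample, se_sample = _origin_slope(sample.a450, sample.i_em)
    s_ref, _ = _origin_slope(reference.a450, reference.i_em)
    if s_ref == 0:
        raise ValueError("reference slope is zero")
    qy = qy_ref * s_sample / s_ref
    qy_sd = qy_ref * se_sample / abs(s_ref)
    return qy, qy_sd


def extinction_coefficient(m: AbsorbanceMeasurement) -> tuple[float, float]:
    """Peak extinction coefficient by the denatured-chromophore method.

    Concentration from Beer-Lambert on the denatured spectrum at 462 nm
    (eps = 46,000 M^-1 cm^-1); eps_max is the native-spectrum maximum
    divided by c*l.  Returns ``(eps_max_M_cm, lambda_max_nm)``.
    """
    a462 = m.denatured_spectrum.at(DENATURED_WAVELENGTH)
    if a462 <= 0:
        raise ValueError("denatured absorbance at 462 nm must be positive")
    c = a462 / (DENATURED_EPS_462 * m.path_length_cm)  # mol/L
    lam, a_max = m.native_spectrum.peak()
    return a_max / (c * m.path_length_cm), lam


def _overlap(state_spec: Spectrum, band, profile: Optional[Spectrum], grid_step: float) -> float:
    """Trapezoid integral of peak-normalized spectrum x filter x profile.

    Top-hat (lo, hi) bands clip the integration interval exactly, so the
    filter edges contribute no discretization error.
    """
    spec = state_spec.normalized()
    lo = spec.wavelengths_nm[0]
    hi = spec.wavelengths_nm[-1]
    if not isinstance(band, Spectrum):
        lo, hi = max(lo, band[0]), min(hi, band[1])
        if hi <= lo:
            return 0.0
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    if grid[-1] < hi:
        grid = np.append(grid, hi)
    vals = np.interp(grid, spec.wavelengths_nm, spec.values)
    if isinstance(band, Spectrum):
        vals = vals * np.interp(grid, band.wavelengths_nm, band.values, left=0.0, right=0.0)
    if profile is not None:
        vals = vals * np.interp(grid, profile.wavelengths_nm, profile.values, left=0.0, right=0.0)
    return float(np.trapezoid(vals, grid))


def intensity_ratio(
    apo: StatePhotophysics,
    sat: StatePhotophysics,
    instrument: InstrumentProfile,
    grid_step_nm: float = 1.0,
) -> float:
    """Theoretical bound/free detected-brightness ratio R.

    Per state, detected brightness is eps_max * QY times the overlap of the
    peak-normalized excitation spectrum with the excitation band (source
    profile x filter) and of the peak-normalized emission spectrum with the
    detection band (detector profile x filter); R = B_sat / B_apo.
    """
    def brightness(state: StatePhotophysics) -> float:
        ex = _overlap(state.excitation, instrument.excitation_filter,
                      instrument.source_profile, grid_step_nm)
        em = _overlap(state.emission, instrument.emission_filter,
                      instrument.detector_profile, grid_step_nm)
        if ex <= 0 or em <= 0:
            raise ValueError("spectrum does not overlap the instrument band")
        return state.eps_max * state.qy * ex * em

    return brightness(sat) / brightness(apo)
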