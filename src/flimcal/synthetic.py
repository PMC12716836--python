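"""Seeded generators for every input the pipeline consumes.

The generators emulate the study conditions the analysis assumes:

* a calcium calibration ladder (buffers spanning 0-39 uM free Ca2+) whose
  phasors follow the two-state mixing line with isotropic Gaussian
  measurement noise,
* TCSPC photon-arrival histograms sampled from the Gaussian-convolved
  exponential mixture with a uniform background,
* mitochondria-like concentration timelapses with heterogeneous regions,
  optional oscillations, and a final saturation step (the
  maximal-response addition at the end of a live-cell run),
* simple sum-of-Gaussians spectra for photophysics fixtures.

Every generator is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, HillParams, hill_fraction
from .phasor import (
    CalibrationEndpoints,
    LifetimePair,
    ModulationSettings,
    endpoints_from_lifetimes,
    line_fraction_from_bound,
    mix_phasor,
)
from .calibration import CalibrationSeries
from .photophysics import Spectrum
from .tcspc import ArrivalHistogram, DecayModel

__all__ = [
    "paper_like_endpoints",
    "paper_like_hill",
    "default_concentration_ladder",
    "Region",
    "SceneSpec",
    "gen_calibration_series",
    "gen_tcspc_histogram",
    "gen_ca_timelapse",
    "gen_spectra",
]

#: published in-vitro brightness ratio of the bound vs free state
DEFAULT_R = 0.836


def paper_like_endpoints(temperature: str = "37C", R: float = DEFAULT_R,
                         mod: ModulationSettings = ModulationSettings()) -> CalibrationEndpoints:
    """Endpoints from the published apo/sat lifetime pairs of the sensor.

    temperature "37C": apo (2.98, 3.50) ns, sat (1.93, 2.43) ns;
    "RT": apo (3.52, 3.99) ns, sat (2.03, 2.57) ns.
    """
    table = {
        "37C": (LifetimePair(2.98, 3.50), LifetimePair(1.93, 2.43)),
        "RT": (LifetimePair(3.52, 3.99), LifetimePair(2.03, 2.57)),
    }
    if temperature not in table:
        raise ValueError(f"temperature must be one of {sorted(table)}")
    apo, sat = table[temperature]
    return endpoints_from_lifetimes(apo, sat, R, mod)


def paper_like_hill(temperature: str = "37C") -> HillParams:
    """Published Hill parameters: Kd 209 nM / n 1.53 at 37C, 339 nM / 1.67 at RT."""
    table = {"37C": HillParams(209.0, 1.53), "RT": HillParams(339.0, 1.67)}
    if temperature not in table:
        raise ValueError(f"temperature must be one of {sorted(table)}")
    return table[temperature]


def default_concentration_ladder(n: int = 11, lo_nM: float = 10.0,
                                 hi_nM: float = 39_000.0) -> np.ndarray:
    """Zero plus (n-1) log-spaced concentrations up to the saturating buffer."""
    return np.concatenate([[0.0], np.logspace(np.log10(lo_nM), np.log10(hi_nM), n - 1)])


def gen_calibration_series(
    truth: HillParams,
    ends: CalibrationEndpoints,
    concentrations_nM: Optional[Sequence[float]] = None,
    replicates: int = 3,
    phasor_noise_sd: float = 0.003,
    seed: int = 0,
    mod: ModulationSettings = ModulationSettings(),
) -> CalibrationSeries:
    """Simulate a calibration ladder measured in phasor space.

    For each concentration L the bound fraction follows the Hill truth, the
    noiseless phasor sits on the mixing line (intensity-weighted by R), and
    isotropic Gaussian noise of sd ``phasor_noise_sd`` is added to (G, S)
    per replicate.  Deterministic given the seed.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if concentrations_nM is None:
        concentrations_nM = default_concentration_ladder()
    conc = np.asarray(concentrations_nM, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        f = hill_fraction(conc, truth)
        g, s = mix_phasor(f, ends)
        g = g + rng.normal(0.0, phasor_noise_sd, size=conc.shape)
        s = s + rng.normal(0.0, phasor_noise_sd, size=conc.shape)
        rows.append(pd.DataFrame({
            "replicate": rep,
            "free_ca_nM": conc,
            "g": g,
            "s": s,
        }))
    return CalibrationSeries(pd.concat(rows, ignore_index=True), modulation=mod)


def gen_tcspc_histogram(
    model: DecayModel,
    n_photons: int,
    t_max_ns: float = 25.0,
    bin_width_ns: float = 0.01,
    seed: int = 0,
) -> ArrivalHistogram:
    """Sample an arrival-time histogram from the decay model.

    Each photon is uniform on [0, t_max] with probability eps, otherwise a
    Gaussian(mu, sigma) IRF draw plus an Exponential(tau_j) draw for
    component j chosen with probability f_j/(f1+f2); arrivals outside the
    window are redrawn.  Deterministic given the seed.
    """
    if n_photons < 1:
        raise ValueError("need at least one photon")
    rng = np.random.default_rng(seed)
    u = rng.random(n_photons)
    is_noise = u < model.eps
    n_noise = int(is_noise.sum())
    times = np.empty(n_photons, dtype=float)
    times[is_noise] = rng.uniform(0.0, t_max_ns, n_noise)

    n_sig = n_photons - n_noise
    f_total = model.f1 + model.f2
    taus = np.where(
        rng.random(n_sig) < (model.f1 / f_total if f_total > 0 else 1.0),
        model.tau1_ns,
        model.tau2_ns,
    )
    arr = rng.normal(model.mu_ns, model.sigma_ns, n_sig) + rng.exponential(1.0, n_sig) * taus
    # redraw out-of-window signal photons
    bad = (arr < 0) | (arr > t_max_ns)
    while bad.any():
        k = int(bad.sum())
        t_new = rng.normal(model.mu_ns, model.sigma_ns, k) + rng.exponential(1.0, k) * taus[bad]
        arr[bad] = t_new
        bad = (arr < 0) | (arr > t_max_ns)
    times[~is_noise] = arr

    n_bins = int(round(t_max_ns / bin_width_ns))
    edges = np.linspace(0.0, t_max_ns, n_bins + 1)
    counts, _ = np.histogram(times, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ArrivalHistogram(bin_centers_ns=centers, counts=counts)


@dataclass(frozen=True)
class Region:
    """An elliptical region of a synthetic scene with its own Ca2+ program.

    center/axes in pixels; ``baseline_nM`` the resting concentration;
    optional oscillation (period in frames, amplitude in nM).
    """

    center: tuple[float, float]
    axes: tuple[float, float]
    baseline_nM: float
    oscillation_period: Optional[float] = None
    oscillation_amplitude_nM: float = 0.0

    def concentration(self, frame: int) -> float:
        c = self.baseline_nM
        if self.oscillation_period:
            c = c + self.oscillation_amplitude_nM * 0.5 * (
                1.0 - np.cos(2.0 * np.pi * frame / self.oscillation_period)
            )
        return max(c, 0.0)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        cy, cx = self.center
        ay, ax = self.axes
        return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


@dataclass(frozen=True)
class SceneSpec:
    """Layout and acquisition program of a synthetic timelapse.

    ``saturation_frames`` final frames are driven to a saturating
    concentration everywhere (the maximal-response step), so in-situ
    endpoint estimation has both extremes available.  ``background_nM`` is
    the concentration outside all regions.
    """

    shape: tuple[int, int]
    regions: tuple[Region, ...]
    n_frames: int
    photon_budget: float = 1e4
    background_nM: float = 50.0
    saturation_frames: int = 1
    saturation_nM: float = 39_000.0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.photon_budget <= 0:
            raise ValueError("invalid scene")
        for r in self.regions:
            cy, cx = r.center
            if not (0 <= cy < self.shape[0] and 0 <= cx < self.shape[1]):
                raise ValueError("region center outside image bounds")

    def truth_stack(self) -> np.ndarray:
        """(t, y, x) array of generating concentrations in nM."""
        stack = np.full((self.n_frames, *self.shape), self.background_nM, dtype=float)
        for r in self.regions:
            m = r.mask(self.shape)
            for k in range(self.n_frames):
                stack[k][m] = r.concentration(k)
        if self.saturation_frames:
            stack[-self.saturation_frames :] = self.saturation_nM
        return stack


def gen_ca_timelapse(
    scene: SceneSpec,
    result: CalibrationResult,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate (G, S, intensity, truth) stacks for a concentration scene.

    Per pixel and frame, the bound fraction follows the calibration's Hill
    parameters, the phasor sits on the mixing line plus isotropic Gaussian
    shot noise of sd 1/sqrt(photon budget), and the detected intensity
    scales with the state-dependent brightness (1 - F) + F * R.
    """
    rng = np.random.default_rng(seed)
    ends = result.endpoints
    truth = scene.truth_stack()
    f = hill_fraction(truth, result.params)
    a = line_fraction_from_bound(f, ends.R)
    g = ends.phasor_min.G + a * ends.dG_max
    s = ends.phasor_min.S + a * ends.dS_max
    intensity = scene.photon_budget * ((1.0 - f) + f * ends.R)
    noise_sd = 1.0 / np.sqrt(np.maximum(intensity, 1.0))
    g = g + rng.normal(0.0, 1.0, g.shape) * noise_sd
    s = s + rng.normal(0.0, 1.0, s.shape) * noise_sd
    return g, s, intensity, truth


def gen_spectra(
    peaks_nm: Sequence[float],
    widths_nm: Sequence[float],
    amplitudes: Sequence[float],
    grid: Optional[np.ndarray] = None,
    kind: str = "emission",
) -> Spectrum:
    """Sum-of-Gaussians spectrum on the given wavelength grid."""
    peaks = np.asarray(peaks_nm, dtype=float)
    widths = np.asarray(widths_nm, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if np.any(widths <= 0):
        raise ValueError("widths must be positive")
    if grid is None:
        lo = peaks.min() - 4 * widths.max()
        hi = peaks.max() + 4 * widths.max()
        grid = np.arange(lo, hi + 0.5, 1.0)
    grid = np.asarray(grid, dtype=float)
    vals = np.zeros_like(grid)
    for p, w, a in zip(peaks, widths, amps):
        vals += a * np.exp(-((grid - p) ** 2) / (2.0 * w**2))
    return Spectrum(grid, vals, kind)
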