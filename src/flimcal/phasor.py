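"""Phasor-space primitives for frequency-domain FLIM.

A fluorescence decay measured at modulation frequency ``f`` is summarized by
its phase lifetime ``tau_phi`` and modulation lifetime ``tau_mod``, or
equivalently by the phasor coordinates

    G = M cos(Phi),  S = M sin(Phi),

with ``Phi = arctan(omega * tau_phi)`` and ``M = 1/sqrt(1 + (omega*tau_mod)^2)``
where ``omega = 2*pi*f`` is the angular modulation frequency.  Mono-exponential
decays lie on the universal semicircle ``(G - 1/2)^2 + S^2 = 1/4``; intensity
mixtures of two decays lie on the straight chord between the component
phasors, weighted by their photon contributions.

A two-state biosensor therefore traces a line segment between its
calcium-free ("apo") and calcium-saturated ("sat") phasors.  The position of
a measurement along that segment (the *line fraction* ``a``) weights the
states by detected intensity; the molecular *bound fraction* ``F`` follows
after correcting for the brightness ratio ``R`` of the two states.

All functions accept scalars or numpy arrays for the coordinate arguments
and broadcast elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = [
    "ModulationSettings",
    "LifetimePair",
    "PhasorPoint",
    "CalibrationEndpoints",
    "StateFractions",
    "lifetime_to_phasor",
    "phasor_to_lifetime",
    "project_line_fraction",
    "bound_fraction",
    "line_fraction_from_bound",
    "mix_phasor",
    "endpoints_from_lifetimes",
]

#: absolute tolerance used for geometric comparisons in (G, S) space
PHASOR_ATOL = 1e-9

#: endpoints closer than this are considered degenerate
ENDPOINT_EPS = 1e-6


@dataclass(frozen=True)
class ModulationSettings:
    """Modulation frequency of the FD-FLIM acquisition.

    Parameters
    ----------
    frequency_MHz : float
        Modulation frequency in MHz.  The default 40 MHz is the standard
        setting for widefield FD-FLIM of fluorescent proteins.
    """

    frequency_MHz: float = 40.0

    def __post_init__(self) -> None:
        if not self.frequency_MHz > 0:
            raise ValueError(f"frequency must be positive, got {self.frequency_MHz}")

    @property
    def omega_rad_per_ns(self) -> float:
        """Angular frequency 2*pi*f in rad/ns."""
        return 2.0 * math.pi * self.frequency_MHz * 1e-3


@dataclass(frozen=True)
class LifetimePair:
    """Phase and modulation lifetime of a decay, in ns.

    For a mono-exponential decay the two are equal; for any intensity mixture
    ``tau_mod >= tau_phi``.
    """

    tau_phi_ns: float
    tau_mod_ns: float

    def __post_init__(self) -> None:
        if self.tau_phi_ns < 0 or self.tau_mod_ns < 0:
            raise ValueError(
                f"lifetimes must be non-negative, got "
                f"({self.tau_phi_ns}, {self.tau_mod_ns})"
            )


@dataclass(frozen=True)
class PhasorPoint:
    """A (G, S) phasor coordinate at one modulation frequency."""

    G: float
    S: float

    def __post_init__(self) -> None:
        if self.S < -PHASOR_ATOL:
            raise ValueError(f"S < 0 is unphysical for a decay, got S={self.S}")

    def distance(self, other: "PhasorPoint") -> float:
        return math.hypot(self.G - other.G, self.S - other.S)


@dataclass(frozen=True)
class CalibrationEndpoints:
    """Apo/sat phasor endpoints and the bound/free brightness ratio R.

    ``phasor_min`` is the calcium-free (apo) state, ``phasor_max`` the
    calcium-saturated state; R is the detected brightness of the bound state
    relative to the free state under the instrument settings in use.
    """

    phasor_min: PhasorPoint
    phasor_max: PhasorPoint
    R: float

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError(f"intensity ratio R must be positive, got {self.R}")
        if self.phasor_min.distance(self.phasor_max) <= ENDPOINT_EPS:
            raise ValueError("degenerate endpoints: apo and sat phasors coincide")

    @property
    def dG_max(self) -> float:
        return self.phasor_max.G - self.phasor_min.G

    @property
    def dS_max(self) -> float:
        return self.phasor_max.S - self.phasor_min.S


@dataclass(frozen=True)
class StateFractions:
    """Line fraction ``a`` and true bound fraction ``F`` of a measurement.

    ``in_range`` is False when the unclamped projection fell outside [0, 1]
    (noisy points beyond the calibration extremes).
    """

    a: float
    F: float
    in_range: bool = field(default=True)


def lifetime_to_phasor(lt, mod: ModulationSettings = ModulationSettings()):
    """Convert a (phase, modulation) lifetime pair to phasor coordinates.

    Parameters
    ----------
    lt : LifetimePair or tuple of array_like
        Phase and modulation lifetimes in ns.
    mod : ModulationSettings
        Modulation frequency.

    Returns
    -------
    PhasorPoint, or (G, S) arrays when array input is given.
    """
    scalar = isinstance(lt, LifetimePair)
    if scalar:
        tau_phi, tau_mod = lt.tau_phi_ns, lt.tau_mod_ns
    else:
        tau_phi, tau_mod = lt
    tau_phi = np.asarray(tau_phi, dtype=float)
    tau_mod = np.asarray(tau_mod, dtype=float)
    if np.any(tau_phi < 0) or np.any(tau_mod < 0):
        raise ValueError("negative lifetime")
    w = mod.omega_rad_per_ns
    phi = np.arctan(w * tau_phi)
    m = np.sqrt(1.0 / (1.0 + (w * tau_mod) ** 2))
    g = m * np.cos(phi)
    s = m * np.sin(phi)
    if scalar:
        return PhasorPoint(float(g), float(s))
    return g, s


def phasor_to_lifetime(p, mod: ModulationSettings = ModulationSettings()):
    """Invert :func:`lifetime_to_phasor`.

    Requires ``G > 0`` and ``G^2 + S^2 <= 1`` (phase in the first quadrant and
    modulation depth at most 1); raises otherwise for scalar input, returns
    NaN elementwise for array input.
    """
    scalar = isinstance(p, PhasorPoint)
    if scalar:
        g, s = p.G, p.S
    else:
        g, s = p
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    w = mod.omega_rad_per_ns
    msq = g**2 + s**2
    bad = (g <= 0) | (msq > 1.0 + PHASOR_ATOL)
    if scalar and bad:
        raise ValueError(f"phasor ({g}, {s}) outside the invertible domain")
    with np.errstate(divide="ignore", invalid="ignore"):
        tau_phi = np.tan(np.arctan2(s, g)) / w
        tau_mod = np.sqrt(np.maximum(1.0 / msq - 1.0, 0.0)) / w
    if scalar:
        return LifetimePair(float(tau_phi), float(tau_mod))
    tau_phi = np.where(bad, np.nan, tau_phi)
    tau_mod = np.where(bad, np.nan, tau_mod)
    return tau_phi, tau_mod


def project_line_fraction(p, ends: CalibrationEndpoints):
    """Orthogonal projection of a phasor onto the apo->sat segment.

    Returns the line fraction

        a = (dG*dG_max + dS*dS_max) / (dG_max^2 + dS_max^2)

    with ``dG = G - G_min`` etc.  The value is *unclamped*: noisy points
    beyond the extremes yield a < 0 or a > 1 and are left intact so that
    quality control can see them; clamping happens only at the
    concentration-conversion stage.
    """
    scalar = isinstance(p, PhasorPoint)
    if scalar:
        g, s = p.G, p.S
    else:
        g, s = p
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    dg = g - ends.phasor_min.G
    ds = s - ends.phasor_min.S
    denom = ends.dG_max**2 + ends.dS_max**2
    a = (dg * ends.dG_max + ds * ends.dS_max) / denom
    if scalar:
        return float(a)
    return a


def bound_fraction(a, R: float):
    """Correct a line fraction for the two-state brightness ratio.

        F = a / (R*(1 - a) + a)

    ``F`` is the molecular fraction of sensors in the calcium-bound state;
    for R = 1 (equal brightness) F equals a.  Unclamped a < 0 can make the
    denominator non-positive; such values come back as NaN.
    """
    if not R > 0:
        raise ValueError(f"R must be positive, got {R}")
    a_arr = np.asarray(a, dtype=float)
    denom = R * (1.0 - a_arr) + a_arr
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(denom > 0, a_arr / denom, np.nan)
    if np.isscalar(a):
        return float(f)
    return f


def line_fraction_from_bound(F, R: float):
    """Inverse of :func:`bound_fraction`: a = F*R / ((1-F) + F*R)."""
    if not R > 0:
        raise ValueError(f"R must be positive, got {R}")
    f_arr = np.asarray(F, dtype=float)
    a = f_arr * R / ((1.0 - f_arr) + f_arr * R)
    if np.isscalar(F):
        return float(a)
    return a


def mix_phasor(F, ends: CalibrationEndpoints):
    """Phasor of a population with bound fraction F.

    The two states mix linearly in phasor space by *intensity* weight, so the
    molecular fraction is first converted to a line fraction with the
    brightness ratio R and then interpolated between the endpoints.
    """
    a = line_fraction_from_bound(F, ends.R)
    g = ends.phasor_min.G + np.asarray(a) * ends.dG_max
    s = ends.phasor_min.S + np.asarray(a) * ends.dS_max
    if np.isscalar(F):
        return PhasorPoint(float(g), float(s))
    return g, s


def endpoints_from_lifetimes(
    apo: LifetimePair,
    sat: LifetimePair,
    R: float,
    mod: ModulationSettings = ModulationSettings(),
) -> CalibrationEndpoints:
    """Build calibration endpoints from apo/sat lifetime pairs."""
    return CalibrationEndpoints(
        phasor_min=lifetime_to_phasor(apo, mod),
        phasor_max=lifetime_to_phasor(sat, mod),
        R=R,
    )
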