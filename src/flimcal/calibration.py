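"""Hill-model calibration of a two-state lifetime biosensor.

The calibration series measures the sensor in buffers of known free Ca2+
concentration L.  Each measurement is reduced to a bound fraction F via the
phasor projection (``flimcal.phasor``) and the series is fitted with the
Hill equation

    F(L) = F_min + (F_max - F_min) / ((K_d / L)^n + 1)

by bounded nonlinear least squares, yielding the dissociation constant K_d,
the Hill coefficient n, and the end-state fractions.  The fitted model is
then inverted pixelwise to turn phasor images into calcium-concentration
maps, and the replicate scatter at the two extreme buffers defines the
measurable concentration range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phasor import (
    CalibrationEndpoints,
    ModulationSettings,
    PhasorPoint,
    bound_fraction,
    lifetime_to_phasor,
    line_fraction_from_bound,
    phasor_to_lifetime,
    project_line_fraction,
)

__all__ = [
    "HillParams",
    "CalibrationSeries",
    "CalibrationResult",
    "hill_fraction",
    "concentration_from_fraction",
    "fit_hill",
    "measurable_range",
    "phasor_image_to_ca_map",
    "estimate_extremes_from_timelapse",
    "FLAG_OK",
    "FLAG_BELOW",
    "FLAG_SATURATED",
    "FLAG_MASKED",
]

# flag codes of the concentration-map companion channel
FLAG_OK = 0
FLAG_BELOW = 1
FLAG_SATURATED = 2
FLAG_MASKED = 3

#: sentinel stored in float concentration maps for saturated pixels
SATURATED_SENTINEL = np.inf


@dataclass(frozen=True)
class HillParams:
    """Hill binding model parameters.

    Kd_nM : dissociation constant (half-saturation concentration), nM.
    hill_n : Hill coefficient (cooperativity), dimensionless.
    F_min, F_max : bound fraction at zero and saturating calcium.
    """

    Kd_nM: float
    hill_n: float
    F_min: float = 0.0
    F_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.Kd_nM > 0:
            raise ValueError(f"Kd must be positive, got {self.Kd_nM}")
        if not self.hill_n > 0:
            raise ValueError(f"Hill coefficient must be positive, got {self.hill_n}")
        if not (0.0 <= self.F_min < self.F_max <= 1.0):
            raise ValueError(
                f"need 0 <= F_min < F_max <= 1, got ({self.F_min}, {self.F_max})"
            )


@dataclass
class CalibrationSeries:
    """Measurements of a calibration ladder.

    ``data`` has one row per (replicate, concentration) with columns
    ``replicate``, ``free_ca_nM`` and either (``g``, ``s``) or
    (``tau_phi_ns``, ``tau_mod_ns``); lifetimes are converted to phasors on
    access.
    """

    data: pd.DataFrame
    modulation: ModulationSettings = field(default_factory=ModulationSettings)

    def __post_init__(self) -> None:
        cols = set(self.data.columns)
        if "free_ca_nM" not in cols:
            raise ValueError("series needs a free_ca_nM column")
        if not ({"g", "s"} <= cols or {"tau_phi_ns", "tau_mod_ns"} <= cols):
            raise ValueError("series needs (g, s) or (tau_phi_ns, tau_mod_ns) columns")
        if (self.data["free_ca_nM"] < 0).any():
            raise ValueError("concentrations must be non-negative")
        if self.data["free_ca_nM"].nunique() < 2:
            raise ValueError("need at least 2 distinct concentrations")

    @property
    def concentrations_nM(self) -> np.ndarray:
        return self.data["free_ca_nM"].to_numpy(dtype=float)

    def phasors(self) -> tuple[np.ndarray, np.ndarray]:
        if {"g", "s"} <= set(self.data.columns):
            return (
                self.data["g"].to_numpy(dtype=float),
                self.data["s"].to_numpy(dtype=float),
            )
        g, s = lifetime_to_phasor(
            (
                self.data["tau_phi_ns"].to_numpy(dtype=float),
                self.data["tau_mod_ns"].to_numpy(dtype=float),
            ),
            self.modulation,
        )
        return g, s

    def endpoints_from_extremes(self, R: float) -> CalibrationEndpoints:
        """Mean phasor at the lowest/highest concentration as apo/sat."""
        g, s = self.phasors()
        conc = self.concentrations_nM
        lo, hi = conc.min(), conc.max()
        return CalibrationEndpoints(
            phasor_min=PhasorPoint(g[conc == lo].mean(), s[conc == lo].mean()),
            phasor_max=PhasorPoint(g[conc == hi].mean(), s[conc == hi].mean()),
            R=R,
        )


@dataclass
class CalibrationResult:
    """Fitted calibration: Hill parameters, CIs, endpoints and diagnostics."""

    params: HillParams
    ci95: dict[str, tuple[float, float]]
    endpoints: CalibrationEndpoints
    residual_norm: float
    converged: bool
    measurable_range_nM: Optional[tuple[float, float]] = None
    range_degenerate: bool = False


def hill_fraction(L_nM, params: HillParams):
    """Forward Hill evaluation; L = 0 returns the limit F_min."""
    L = np.asarray(L_nM, dtype=float)
    if np.any(L < 0):
        raise ValueError("concentration must be non-negative")
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(L > 0, (params.Kd_nM / np.where(L > 0, L, 1.0)) ** params.hill_n, np.inf)
        f = params.F_min + (params.F_max - params.F_min) / (ratio + 1.0)
    if np.isscalar(L_nM):
        return float(f)
    return f


def concentration_from_fraction(F, params: HillParams):
    """Invert the Hill equation.

        L = Kd * ((F - F_min) / (F_max - F))^(1/n)

    Returns ``(L_nM, flags)`` where flags mark out-of-range inputs:
    F <= F_min maps to 0 nM with FLAG_BELOW, F >= F_max to +inf with
    FLAG_SATURATED, NaN to NaN with FLAG_MASKED.
    """
    f = np.asarray(F, dtype=float)
    flags = np.zeros(f.shape, dtype=np.uint8)
    nan = np.isnan(f)
    below = ~nan & (f <= params.F_min)
    above = ~nan & (f >= params.F_max)
    ok = ~(nan | below | above)
    L = np.empty(f.shape, dtype=float)
    L[below] = 0.0
    L[above] = SATURATED_SENTINEL
    L[nan] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        L[ok] = params.Kd_nM * (
            (f[ok] - params.F_min) / (params.F_max - f[ok])
        ) ** (1.0 / params.hill_n)
    flags[below] = FLAG_BELOW
    flags[above] = FLAG_SATURATED
    flags[nan] = FLAG_MASKED
    if np.isscalar(F):
        return float(L), int(flags)
    return L, flags


def _hill_model(L, log_kd, log_n, f_min, f_max):
    kd = np.exp(log_kd)
    n = np.exp(log_n)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(L > 0, (kd / np.where(L > 0, L, 1.0)) ** n, np.inf)
    return f_min + (f_max - f_min) / (ratio + 1.0)


def fit_hill(
    series: CalibrationSeries,
    ends: Optional[CalibrationEndpoints] = None,
    R: float = 0.836,
    pin_extremes: bool = False,
) -> CalibrationResult:
    """Fit the Hill equation to a calibration series in fraction space.

    Each measurement is projected onto the apo->sat line and corrected with
    the brightness ratio R to obtain its bound fraction F; the Hill model is
    then fitted by bounded least squares with K_d and n parameterized on the
    log scale (positivity by construction) and F_min in [0, 0.5],
    F_max in [0.5, 1] unless ``pin_extremes`` fixes them at 0 and 1.

    Parameters
    ----------
    series : CalibrationSeries
    ends : CalibrationEndpoints, optional
        If omitted, the mean phasors at the lowest and highest concentration
        of the series define the endpoints ("in-vitro" endpoint source).
    R : float
        Brightness ratio used when deriving endpoints from the series.
    pin_extremes : bool
        Fix F_min = 0 and F_max = 1 instead of fitting them.

    Returns
    -------
    CalibrationResult with 95% confidence intervals from the Jacobian-based
    covariance and Student-t quantiles.
    """
    if series.data["free_ca_nM"].nunique() < 4:
        raise ValueError("underdetermined: need >= 4 distinct concentrations")
    if ends is None:
        ends = series.endpoints_from_extremes(R)

    g, s = series.phasors()
    a = project_line_fraction((g, s), ends)
    f_obs = bound_fraction(a, ends.R)
    L = series.concentrations_nM
    keep = np.isfinite(f_obs)
    f_obs, L = f_obs[keep], L[keep]

    kd0 = max(np.median(L[L > 0]), 1e-3)
    if pin_extremes:
        def residuals(theta):
            return _hill_model(L, theta[0], theta[1], 0.0, 1.0) - f_obs

        x0 = np.array([np.log(kd0), 0.0])
        lb = np.array([-np.inf, np.log(0.1)])
        ub = np.array([np.inf, np.log(10.0)])
        names = ["Kd_nM", "hill_n"]
    else:
        def residuals(theta):
            return _hill_model(L, *theta) - f_obs

        x0 = np.array([np.log(kd0), 0.0, 0.0, 1.0])
        lb = np.array([-np.inf, np.log(0.1), 0.0, 0.5])
        ub = np.array([np.inf, np.log(10.0), 0.5, 1.0])
        names = ["Kd_nM", "hill_n", "F_min", "F_max"]

    sol = optimize.least_squares(residuals, x0, bounds=(lb, ub), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)

    theta = sol.x
    kd, n = float(np.exp(theta[0])), float(np.exp(theta[1]))
    if pin_extremes:
        f_min, f_max = 0.0, 1.0
    else:
        f_min, f_max = float(theta[2]), float(min(theta[3], 1.0))
    params = HillParams(Kd_nM=kd, hill_n=n, F_min=f_min, F_max=f_max)

    # covariance of theta from the Jacobian; delta-method back to (Kd, n)
    dof = max(len(f_obs) - len(theta), 1)
    rss = float(np.sum(sol.fun**2))
    ci95: dict[str, tuple[float, float]] = {}
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * (rss / dof)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        tq = stats.t.ppf(0.975, dof)
        point = {"Kd_nM": kd, "hill_n": n, "F_min": f_min, "F_max": f_max}
        for i, name in enumerate(names):
            if name in ("Kd_nM", "hill_n"):  # log-scale parameter
                lo = point[name] * np.exp(-tq * se[i])
                hi = point[name] * np.exp(tq * se[i])
            else:
                lo = point[name] - tq * se[i]
                hi = point[name] + tq * se[i]
            ci95[name] = (float(lo), float(hi))
    except np.linalg.LinAlgError:
        ci95 = {name: (np.nan, np.nan) for name in names}

    return CalibrationResult(
        params=params,
        ci95=ci95,
        endpoints=ends,
        residual_norm=float(np.sqrt(rss)),
        converged=bool(sol.success),
    )


def measurable_range(
    result: CalibrationResult,
    low_fractions: Sequence[float],
    high_fractions: Sequence[float],
    confidence: float = 0.95,
) -> tuple[tuple[float, float], bool]:
    """Concentration range the calibration can reliably resolve.

    The lowest measurable fraction is the mean bound fraction of the
    zero-calcium replicates plus the half-width of its ``confidence`` CI
    (Student-t, mean of n replicates); the highest measurable fraction is
    the saturating-buffer mean minus its half-width.  Both are pushed through
    the inverse Hill equation.

    Returns ``((L_lo_nM, L_hi_nM), degenerate)``; zero replicate variance at
    either extreme yields the full range ``(0, inf)`` with ``degenerate``
    True.
    """
    lo = np.asarray(low_fractions, dtype=float)
    hi = np.asarray(high_fractions, dtype=float)
    if lo.size < 2 or hi.size < 2:
        raise ValueError("need >= 2 replicates per extreme")
    if lo.std(ddof=1) == 0.0 or hi.std(ddof=1) == 0.0:
        return (0.0, np.inf), True

    def half_width(x):
        tq = stats.t.ppf(0.5 + confidence / 2.0, x.size - 1)
        return tq * x.std(ddof=1) / np.sqrt(x.size)

    f_lowest = lo.mean() + half_width(lo)
    f_highest = hi.mean() - half_width(hi)
    l_lo, _ = concentration_from_fraction(float(f_lowest), result.params)
    l_hi, _ = concentration_from_fraction(float(f_highest), result.params)
    return (l_lo, l_hi), False


def phasor_image_to_ca_map(
    G_img: np.ndarray,
    S_img: np.ndarray,
    result: CalibrationResult,
    mask: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert per-pixel phasor images to a calcium-concentration map.

    Pixelwise: project onto the calibration line, correct with R, invert the
    Hill equation.  Below-range pixels clamp to 0 nM, saturated pixels to the
    +inf sentinel; masked-out pixels are NaN.  Returns ``(ca_nM, flags)``
    with flag codes FLAG_OK/BELOW/SATURATED/MASKED.
    """
    G_img = np.asarray(G_img, dtype=float)
    S_img = np.asarray(S_img, dtype=float)
    if G_img.shape != S_img.shape:
        raise ValueError(f"shape mismatch: {G_img.shape} vs {S_img.shape}")
    a = project_line_fraction((G_img, S_img), result.endpoints)
    f = bound_fraction(a, result.endpoints.R)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != G_img.shape:
            raise ValueError("mask shape mismatch")
        f = np.where(mask, f, np.nan)
    ca, flags = concentration_from_fraction(f, result.params)
    return ca, flags


def estimate_extremes_from_timelapse(
    G_stack: np.ndarray,
    S_stack: np.ndarray,
    R: float,
    mod: ModulationSettings = ModulationSettings(),
    n_baseline: int = 1,
    n_saturated: int = 1,
    low_percentile: float = 5.0,
    high_percentile: float = 95.0,
    mask: Optional[np.ndarray] = None,
) -> CalibrationEndpoints:
    """Estimate apo/sat endpoints from a timelapse ending in saturation.

    The sensor's lifetime *drops* on calcium binding, so the saturated
    (phasor_max) endpoint is the median phasor of pixels in the lowest
    ``low_percentile`` phase-lifetime band of the final ``n_saturated``
    frames (post saturation, e.g. after digitonin), and the apo endpoint
    (phasor_min) is the median phasor of pixels in the highest
    ``high_percentile`` band of the first ``n_baseline`` baseline frames.
    """
    G_stack = np.asarray(G_stack, dtype=float)
    S_stack = np.asarray(S_stack, dtype=float)
    if G_stack.ndim != 3 or G_stack.shape != S_stack.shape:
        raise ValueError("expected matching (t, y, x) stacks")
    if G_stack.shape[0] < 2:
        raise ValueError("timelapse must have at least 2 frames")

    def centroid(g_frames, s_frames, band_low: bool) -> PhasorPoint:
        g = g_frames.ravel()
        s = s_frames.ravel()
        if mask is not None:
            m = np.broadcast_to(np.asarray(mask, dtype=bool), g_frames.shape).ravel()
            g, s = g[m], s[m]
        tau_phi, _ = phasor_to_lifetime((g, s), mod)
        tau_phi = np.where(np.isfinite(tau_phi), tau_phi, np.nan)
        if band_low:
            thr = np.nanpercentile(tau_phi, low_percentile)
            sel = tau_phi <= thr
        else:
            thr = np.nanpercentile(tau_phi, high_percentile)
            sel = tau_phi >= thr
        return PhasorPoint(float(np.median(g[sel])), float(np.median(s[sel])))

    p_min = centroid(G_stack[:n_baseline], S_stack[:n_baseline], band_low=False)
    p_max = centroid(G_stack[-n_saturated:], S_stack[-n_saturated:], band_low=True)
    return CalibrationEndpoints(phasor_min=p_min, phasor_max=p_max, R=R)
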