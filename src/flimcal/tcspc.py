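"""Time-domain (TCSPC) decay modeling and lifetime estimation.

Photon arrival times after a laser pulse are modeled as a mixture of

* a uniform background over the acquisition window [0, t_max] with weight
  ``eps`` (uncorrelated noise counts), and
* up to two exponential decay components convolved with a Gaussian
  instrument response of center ``mu`` and width ``sigma``, with weights
  ``f1`` and ``f2``, where ``eps + f1 + f2 = 1``.

Each convolved component is the exponentially-modified-Gaussian density

    F(t; tau, sigma, mu) = 1/(2 tau) * exp(sigma^2/(2 tau^2) - (t-mu)/tau)
                           * erfc((sigma/tau - (t-mu)/sigma) / sqrt(2))

which integrates to one over the real line; over a finite window that is
accurate whenever the pulse sits well inside it (mu - 5 sigma > 0 and
t_max >> tau).

Fitting minimizes the Pearson chi-squared between the observed histogram and
the binned model expectation.  The *empirical lifetime* then summarizes a
histogram nonparametrically: the mean photon arrival time minus the fitted
IRF offset and the mean contribution of the uniform background,

    L = <t> - (mu + eps * t_max / 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import optimize, special

from .phasor import ModulationSettings, PhasorPoint

__all__ = [
    "DecayModel",
    "ArrivalHistogram",
    "FrameSeries",
    "decay_pdf",
    "fit_decay",
    "empirical_lifetime",
    "intensity_weighted_lifetime",
    "phasor_from_histogram",
    "foreground_mask",
]


@dataclass(frozen=True)
class DecayModel:
    """Parameters of the TCSPC arrival-time density.

    eps : uniform-background weight; f1, f2 : component weights
    (eps + f1 + f2 = 1); tau1_ns <= tau2_ns : component time constants;
    sigma_ns, mu_ns : Gaussian IRF width and center.
    """

    eps: float
    f1: float
    f2: float
    tau1_ns: float
    tau2_ns: float
    sigma_ns: float
    mu_ns: float

    def __post_init__(self) -> None:
        total = self.eps + self.f1 + self.f2
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"eps + f1 + f2 must be 1, got {total}")
        for name in ("eps", "f1", "f2", "tau1_ns", "tau2_ns", "sigma_ns", "mu_ns"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.f1 > 0 and self.tau1_ns == 0:
            raise ValueError("tau1 = 0 with f1 > 0")
        if self.f2 > 0 and self.tau2_ns == 0:
            raise ValueError("tau2 = 0 with f2 > 0")
        if self.tau1_ns > self.tau2_ns:
            raise ValueError("canonical ordering requires tau1_ns <= tau2_ns")

    @staticmethod
    def mono(tau_ns: float, sigma_ns: float, mu_ns: float, eps: float = 0.0) -> "DecayModel":
        """Single-component model (f2 = 0)."""
        return DecayModel(
            eps=eps, f1=1.0 - eps, f2=0.0,
            tau1_ns=tau_ns, tau2_ns=tau_ns, sigma_ns=sigma_ns, mu_ns=mu_ns,
        )


@dataclass(frozen=True)
class ArrivalHistogram:
    """Binned photon arrival times over a window [0, t_max]."""

    bin_centers_ns: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.bin_centers_ns, dtype=float)
        c = np.asarray(self.counts)
        object.__setattr__(self, "bin_centers_ns", t)
        object.__setattr__(self, "counts", c)
        if t.ndim != 1 or t.size != c.size:
            raise ValueError("bin_centers and counts must be matching 1-D arrays")
        if t.size < 2:
            raise ValueError("histogram needs at least 2 bins")
        widths = np.diff(t)
        if not np.allclose(widths, widths[0], atol=1e-9):
            raise ValueError("bins must be uniform")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bin_width_ns(self) -> float:
        return float(self.bin_centers_ns[1] - self.bin_centers_ns[0])

    @property
    def t_max_ns(self) -> float:
        return float(self.bin_centers_ns.size * self.bin_width_ns)

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class FrameSeries:
    """Per-frame photon counts and empirical lifetimes of an acquisition."""

    intensities: np.ndarray
    lifetimes_ns: np.ndarray

    def __post_init__(self) -> None:
        i = np.asarray(self.intensities, dtype=float)
        lt = np.asarray(self.lifetimes_ns, dtype=float)
        object.__setattr__(self, "intensities", i)
        object.__setattr__(self, "lifetimes_ns", lt)
        if i.size != lt.size or i.size < 1:
            raise ValueError("need matching, non-empty intensity/lifetime arrays")
        if np.any(i < 0):
            raise ValueError("intensities must be non-negative")


def _emg_density(t: np.ndarray, tau: float, sigma: float, mu: float) -> np.ndarray:
    """Exponentially-modified-Gaussian density, numerically stable.

    Uses the scaled complementary error function so that sigma/tau ratios up
    to ~10 and far tails do not overflow.
    """
    t = np.asarray(t, dtype=float)
    if sigma <= 0:
        # pure exponential limit
        out = np.where(t >= mu, np.exp(-(t - mu) / tau) / tau, 0.0)
        return out
    u = (sigma / tau - (t - mu) / sigma) / np.sqrt(2.0)
    out = np.empty(t.shape, dtype=float)
    # erfcx branch: erfc(u) = erfcx(u) exp(-u^2); combining exponents gives
    # the Gaussian factor exp(-(t-mu)^2 / 2 sigma^2)
    safe = u > -20.0
    out[safe] = (
        0.5 / tau
        * special.erfcx(u[safe])
        * np.exp(-((t[safe] - mu) ** 2) / (2.0 * sigma**2))
    )
    # far right tail: erfc(u) -> 2, direct form no longer overflows
    far = ~safe
    if np.any(far):
        a = sigma**2 / (2.0 * tau**2) - (t[far] - mu) / tau
        out[far] = 0.5 / tau * np.exp(a) * (2.0 - special.erfc(-u[far]))
    return out


def decay_pdf(t, model: DecayModel, t_max_ns: float):
    """Arrival-time density p(t) of the mixture model over [0, t_max].

    p(t) = eps/t_max + f1 F(t; tau1) + f2 F(t; tau2); integrates to 1 over
    the window whenever the IRF and decay tails fit inside it.
    """
    t_arr = np.asarray(t, dtype=float)
    p = np.full(t_arr.shape, model.eps / t_max_ns, dtype=float)
    if model.f1 > 0:
        p += model.f1 * _emg_density(t_arr, model.tau1_ns, model.sigma_ns, model.mu_ns)
    if model.f2 > 0:
        p += model.f2 * _emg_density(t_arr, model.tau2_ns, model.sigma_ns, model.mu_ns)
    if np.isscalar(t):
        return float(p)
    return p


def _simplex(logits: np.ndarray) -> np.ndarray:
    """Softmax: maps free logits to weights on the probability simplex."""
    z = np.concatenate([logits, [0.0]])
    z = z - z.max()
    w = np.exp(z)
    return w / w.sum()


def fit_decay(
    hist: ArrivalHistogram,
    init: Optional[DecayModel] = None,
    n_components: int = 2,
    min_counts: float = 1e4,
    n_starts: int = 8,
) -> tuple[DecayModel, dict]:
    """Fit the mixture decay model to an arrival histogram.

    Minimizes the Pearson chi-squared sum((obs - exp)^2 / exp) with the
    weights (eps, f1, f2) parameterized on the simplex by softmax, the time
    constants and IRF width on the log scale, and the IRF center free.  Tail
    bins are pooled (from the right) until each pooled bin has expected
    count >= 1, with the pooling fixed from the initial estimate.  Up to
    ``n_starts`` starting points spread the initial time constants over
    decades; the best chi-squared wins, ties broken by smaller tau1.

    Returns ``(model, diagnostics)`` with the model in canonical order
    (tau1 <= tau2) and diagnostics holding ``chi2``, ``dof``, ``converged``
    and the number of pooled bins.
    """
    if hist.total_counts <= 0:
        raise ValueError("histogram has no counts")
    if hist.total_counts < min_counts:
        raise ValueError(
            f"need >= {min_counts:g} photons for a stable fit, got {hist.total_counts:g}"
        )
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")

    t = hist.bin_centers_ns
    counts = np.asarray(hist.counts, dtype=float)
    dt = hist.bin_width_ns
    t_max = hist.t_max_ns
    n_total = counts.sum()

    # heuristics for the starting point
    if init is None:
        peak = t[np.argmax(counts)]
        mu0 = max(peak, dt)
        sigma0 = max(2 * dt, 0.05)
        tail_mean = float(np.sum(t * counts) / n_total) - mu0
        tau0 = float(np.clip(tail_mean, 0.1, t_max / 2))
        eps0 = 0.01
    else:
        mu0, sigma0 = init.mu_ns, max(init.sigma_ns, dt / 2)
        tau0 = max(init.tau1_ns, 1e-3)
        eps0 = max(init.eps, 1e-4)

    def pack(eps, f1, f2, tau1, tau2, sigma, mu):
        if n_components == 1:
            # simplex over (eps, f1): a single free logit
            return np.array([np.log(max(eps, 1e-8) / max(f1 + f2, 1e-8)),
                             np.log(tau1), np.log(sigma), mu])
        l_eps = np.log(max(eps, 1e-8))
        l_f1 = np.log(max(f1, 1e-8))
        l_f2 = np.log(max(f2, 1e-8))
        return np.array([l_eps - l_f2, l_f1 - l_f2, np.log(tau1), np.log(tau2),
                         np.log(sigma), mu])

    def unpack(theta):
        if n_components == 1:
            w = _simplex(theta[:1])
            eps, f1, f2 = w[0], w[1], 0.0
            tau1 = tau2 = float(np.exp(theta[1]))
            sigma, mu = float(np.exp(theta[2])), float(theta[3])
        else:
            w = _simplex(theta[:2])
            eps, f1, f2 = w[0], w[1], w[2]
            tau1, tau2 = float(np.exp(theta[2])), float(np.exp(theta[3]))
            sigma, mu = float(np.exp(theta[4])), float(theta[5])
        return eps, f1, f2, tau1, tau2, sigma, mu

    def expected(theta):
        eps, f1, f2, tau1, tau2, sigma, mu = unpack(theta)
        p = np.full(t.shape, eps / t_max)
        p = p + f1 * _emg_density(t, tau1, sigma, mu)
        if f2 > 0:
            p = p + f2 * _emg_density(t, tau2, sigma, mu)
        return n_total * p * dt

    # fixed tail pooling from the pilot estimate
    if n_components == 1:
        theta_pilot = pack(eps0, 1 - eps0, 0.0, tau0, tau0, sigma0, mu0)
    else:
        theta_pilot = pack(eps0, (1 - eps0) * 0.6, (1 - eps0) * 0.4,
                           tau0 * 0.7, tau0 * 1.5, sigma0, mu0)
    exp_pilot = expected(theta_pilot)
    # walk from the right edge, grouping bins until each group's expected >= 1
    edges = [t.size]
    acc = 0.0
    for i in range(t.size - 1, -1, -1):
        acc += exp_pilot[i]
        if acc >= 1.0:
            edges.append(i)
            acc = 0.0
    if edges[-1] != 0:
        edges.append(0)
    edges = np.array(edges[::-1])
    n_pooled = t.size - (edges.size - 1)

    def pooled(x):
        return np.add.reduceat(x, edges[:-1])

    obs_pooled = pooled(counts)

    def residuals(theta):
        e = pooled(expected(theta))
        e = np.maximum(e, 1e-12)
        return (obs_pooled - e) / np.sqrt(e)

    # multi-start over time-constant decades (deterministic).  Two-component
    # fits are anchored on a robust mono-component pre-fit: a single
    # component cannot trade the IRF center against a zero-lifetime spike,
    # so its (eps, sigma, mu) land in the right basin, and the component
    # starts then bracket its time constant.
    starts = [theta_pilot]
    if n_components == 2 and init is None:
        mono, _ = fit_decay(hist, n_components=1, min_counts=min_counts, n_starts=4)
        eps0, sigma0, mu0 = max(mono.eps, 1e-4), mono.sigma_ns, mono.mu_ns
        tau0 = mono.tau1_ns
        sig = 1.0 - eps0
        for (a, b), w1 in [((1.0, 1.05), 0.5), ((0.6, 1.4), 0.5), ((0.3, 1.0), 0.2),
                           ((1.0, 3.0), 0.8), ((0.8, 1.2), 0.5), ((0.25, 4.0), 0.5),
                           ((0.5, 2.0), 0.3)]:
            starts.append(pack(eps0, sig * w1, sig * (1 - w1),
                               tau0 * a, tau0 * b, sigma0, mu0))
        starts = starts[: max(n_starts, 2)]
    else:
        scales = [0.25, 0.5, 1.0, 2.0, 4.0]
        k = 0
        while len(starts) < n_starts:
            s1 = scales[k % len(scales)]
            s2 = scales[(k // len(scales) + 2) % len(scales)]
            if n_components == 1:
                starts.append(pack(eps0, 1 - eps0, 0.0, tau0 * s1, tau0 * s1, sigma0, mu0))
            else:
                starts.append(pack(eps0, (1 - eps0) * 0.5, (1 - eps0) * 0.5,
                                   tau0 * s1 * 0.7, tau0 * s2 * 1.5, sigma0, mu0))
            k += 1

    best = None
    # transient over/underflow while the optimizer probes extreme time
    # constants is expected and self-correcting
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        for theta0 in starts:
            try:
                sol = optimize.least_squares(residuals, theta0, method="lm",
                                             xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            chi2 = float(np.sum(sol.fun**2))
            tau1 = unpack(sol.x)[3]
            key = (round(chi2, 6), tau1)
            if best is None or key < best[0]:
                best = (key, sol, chi2)
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    _, sol, chi2 = best
    eps, f1, f2, tau1, tau2, sigma, mu = unpack(sol.x)
    if tau1 > tau2:  # canonical ordering
        tau1, tau2 = tau2, tau1
        f1, f2 = f2, f1
    # renormalize against softmax round-off
    total = eps + f1 + f2
    model = DecayModel(eps=eps / total, f1=f1 / total, f2=f2 / total,
                       tau1_ns=tau1, tau2_ns=tau2, sigma_ns=sigma, mu_ns=mu)
    diagnostics = {
        "chi2": chi2,
        "dof": int(obs_pooled.size - sol.x.size),
        "converged": bool(sol.success),
        "n_pooled_bins": int(n_pooled),
    }
    return model, diagnostics


def empirical_lifetime(hist: ArrivalHistogram, model: DecayModel) -> float:
    """Mean arrival time corrected for IRF offset and uniform background.

        L = <t> - (mu + eps * t_max / 2)

    with <t> the count-weighted mean bin center, mu and eps taken from the
    (fitted or supplied) model.  Invariant to rescaling the counts.
    """
    if hist.total_counts <= 0:
        raise ValueError("empty histogram")
    mean_t = float(np.sum(hist.bin_centers_ns * hist.counts) / hist.total_counts)
    return mean_t - (model.mu_ns + model.eps * hist.t_max_ns / 2.0)


def intensity_weighted_lifetime(frames: FrameSeries) -> float:
    """Mean lifetime of a frame series weighted by frame intensity.

        <L> = sum_k I_k L_k / (n <I>)

    where n is the number of frames and <I> the mean frame intensity.
    """
    i = frames.intensities
    total = i.sum()
    if total <= 0:
        raise ValueError("all-zero intensities")
    return float(np.sum(i * frames.lifetimes_ns) / total)


def phasor_from_histogram(
    hist: ArrivalHistogram,
    mod: ModulationSettings = ModulationSettings(),
    zero_time_ns: float = 0.0,
) -> PhasorPoint:
    """Time-domain phasor of an arrival histogram.

    G and S are the count-weighted cosine/sine transforms at the modulation
    frequency, referenced to ``zero_time_ns`` (typically the IRF center).
    """
    if hist.total_counts <= 0:
        raise ValueError("empty histogram")
    w = mod.omega_rad_per_ns
    phase = w * (hist.bin_centers_ns - zero_time_ns)
    c = hist.counts
    g = float(np.sum(c * np.cos(phase)) / hist.total_counts)
    s = float(np.sum(c * np.sin(phase)) / hist.total_counts)
    return PhasorPoint(g, s)


def foreground_mask(
    image: np.ndarray,
    method: str = "otsu",
    quantile: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Foreground (signal) mask of an intensity image.

    method "otsu" thresholds the intensity histogram by Otsu's criterion;
    "quantile" keeps pixels above the given intensity quantile (rank-based,
    hence invariant to monotone intensity rescaling).  Returns
    ``(mask, threshold)``; a constant image yields an all-background mask
    with a warning.
    """
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("intensity image must be non-negative")
    if image.max() == image.min():
        warnings.warn("constant image: returning all-background mask", stacklevel=2)
        return np.zeros(image.shape, dtype=bool), float(image.max())
    if method == "otsu":
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(image))
    elif method == "quantile":
        thr = float(np.quantile(image, quantile))
    else:
        raise ValueError(f"unknown method {method!r}")
    return image > thr, thr
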