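"""Small reporting computations: SNR over an ROI, ratiometric
normalization against control constructs, and per-condition lifetime-change
summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["snr_report", "ratio_normalize", "lifetime_change_summary"]


def snr_report(
    lifetime_image: np.ndarray,
    roi: tuple[int, int, int, int],
    expected_pixels: Optional[int] = 400,
) -> tuple[float, float, float]:
    """Mean, sd and SNR (= mean/sd) of the lifetime over a rectangular ROI.

    ``roi`` is (row, col, height, width).  By convention the ROI covers a
    fixed pixel count (default 400, e.g. 20x20) so SNR values are comparable
    between cells; pass ``expected_pixels=None`` to lift the constraint.
    A constant ROI reports SNR = inf.
    """
    img = np.asarray(lifetime_image, dtype=float)
    r, c, h, w = roi
    if r < 0 or c < 0 or r + h > img.shape[0] or c + w > img.shape[1]:
        raise ValueError(f"ROI {roi} outside image of shape {img.shape}")
    if expected_pixels is not None and h * w != expected_pixels:
        raise ValueError(f"ROI has {h * w} pixels, expected {expected_pixels}")
    patch = img[r : r + h, c : c + w]
    mean = float(patch.mean())
    sd = float(patch.std(ddof=1))
    snr = np.inf if sd == 0 else mean / sd
    return mean, sd, snr


def ratio_normalize(
    green: np.ndarray,
    red: np.ndarray,
    egfp_control_ratio: float,
    no_gfp_control_ratio: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize per-cell green/red ratios against two controls.

    The raw ratio green/red is mapped linearly so the no-GFP control is 0
    and the EGFP control is 1.  Cells with red mean <= 0 cannot be
    ratioed: they come back NaN and are flagged in the returned boolean
    ``excluded`` array.

    Returns ``(normalized, excluded)``.
    """
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape:
        raise ValueError("green and red arrays must match")
    if egfp_control_ratio == no_gfp_control_ratio:
        raise ValueError("control ratios must be distinct")
    excluded = red <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(excluded, np.nan, green / np.where(excluded, 1.0, red))
    normalized = (raw - no_gfp_control_ratio) / (egfp_control_ratio - no_gfp_control_ratio)
    return normalized, excluded


@dataclass(frozen=True)
class LifetimeChange:
    """Per-condition lifetime summary; change = mean_post - mean_pre (ns)."""

    mean_pre: float
    sd_pre: float
    mean_post: float
    sd_post: float
    change: float

    def formatted(self) -> str:
        """Two-decimal presentation, matching common table style."""
        return (
            f"pre {self.mean_pre:.2f} ± {self.sd_pre:.2f} ns, "
            f"post {self.mean_post:.2f} ± {self.sd_post:.2f} ns, "
            f"change {self.change:+.2f} ns"
        )


def lifetime_change_summary(pre, post) -> LifetimeChange:
    """Summarize per-cell lifetimes before/after a treatment.

    The change is the mean lifetime in the high-calcium (post) condition
    minus the low-calcium (pre) condition; values are kept at full precision
    and rounded only at presentation.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("each condition needs at least one cell")
    sd = lambda x: float(x.std(ddof=1)) if x.size > 1 else 0.0
    return LifetimeChange(
        mean_pre=float(pre.mean()),
        sd_pre=sd(pre),
        mean_post=float(post.mean()),
        sd_post=sd(post),
        change=float(post.mean() - pre.mean()),
    )
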