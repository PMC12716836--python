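"""File formats: CSV tables, float TIFF image stacks, and calibration JSON.

Conventions
-----------
calibration series CSV : columns ``replicate, free_ca_nM`` and either
    ``g, s`` or ``tau_phi_ns, tau_mod_ns``.
histogram CSV : columns ``t_ns, counts`` (one pixel) or ``t_ns`` plus one
    column per pixel id (wide form).
spectrum CSV : columns ``wavelength_nm, value``.
images : single-channel float32 multi-page TIFF, one page per timepoint;
    concentration maps as float32 nM plus a uint8 flag TIFF
    (0 ok, 1 below range, 2 saturated, 3 masked).
calibration JSON : kd_nM, hill_n, f_min, f_max, ci95, endpoints
    {g_min, s_min, g_max, s_max, r}, freq_MHz, measurable_range_nM.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile

from .calibration import CalibrationResult, CalibrationSeries, HillParams
from .phasor import CalibrationEndpoints, ModulationSettings, PhasorPoint
from .photophysics import DilutionSeries, Spectrum
from .tcspc import ArrivalHistogram, DecayModel

__all__ = [
    "read_calibration_series",
    "write_calibration_series",
    "read_histogram",
    "write_histogram",
    "read_spectrum",
    "write_spectrum",
    "read_dilution_series",
    "read_image_stack",
    "write_image_stack",
    "write_ca_map",
    "read_calibration_json",
    "write_calibration_json",
    "write_decay_model_json",
    "read_decay_model_json",
]

PathLike = Union[str, Path]


def read_calibration_series(path: PathLike, frequency_MHz: float = 40.0) -> CalibrationSeries:
    df = pd.read_csv(path)
    return CalibrationSeries(df, modulation=ModulationSettings(frequency_MHz))


def write_calibration_series(series: CalibrationSeries, path: PathLike) -> None:
    series.data.to_csv(path, index=False)


def read_histogram(path: PathLike, column: Optional[str] = None) -> ArrivalHistogram:
    """Read one histogram; ``column`` selects a pixel in wide CSVs."""
    df = pd.read_csv(path)
    if "t_ns" not in df.columns:
        raise ValueError("histogram CSV needs a t_ns column")
    if column is None:
        column = "counts" if "counts" in df.columns else df.columns[1]
    return ArrivalHistogram(
        bin_centers_ns=df["t_ns"].to_numpy(float),
        counts=df[column].to_numpy(),
    )


def write_histogram(hist: ArrivalHistogram, path: PathLike) -> None:
    pd.DataFrame({"t_ns": hist.bin_centers_ns, "counts": hist.counts}).to_csv(
        path, index=False
    )


def read_spectrum(path: PathLike, kind: str = "emission") -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(df["wavelength_nm"].to_numpy(float), df["value"].to_numpy(float), kind)


def write_spectrum(spec: Spectrum, path: PathLike) -> None:
    pd.DataFrame({"wavelength_nm": spec.wavelengths_nm, "value": spec.values}).to_csv(
        path, index=False
    )


def read_dilution_series(path: PathLike, label: Optional[str] = None) -> DilutionSeries:
    """Read a dilution series CSV (columns label, a450, i_em)."""
    df = pd.read_csv(path)
    if label is not None:
        df = df[df["label"] == label]
    return DilutionSeries(
        a450=df["a450"].to_numpy(float),
        i_em=df["i_em"].to_numpy(float),
        label=label or str(df["label"].iloc[0]) if "label" in df.columns else "sample",
    )


def read_image_stack(path: PathLike) -> np.ndarray:
    """Read a (t, y, x) float stack; single pages gain a leading axis."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return np.asarray(arr, dtype=np.float32)


def write_image_stack(stack: np.ndarray, path: PathLike) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def write_ca_map(ca_nM: np.ndarray, flags: np.ndarray, path: PathLike) -> tuple[Path, Path]:
    """Write a concentration map (float32 nM) and its flag channel (uint8).

    The flag file sits next to the map with a ``_flags`` suffix.
    """
    path = Path(path)
    flag_path = path.with_name(path.stem + "_flags" + path.suffix)
    tifffile.imwrite(path, np.asarray(ca_nM, dtype=np.float32),
                     photometric="minisblack")
    tifffile.imwrite(flag_path, np.asarray(flags, dtype=np.uint8),
                     photometric="minisblack")
    return path, flag_path


def write_calibration_json(result: CalibrationResult, path: PathLike,
                           frequency_MHz: float = 40.0) -> None:
    ends = result.endpoints
    payload = {
        "kd_nM": result.params.Kd_nM,
        "hill_n": result.params.hill_n,
        "f_min": result.params.F_min,
        "f_max": result.params.F_max,
        "ci95": {k: list(v) for k, v in result.ci95.items()},
        "endpoints": {
            "g_min": ends.phasor_min.G,
            "s_min": ends.phasor_min.S,
            "g_max": ends.phasor_max.G,
            "s_max": ends.phasor_max.S,
            "r": ends.R,
        },
        "freq_MHz": frequency_MHz,
        "measurable_range_nM": (
            list(result.measurable_range_nM) if result.measurable_range_nM else None
        ),
        "residual_norm": result.residual_norm,
        "converged": result.converged,
    }
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2))


def read_calibration_json(path: PathLike) -> CalibrationResult:
    d = json.loads(Path(path).read_text())
    e = d["endpoints"]
    rng = d.get("measurable_range_nM")
    return CalibrationResult(
        params=HillParams(d["kd_nM"], d["hill_n"], d["f_min"], d["f_max"]),
        ci95={k: tuple(v) for k, v in d.get("ci95", {}).items()},
        endpoints=CalibrationEndpoints(
            phasor_min=PhasorPoint(e["g_min"], e["s_min"]),
            phasor_max=PhasorPoint(e["g_max"], e["s_max"]),
            R=e["r"],
        ),
        residual_norm=d.get("residual_norm", float("nan")),
        converged=d.get("converged", True),
        measurable_range_nM=tuple(rng) if rng else None,
    )


def write_decay_model_json(model: DecayModel, path: PathLike,
                           diagnostics: Optional[dict] = None) -> None:
    payload = {
        "eps": model.eps,
        "f1": model.f1,
        "f2": model.f2,
        "tau1_ns": model.tau1_ns,
        "tau2_ns": model.tau2_ns,
        "sigma_ns": model.sigma_ns,
        "mu_ns": model.mu_ns,
    }
    if diagnostics:
        payload["chi2"] = diagnostics.get("chi2")
        payload["converged"] = diagnostics.get("converged")
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2))


def read_decay_model_json(path: PathLike) -> DecayModel:
    d = json.loads(Path(path).read_text())
    return DecayModel(
        eps=d["eps"], f1=d["f1"], f2=d["f2"],
        tau1_ns=d["tau1_ns"], tau2_ns=d["tau2_ns"],
        sigma_ns=d["sigma_ns"], mu_ns=d["mu_ns"],
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj
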