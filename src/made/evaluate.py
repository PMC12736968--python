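"""Evaluation harness: angular-error metrics, (φ × v) sweeps and combined
performance maps over synthetic frames."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .directions import NoObjectError
from .geometry import NoArtifactError, estimate
from .simulate import MotionParameters, PSFSpec, render_object_trail

__all__ = [
    "SweepRecord",
    "angular_error",
    "orientation_error",
    "run_sweep",
    "performance_map",
    "fit_velocity_trend",
]

SWEEP_COLUMNS = ["phi_gt", "v", "theta_est", "q_est", "AE", "AE180"]


@dataclass
class SweepRecord:
    phi_gt: float
    v: float
    theta_est: float  # NaN when estimation failed
    q_est: float
    AE: float
    AE180: float


def angular_error(theta_est: float, phi_gt: float) -> float:
    """Circular distance in degrees, in [0, 180]; symmetric in its arguments."""
    d = abs(theta_est % 360.0 - phi_gt % 360.0)
    return min(d, 360.0 - d)


def orientation_error(theta_est: float, phi_gt: float) -> float:
    """Orientation-class error in [0, 90]: complements (±180°) count as correct."""
    ae = angular_error(theta_est, phi_gt)
    return min(ae, 180.0 - ae)


def run_sweep(
    phis,
    vs,
    sim: MotionParameters | None = None,
    psf: PSFSpec | None = None,
    config: PipelineConfig | None = None,
    object_radius: float = 1.1,
    shape: tuple[int, int] = (256, 256),
) -> pd.DataFrame:
    """One estimate per (φ, v) cell; deterministic for fixed inputs.

    Estimation failures (blank frame / no artifact signal) are recorded as
    NaN θ and q = 0, never aborts.
    """
    if len(phis) == 0 or len(vs) == 0:
        raise ValueError("phis and vs must be nonempty")
    sim = sim or MotionParameters()
    psf = psf or PSFSpec()
    cfg = config or PipelineConfig()
    records = []
    for phi in phis:
        for v in vs:
            params = MotionParameters(
                A=sim.A, omega=sim.omega, v=float(v), phi=float(phi),
                T=sim.T, s=sim.s, pixels_per_meter=sim.pixels_per_meter,
            )
            frame = render_object_trail(params, psf, object_radius, shape)
            try:
                est = estimate(frame.intensities, cfg)
                theta, q = est.theta, est.q
                ae = angular_error(theta, phi)
                ae180 = orientation_error(theta, phi)
            except (NoObjectError, NoArtifactError):
                theta, q, ae, ae180 = math.nan, 0.0, math.nan, math.nan
            records.append(SweepRecord(float(phi), float(v), theta, q, ae, ae180))
    return pd.DataFrame([vars(r) for r in records], columns=SWEEP_COLUMNS)


def _minmax(col: np.ndarray) -> np.ndarray:
    """Min–max normalise; a constant (degenerate) column maps to zeros."""
    finite = np.isfinite(col)
    if not finite.any():
        return np.zeros_like(col)
    lo, hi = np.nanmin(col), np.nanmax(col)
    if hi - lo <= 0:
        return np.zeros_like(col)
    out = (col - lo) / (hi - lo)
    return np.where(finite, out, 1.0)  # failed estimates score worst


def performance_map(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Combined per-cell score in [0, 1]: mean of the min–max-normalised
    orientation error and the min–max-normalised magnitude deficit (1 − q̂).

    0 = best (low direction error, strong magnitude response); 1 marks a
    boundary limitation.  Normalisation bounds are taken over the evaluated
    grid and returned so scores are reproducible.
    """
    df = records.copy()
    err = _minmax(df["AE180"].to_numpy(dtype=float))
    qn = _minmax(df["q_est"].to_numpy(dtype=float))
    q_const = np.nanmax(df["q_est"].to_numpy(dtype=float)) <= np.nanmin(
        df["q_est"].to_numpy(dtype=float)
    )
    deficit = np.zeros_like(qn) if q_const else 1.0 - qn
    df["score"] = 0.5 * (err + deficit)
    bounds = {
        "ae180_min": float(np.nanmin(records["AE180"])) if np.isfinite(records["AE180"]).any() else 0.0,
        "ae180_max": float(np.nanmax(records["AE180"])) if np.isfinite(records["AE180"]).any() else 0.0,
        "q_min": float(np.nanmin(records["q_est"])),
        "q_max": float(np.nanmax(records["q_est"])),
    }
    grid = df.pivot_table(index="phi_gt", columns="v", values="score", aggfunc="mean")
    return grid, bounds


def fit_velocity_trend(records: pd.DataFrame, column: str = "AE180", degree: int = 2):
    """Least-squares polynomial trend of a sweep column against velocity.

    A reporting utility for summarising how direction error or magnitude
    varies across the velocity range; returns (coefficients, fitted values
    per unique velocity).
    """
    by_v = records.groupby("v")[column].mean().dropna()
    coeffs = np.polyfit(by_v.index.to_numpy(), by_v.to_numpy(), degree)
    fitted = np.polyval(coeffs, by_v.index.to_numpy())
    return coeffs, pd.Series(fitted, index=by_v.index, name=f"{column}_trend")
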