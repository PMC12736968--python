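"""Movement Artifact Quantification (MAQ).

For each scanline the signed displacement between the ROPE reference origin
and the nearest valid artifact candidate is computed.  The MAPE lag l maps to
two candidate positions — p = g + l and its complement p̄ = g − l under the
default mapping — and the candidate closer to the origin wins (ties toward
g − p).  Displacements whose magnitude exceeds the plausibility threshold
tau_maq are suppressed (recorded as NaN, never zero-filled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MAQSet", "maq_scanline", "maq_matrix"]

_LAG_MAPPINGS = ("origin_offset",)


@dataclass
class MAQSet:
    """Per-scanline quantified displacements for one direction.

    ``values`` holds the signed q_i; NaN marks missing or suppressed entries
    and ``suppressed`` distinguishes the two.  ``evaluated`` flags scanlines
    where MAQ ran at all (a retained reference origin existed): those are the
    K_d "lines" over which the directional mean is taken.
    """

    direction: str
    values: np.ndarray
    suppressed: np.ndarray
    evaluated: np.ndarray
    tau_maq: float

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def n_lines(self) -> int:
        return int(self.evaluated.sum())


def maq_scanline(
    g: float | None,
    p: float | None,
    p_bar: float | None,
    tau_maq: float,
) -> float:
    """Piecewise displacement rule for one scanline; NaN encodes missing.

    missing origin -> missing; only p̄ -> g−p̄; only p -> g−p; both ->
    g−p if |g−p| <= |g−p̄| else g−p̄; finally |q| > tau_maq -> suppressed
    (NaN).  Total over all missing patterns.
    """
    if tau_maq <= 0:
        raise ValueError("tau_maq must be > 0")

    def missing(v) -> bool:
        return v is None or (isinstance(v, float) and np.isnan(v))

    if missing(g):
        return float("nan")
    if missing(p) and missing(p_bar):
        return float("nan")
    if missing(p):
        q = g - p_bar
    elif missing(p_bar):
        q = g - p
    else:
        q = g - p if abs(g - p) <= abs(g - p_bar) else g - p_bar
    return float("nan") if abs(q) > tau_maq else float(q)


def maq_matrix(
    origins,
    peaks,
    tau_maq: float = 112.0,
    lag_mapping: str = "origin_offset",
    direction: str = "horizontal",
) -> MAQSet:
    """Apply the scanline rule across a direction.

    The default ``origin_offset`` mapping anchors each detected lag l at the
    scanline's own origin: p = g + l, p̄ = g − l, so |q| = |l| whenever both
    candidates exist.
    """
    if lag_mapping not in _LAG_MAPPINGS:
        raise ValueError(f"unknown lag_mapping {lag_mapping!r}")
    g = np.asarray(origins.origins, dtype=float)
    lags = np.asarray(peaks.lags, dtype=float)
    if g.shape != lags.shape:
        raise ValueError("origins and peaks must index the same scanlines")
    values = np.full(len(g), np.nan)
    suppressed = np.zeros(len(g), dtype=bool)
    evaluated = np.isfinite(g)
    for i in range(len(g)):
        gi = g[i] if np.isfinite(g[i]) else float("nan")
        if np.isfinite(lags[i]):
            p, p_bar = gi + lags[i], gi - lags[i]
        else:
            p = p_bar = float("nan")
        q = maq_scanline(gi, p, p_bar, tau_maq)
        values[i] = q
        if (
            np.isnan(q)
            and np.isfinite(gi)
            and (np.isfinite(p) or np.isfinite(p_bar))
        ):
            suppressed[i] = True
    return MAQSet(direction, values, suppressed, evaluated, tau_maq)
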