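"""Reference Origin Position Estimation (ROPE).

Each scanline is smoothed with an exponential moving average; the dominant
intensity transition — the index where the first difference of the smoothed
signal attains its maximum absolute value — anchors the undistorted object
edge.  A scanline's origin is retained only if its maximum slope magnitude
reaches tau_rope times the largest maximum slope across all scanlines, which
rejects scanlines that merely graze the object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["ReferenceOrigins", "ema_smooth", "slope_sequence", "reference_origins"]


@dataclass
class ReferenceOrigins:
    """Per-scanline origin indices (NaN = not retained) plus diagnostics."""

    origins: np.ndarray       # float; NaN where rejected
    max_slopes: np.ndarray    # per-row max |slope|
    threshold: float          # T = tau * max_i max_slopes[i]

    @property
    def retained(self) -> np.ndarray:
        return np.isfinite(self.origins)


def ema_smooth(x: np.ndarray, alpha: float) -> np.ndarray:
    """EMA_1 = x_1; EMA_j = alpha·x_j + (1−alpha)·EMA_{j−1}."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        if len(x) < 2:
            raise ValueError("need at least 2 samples")
        zi = np.array([(1 - alpha) * x[0]])
        y, _ = signal.lfilter([alpha], [1.0, alpha - 1.0], x, zi=zi)
        return y
    zi = (1 - alpha) * x[:, :1]
    y, _ = signal.lfilter([alpha], [1.0, alpha - 1.0], x, axis=1, zi=zi)
    return y


def slope_sequence(ema: np.ndarray) -> np.ndarray:
    """First differences; index j refers to the left endpoint."""
    ema = np.asarray(ema, dtype=float)
    if ema.shape[-1] < 2:
        raise ValueError("need at least 2 samples")
    return np.diff(ema, axis=-1)


def reference_origins(
    norm, alpha: float = 0.3, tau_rope: float = 0.3
) -> ReferenceOrigins:
    """Dominant-transition origin per scanline of a NormalizedMatrix.

    Per row i, g_i = argmax_j |s_{i,j}| (ties to the smallest j).  The global
    threshold is T = tau_rope · max_i v_i with v_i the row's maximum |slope|;
    rows with v_i >= T keep their origin, others are NaN.  Invalid
    (zero-spread) rows never yield an origin.
    """
    if not (0 < tau_rope <= 1):
        raise ValueError("tau_rope must lie in (0, 1]")
    values = norm.values
    valid = np.asarray(norm.valid_row_mask, dtype=bool)
    slopes = slope_sequence(ema_smooth(values, alpha))
    abs_s = np.abs(slopes)
    g = abs_s.argmax(axis=1)
    vmax = abs_s[np.arange(len(g)), g]
    vmax = np.where(valid, vmax, 0.0)
    top = vmax.max() if len(vmax) else 0.0
    threshold = tau_rope * top
    retained = valid & (vmax >= threshold) & (vmax > 0)
    origins = np.where(retained, g.astype(float), np.nan)
    return ReferenceOrigins(origins, vmax, threshold)
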