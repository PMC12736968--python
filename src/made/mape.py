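"""Movement Artifact Position Estimation (MAPE).

Each z-normalised scanline is correlated with itself over every integer lag
(zero padding outside the support) and normalised by the zero-lag energy,
giving a self-similarity profile r[l] with r[0] = 1, |r| <= 1 and exact
symmetry r[l] = r[-l].  A blur replica displaced by d pixels shows up as a
pair of secondary peaks at lags ±d; the lag of the second most prominent peak
(prominence measured against the lowest surrounding contour line) is the
per-scanline artifact position estimate.  The complement set is the exact
negation of the detected lags, encoding the bidirectionality of motion blur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "SelfSimilarityProfile",
    "PeakLocations",
    "self_similarity",
    "find_prominent_peaks",
    "second_peak_lag",
    "scan_matrix",
]


@dataclass
class SelfSimilarityProfile:
    lags: np.ndarray       # -(N-1) .. N-1
    values: np.ndarray     # r[l]
    valid: bool = True

    def __getitem__(self, lag: int) -> float:
        n = (len(self.values) + 1) // 2
        return float(self.values[lag + n - 1])


@dataclass
class PeakLocations:
    """Per-scanline second-peak lags (NaN = missing) and the lag sets."""

    lags: np.ndarray
    p_loc: set = field(default_factory=set)
    p_loc_complement: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        detected = {int(l) for l in self.lags[np.isfinite(self.lags)]}
        self.p_loc = detected
        self.p_loc_complement = {-l for l in detected}


def self_similarity(x: np.ndarray) -> SelfSimilarityProfile:
    """Normalised self-similarity profile of one scanline.

    a[l] = sum_n x[n]·x[n−l] with zero padding; the normaliser is the
    zero-lag energy E = sum x², so r = a/E satisfies r[0] = 1 (valid rows)
    and r[l] = r[−l] exactly.  An all-zero scanline yields an all-zero
    profile flagged invalid.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("scanline must have length >= 2")
    lags = np.arange(-(n - 1), n)
    energy = float(np.dot(x, x))
    if energy <= 0:
        return SelfSimilarityProfile(lags, np.zeros(2 * n - 1), valid=False)
    a = np.correlate(x, x, mode="full")
    return SelfSimilarityProfile(lags, a / energy, valid=True)


def find_prominent_peaks(
    profile: SelfSimilarityProfile, min_prominence: float = 0.1
) -> list[tuple[int, float]]:
    """Local maxima of r with prominence >= min_prominence · r[0].

    Returns (lag, prominence) pairs sorted by lag.  Prominence follows the
    lowest-contour-line definition (scipy's peak_prominences).
    """
    r = profile.values
    if not profile.valid:
        return []
    n = (len(r) + 1) // 2
    r0 = r[n - 1]
    idx, props = signal.find_peaks(r, prominence=min_prominence * r0)
    return sorted(
        (int(i - (n - 1)), float(p)) for i, p in zip(idx, props["prominences"])
    )


def second_peak_lag(
    profile: SelfSimilarityProfile, min_prominence: float = 0.1
) -> int | None:
    """Lag of the most prominent qualifying peak excluding lag 0.

    Ties in prominence resolve toward smaller |lag|, then the positive lag;
    the complement set restores the mirrored candidate regardless.
    """
    peaks = [(l, p) for l, p in find_prominent_peaks(profile, min_prominence) if l != 0]
    if not peaks:
        return None
    peaks.sort(key=lambda lp: (-lp[1], abs(lp[0]), -np.sign(lp[0])))
    return peaks[0][0]


def scan_matrix(
    norm, min_prominence: float = 0.1, row_mask: np.ndarray | None = None
) -> PeakLocations:
    """Second-peak lag per scanline of a NormalizedMatrix.

    Invalid rows (and rows excluded by ``row_mask``) yield NaN, never zero.
    """
    values = norm.values
    valid = norm.valid_row_mask
    lags = np.full(len(values), np.nan)
    for i in range(len(values)):
        if not valid[i]:
            continue
        if row_mask is not None and not row_mask[i]:
            continue
        lag = second_peak_lag(self_similarity(values[i]), min_prominence)
        if lag is not None:
            lags[i] = lag
    return PeakLocations(lags)
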