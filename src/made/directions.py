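"""Directional scanline extraction and row normalisation.

A centered square frame is decomposed into four stacks of 1-D scanlines —
horizontal, diagonal (the 45° screen axis), vertical and antidiagonal (135°) —
so that the same scanline pipeline (MAPE → ROPE → MAQ) can be run along each
principal direction.  Under the package's screen convention (x = column
rightward, y = row downward, angles clockwise), the 45° family collects pixels
with constant j−i and the 135° family pixels with constant i+j.

Diagonal scanlines have unequal native lengths; only the central band of
diagonals at least ``min_length_frac``·M long is retained, and each retained
row is centre-aligned and padded with its own edge values to the common
length M, avoiding spurious step edges at the padding boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DIRECTIONS = ("horizontal", "diagonal", "vertical", "antidiagonal")
#: on-screen angle of each scanline family, degrees
DIRECTION_ANGLES = {"horizontal": 0.0, "diagonal": 45.0,
                    "vertical": 90.0, "antidiagonal": 135.0}

__all__ = [
    "DIRECTIONS",
    "DIRECTION_ANGLES",
    "DirectionalMatrix",
    "NormalizedMatrix",
    "NoObjectError",
    "crop_center",
    "sum_diagonals",
    "difference_diagonals",
    "build_directional_matrices",
    "normalize_rows",
]


class NoObjectError(ValueError):
    """Raised when a frame contains no detectable dark object."""


@dataclass
class DirectionalMatrix:
    direction: str
    rows: np.ndarray  # K x L, rows are scanlines
    crop_window: tuple[int, int] = (0, 0)  # retained diagonal index range

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        self.rows = np.asarray(self.rows, dtype=float)


@dataclass
class NormalizedMatrix:
    direction: str
    values: np.ndarray
    valid_row_mask: np.ndarray = field(default=None)  # type: ignore[assignment]


def crop_center(
    image: np.ndarray,
    side: int = 224,
    object_fraction: float = 0.5,
    min_contrast: float = 0.02,
) -> np.ndarray:
    """Translate the dark object's intensity-weighted centroid to the frame
    centre and crop to a ``side``×``side`` window (white padding).

    The object threshold adapts to the frame's own contrast: pixels darker
    than background − ``object_fraction``·(background − darkest) count as
    object, weighted by their darkness below that threshold.  Raises
    :class:`NoObjectError` when the contrast range is below ``min_contrast``.
    """
    img = np.asarray(image, dtype=float)
    bg = img.max()
    if bg - img.min() < min_contrast:
        raise NoObjectError("no object detected")
    thresh = bg - object_fraction * (bg - img.min())
    w = np.clip(thresh - img, 0.0, None)
    ys, xs = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    total = w.sum()
    cy = float((w * ys).sum() / total)
    cx = float((w * xs).sum() / total)
    out = np.ones((side, side), dtype=float)
    oy = int(round(cy - side / 2))
    ox = int(round(cx - side / 2))
    r0, r1 = max(0, -oy), min(side, img.shape[0] - oy)
    c0, c1 = max(0, -ox), min(side, img.shape[1] - ox)
    if r1 > r0 and c1 > c0:
        out[r0:r1, c0:c1] = img[r0 + oy : r1 + oy, c0 + ox : c1 + ox]
    return out


def sum_diagonals(image: np.ndarray) -> list[np.ndarray]:
    """Pixel collections with i+j = k, for k = 0..2M−2, i ascending."""
    a = np.asarray(image)
    m = a.shape[0]
    out = []
    for k in range(2 * m - 1):
        i0, i1 = max(0, k - m + 1), min(m, k + 1)
        idx = np.arange(i0, i1)
        out.append(a[idx, k - idx])
    return out


def difference_diagonals(image: np.ndarray) -> list[np.ndarray]:
    """Pixel collections with j−i+M = k, for k = 1..2M−1, i ascending."""
    a = np.asarray(image)
    m = a.shape[0]
    out = []
    for k in range(1, 2 * m):
        d = k - m  # j - i
        i0, i1 = max(0, -d), min(m, m - d)
        idx = np.arange(i0, i1)
        out.append(a[idx, idx + d])
    return out


def _align_and_crop(diags: list[np.ndarray], m: int, min_length_frac: float):
    """Keep diagonals of length >= frac*M; centre-align and edge-pad to M."""
    keep = [i for i, d in enumerate(diags) if len(d) >= min_length_frac * m]
    rows = np.empty((len(keep), m), dtype=float)
    for r, i in enumerate(keep):
        d = diags[i]
        pad = m - len(d)
        lp = pad // 2
        rows[r, :lp] = d[0]
        rows[r, lp : lp + len(d)] = d
        rows[r, lp + len(d) :] = d[-1]
    window = (keep[0], keep[-1]) if keep else (0, -1)
    return rows, window


def build_directional_matrices(
    image: np.ndarray, min_length_frac: float = 0.5
) -> dict[str, DirectionalMatrix]:
    """Four directional scanline stacks from one square centered image.

    horizontal = image rows verbatim; vertical = rows of the 90°-rotated
    image; diagonal/antidiagonal = constant-(j−i) / constant-(i+j) pixel
    collections, centre-aligned and cropped to diagonals at least
    ``min_length_frac``·M long.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("expected a square 2-D image")
    m = img.shape[0]
    d_rows, d_win = _align_and_crop(difference_diagonals(img), m, min_length_frac)
    a_rows, a_win = _align_and_crop(sum_diagonals(img), m, min_length_frac)
    return {
        "horizontal": DirectionalMatrix("horizontal", img.copy(), (0, m - 1)),
        "diagonal": DirectionalMatrix("diagonal", d_rows, d_win),
        "vertical": DirectionalMatrix("vertical", np.rot90(img).copy(), (0, m - 1)),
        "antidiagonal": DirectionalMatrix("antidiagonal", a_rows, a_win),
    }


def normalize_rows(matrix: DirectionalMatrix, eps: float = 1e-12) -> NormalizedMatrix:
    """Per-row z-score with the population standard deviation.

    Rows with spread below ``eps`` are emitted as all-zeros and flagged
    invalid in ``valid_row_mask``.
    """
    rows = matrix.rows
    if rows.size == 0:
        raise ValueError("empty directional matrix")
    mu = rows.mean(axis=1, keepdims=True)
    sd = rows.std(axis=1, keepdims=True)
    valid = sd[:, 0] > eps
    safe = np.where(sd > eps, sd, 1.0)
    values = np.where(valid[:, None], (rows - mu) / safe, 0.0)
    return NormalizedMatrix(matrix.direction, values, valid)
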