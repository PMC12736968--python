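"""MADE core: 3-D geometric direction estimation from directional MAQ sets.

The four directional MAQ sets are summarised into per-direction means and
dispersions; dispersions are boosted by a configurable factor and converted
into reliability scores by swapping smallest with largest (and the middle
pair), so the most consistent direction scores highest.  Each direction and
its complement map to one of eight 3-D points (x, y = displacement along the
direction, z = reliability) forming an octagon around the MAQ-space origin
(the image centre, mapped to (0, 0)).  The circularly adjacent point triplet
with the largest summed distance from the origin votes for the artifact
direction: θ is the four-quadrant angle of the triplet's centre of mass, and
the weighted magnitude q is the distance from the origin to where the θ-ray
crosses the octagon boundary edge spanning θ's 45° segment.

Diagonal scanlines measure lags in diagonal index units (√2 px per step);
placing the diagonal vertices at (±q̄, ±q̄) — 2-D radius q̄·√2 — restores
pixel units, which is why the diagonal vertices are mapped that way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .directions import DIRECTIONS, build_directional_matrices, crop_center, normalize_rows
from .mape import scan_matrix
from .maq import MAQSet, maq_matrix
from .rope import reference_origins

__all__ = [
    "DirectionalStats",
    "PointOctagon",
    "TripletSelection",
    "DirectionEstimate",
    "NoArtifactError",
    "directional_stats",
    "reliability_swap",
    "map_points",
    "select_triplet",
    "center_of_mass",
    "direction_angle",
    "neighbor_matrix",
    "segment_index",
    "ray_segment_intersection",
    "weighted_distance",
    "estimate",
    "SEGMENT_WIDTH_DEG",
]

#: the 360° plane divided across the octagon's 8 edges
SEGMENT_WIDTH_DEG = 360.0 / 8


class NoArtifactError(ValueError):
    """Raised when no direction carries any artifact signal."""


@dataclass
class DirectionalStats:
    """Per-direction MAQ summary in the order (h, d, v, a).

    ``means`` are detection-fraction-weighted magnitudes: the sum of
    non-suppressed |q_i| divided by the number of evaluated scanlines K_d,
    so a direction detecting on few of its scanlines is down-weighted.
    ``stds`` are population standard deviations of the detected |q_i| —
    the dispersion the reliability swap ranks.
    """

    means: np.ndarray
    stds: np.ndarray
    boosted: np.ndarray
    reliability: np.ndarray
    beta: float
    valid_counts: np.ndarray
    line_counts: np.ndarray

    def per_direction(self) -> dict[str, dict]:
        out = {}
        for i, d in enumerate(DIRECTIONS):
            out[d] = {
                "mean": float(self.means[i]),
                "std": float(self.stds[i]),
                "reliability": float(self.reliability[i]),
                "n_valid": int(self.valid_counts[i]),
                "n_lines": int(self.line_counts[i]),
            }
        return out


@dataclass
class PointOctagon:
    points: np.ndarray          # 8 x 3, ordered p1..p8
    center: tuple[float, float] = (0.0, 0.0)


@dataclass
class TripletSelection:
    """1-based circularly adjacent indices and their summed origin distance."""

    indices: tuple[int, int, int]
    points: np.ndarray          # 3 x 3
    total_distance: float


@dataclass
class DirectionEstimate:
    theta: float
    theta_complement: float
    q: float
    center_of_mass: np.ndarray
    stats: DirectionalStats
    triplet: TripletSelection
    segment: int
    intersection: np.ndarray
    config: PipelineConfig = field(repr=False, default=None)  # type: ignore[assignment]


def directional_stats(maq_sets: dict[str, MAQSet], beta: float = 1.0) -> DirectionalStats:
    """Summarise the four directional MAQ sets.

    A direction with no valid entries gets mean 0 and a pre-swap dispersion
    of 10× the largest finite dispersion (so the swap assigns it the lowest
    reliability).  Raises :class:`NoArtifactError` when all four directions
    are empty.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    means = np.zeros(4)
    stds = np.zeros(4)
    valid_counts = np.zeros(4, dtype=int)
    line_counts = np.zeros(4, dtype=int)
    empty = np.zeros(4, dtype=bool)
    for i, d in enumerate(DIRECTIONS):
        qs = maq_sets[d]
        mags = np.abs(qs.values[qs.valid])
        valid_counts[i] = len(mags)
        line_counts[i] = qs.n_lines
        if len(mags) == 0 or qs.n_lines == 0:
            empty[i] = True
            continue
        means[i] = mags.sum() / qs.n_lines
        stds[i] = mags.std()
    if empty.all():
        raise NoArtifactError("no artifact signal in any direction")
    # Directions without any detection must rank strictly last in reliability.
    # The swap permutes the *values* onto other directions, so the sentinel is
    # kept just above the largest real dispersion rather than a large multiple,
    # which would otherwise dominate the octagon's z channel and hence q.
    finite = stds[~empty]
    sentinel = 1.0001 * finite.max() + 1e-9 if finite.max() > 0 else 1.0
    stds = np.where(empty, sentinel, stds)
    means = np.where(empty, 0.0, means)
    boosted = beta * stds
    reliability = reliability_swap(boosted)
    return DirectionalStats(
        means, stds, boosted, reliability, beta, valid_counts, line_counts
    )


def reliability_swap(sigmas_boosted: np.ndarray) -> np.ndarray:
    """Invert the dispersion order: min↔max, the two middles exchanged.

    The direction with the smallest boosted dispersion receives the largest
    value and vice versa; ties resolve by stable input order (h, d, v, a).
    Applying the swap twice restores the original assignment.
    """
    sp = np.asarray(sigmas_boosted, dtype=float)
    if sp.shape != (4,) or not np.all(np.isfinite(sp)):
        raise ValueError("expected four finite values")
    order = np.argsort(sp, kind="stable")
    ranked = np.sort(sp)
    out = np.empty(4)
    for rank, direction_idx in enumerate(order):
        out[direction_idx] = ranked[3 - rank]
    return out


def map_points(stats: DirectionalStats, center: tuple[float, float] = (0.0, 0.0)) -> PointOctagon:
    """The eight octagon points; p5..p8 are the central reflections of p1..p4."""
    x0, y0 = center
    qh, qd, qv, qa = stats.means
    zh, zd, zv, za = stats.reliability
    pts = np.array([
        [x0 + qh, y0, zh],
        [x0 + qd, y0 + qd, zd],
        [x0, y0 + qv, zv],
        [x0 - qa, y0 + qa, za],
        [x0 - qh, y0, zh],
        [x0 - qd, y0 - qd, zd],
        [x0, y0 - qv, zv],
        [x0 + qa, y0 - qa, za],
    ])
    return PointOctagon(pts, center)


def select_triplet(octagon: PointOctagon) -> TripletSelection:
    """Circularly adjacent triplet maximising the summed origin distance.

    All 8 starting indices are enumerated; ties go to the smallest start.
    """
    pts = octagon.points
    d = np.linalg.norm(pts, axis=1)
    totals = np.array([d[i] + d[(i + 1) % 8] + d[(i + 2) % 8] for i in range(8)])
    i = int(np.argmax(totals))
    idx = (i + 1, (i + 1) % 8 + 1, (i + 2) % 8 + 1)
    return TripletSelection(idx, pts[[i, (i + 1) % 8, (i + 2) % 8]], float(totals[i]))


def center_of_mass(triplet: TripletSelection) -> np.ndarray:
    """Arithmetic mean of the three triplet points."""
    return triplet.points.mean(axis=0)


def direction_angle(c: np.ndarray) -> tuple[float, float]:
    """Four-quadrant angle of the x–y projection, in [0, 360), plus complement."""
    cx, cy = float(c[0]), float(c[1])
    if cx == 0.0 and cy == 0.0:
        raise ValueError("degenerate center of mass")
    theta = math.degrees(math.atan2(cy, cx)) % 360.0
    return theta, (theta + 180.0) % 360.0


def neighbor_matrix(octagon: PointOctagon) -> np.ndarray:
    """8 directed edges (P_i, P_{i+1}) with circular wrap, as an 8×6 matrix."""
    pts = octagon.points
    return np.hstack([pts, np.roll(pts, -1, axis=0)])


def segment_index(theta: float) -> int:
    """1-based 45° segment index; θ = 360 wraps to 1."""
    if not (0.0 <= theta <= 360.0):
        raise ValueError("theta must lie in [0, 360]")
    iota = int(theta // SEGMENT_WIDTH_DEG) + 1
    return iota if iota <= 8 else 1


def ray_segment_intersection(
    theta: float, edge: np.ndarray, epsilon: float = 1e-10
) -> tuple[np.ndarray, float]:
    """Intersection of the θ-ray from the origin with one polygon edge.

    Solves the 2×2 parametric system for (t, s); a near-parallel system
    (|det| < epsilon) falls back to the edge midpoint (s = 0.5).  s is
    clamped to [0, 1] and the 3-D point (z included) is interpolated along
    the edge.  Returns (point, s_clamped).
    """
    edge = np.asarray(edge, dtype=float)
    start, end = edge[:3], edge[3:6]
    d = np.array([math.cos(math.radians(theta)), math.sin(math.radians(theta))])
    a = np.array([
        [d[0], -(end[0] - start[0])],
        [d[1], -(end[1] - start[1])],
    ])
    det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    if abs(det) < epsilon:
        s = 0.5
    else:
        b = start[:2]
        s = float((a[0, 0] * b[1] - a[1, 0] * b[0]) / det)
    s_clamped = min(1.0, max(0.0, s))
    point = start + s_clamped * (end - start)
    return point, s_clamped


def weighted_distance(intersection: np.ndarray) -> float:
    """3-D Euclidean distance of the intersection point from the origin."""
    return float(np.linalg.norm(np.asarray(intersection, dtype=float)))


def estimate(image: np.ndarray, config: PipelineConfig | None = None) -> DirectionEstimate:
    """Full chain: centre-crop → directional matrices → MAPE/ROPE/MAQ per
    direction → octagon → triplet → (θ, θ′, q).

    Deterministic for fixed input and config.  Raises
    :class:`~made.directions.NoObjectError` on blank frames and
    :class:`NoArtifactError` when no direction detects a displacement.
    """
    cfg = config or PipelineConfig()
    cropped = crop_center(image, side=cfg.crop_side)
    matrices = build_directional_matrices(cropped)
    maq_sets: dict[str, MAQSet] = {}
    for name in DIRECTIONS:
        norm = normalize_rows(matrices[name])
        origins = reference_origins(norm, alpha=cfg.alpha, tau_rope=cfg.tau_rope)
        peaks = scan_matrix(norm, cfg.min_prominence, row_mask=origins.retained)
        maq_sets[name] = maq_matrix(
            origins, peaks, tau_maq=cfg.tau_maq,
            lag_mapping=cfg.lag_mapping, direction=name,
        )
    stats = directional_stats(maq_sets, beta=cfg.beta)
    octagon = map_points(stats)
    triplet = select_triplet(octagon)
    com = center_of_mass(triplet)
    theta, theta_c = direction_angle(com)
    iota = segment_index(theta)
    edges = neighbor_matrix(octagon)
    point, _ = ray_segment_intersection(theta, edges[iota - 1], cfg.epsilon_parallel)
    q = weighted_distance(point)
    return DirectionEstimate(
        theta=theta, theta_complement=theta_c, q=q, center_of_mass=com,
        stats=stats, triplet=triplet, segment=iota, intersection=point,
        config=cfg,
    )
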