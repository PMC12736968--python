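"""Ground-truthed single-frame motion-blur simulator.

A compact dark object on a white background is moved along a trajectory that
combines a circular oscillation of amplitude ``A`` and angular frequency
``omega`` with a linear drift at velocity ``v`` along orientation ``phi``,
integrated over one exposure of duration ``T``:

    r(t) = (A cos(ωt) − v_pix·t·cosφ,  A sin(ωt) − v_pix·t·sinφ)

where ``v_pix = v * pixels_per_meter``.  Wherever the trajectory slows down
(its speed minima, once per oscillation cycle) the object dwells and leaves a
darker replica in the exposure-averaged frame; these periodic replicas, spaced
``v_pix·(2π/ω)`` pixels apart along φ, are the "movement artifact" that the
estimation pipeline detects.

Coordinate convention (shared with the estimator): x = column index increasing
rightward, y = row index increasing DOWNWARD, angles measured clockwise on
screen so that φ = 90° points down-rows.  Every frame records this tag in its
metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import integrate, ndimage, signal

logger = logging.getLogger(__name__)

CONVENTION = "x=col-right, y=row-down, angles clockwise-on-screen (phi=90 down)"

__all__ = [
    "CONVENTION",
    "MotionParameters",
    "PSFSpec",
    "SyntheticFrame",
    "trajectory",
    "arc_length",
    "render_point_trail",
    "render_object_trail",
    "make_fixture_grid",
    "dataset_size_bounds",
]


@dataclass(frozen=True)
class MotionParameters:
    """Trajectory and exposure parameters (the simulation ground truth).

    Parameters
    ----------
    A : float
        Oscillation amplitude in pixels (>= 0).
    omega : float
        Oscillation angular frequency in rad/s (>= 0).  The default gives
        3.5 cycles per exposure, so the dwell replicas are spaced
        2/7 of the drift length apart.
    v : float
        Drift velocity in m/s (>= 0).
    phi : float
        Drift orientation in degrees; normalised to [0, 360).
    T : float
        Exposure time in seconds (> 0).
    s : float
        Sampling time step in seconds (0 < s <= T); N = floor(T/s) samples.
    pixels_per_meter : float
        Pixel calibration.  The default (125 px/m with T = 1 s) maps
        v = 0.2 m/s to a 25 px trail in a 256 px frame.
    """

    A: float = 2.0
    omega: float = 7.0 * math.pi
    v: float = 0.2
    phi: float = 0.0
    T: float = 1.0
    s: float = 1e-3
    pixels_per_meter: float = 125.0

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("A must be >= 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.v < 0:
            raise ValueError("v must be >= 0")
        if self.T <= 0:
            raise ValueError("T must be > 0")
        if not (0 < self.s <= self.T):
            raise ValueError("s must satisfy 0 < s <= T")
        if self.pixels_per_meter <= 0:
            raise ValueError("pixels_per_meter must be > 0")
        object.__setattr__(self, "phi", float(self.phi) % 360.0)

    @property
    def v_pix(self) -> float:
        """Drift speed in pixels/s."""
        return self.v * self.pixels_per_meter

    @property
    def n_samples(self) -> int:
        return int(math.floor(self.T / self.s))

    @property
    def drift_length(self) -> float:
        """Total drift displacement over the exposure, in pixels."""
        return self.v_pix * self.T

    @property
    def dwell_spacing(self) -> float:
        """Spacing of consecutive dwell replicas along phi, in pixels.

        One trajectory speed minimum occurs per oscillation cycle, so
        replicas are spaced by the drift per cycle, v_pix * 2π/ω.
        Infinite when the oscillation is absent (omega = 0).
        """
        if self.omega == 0:
            return math.inf
        return self.v_pix * 2.0 * math.pi / self.omega


@dataclass(frozen=True)
class PSFSpec:
    """Point-spread function used when rasterising the trajectory.

    ``gaussian`` spreads each contribution with standard deviation ``sigma``
    (pixels); ``delta`` places a unit impulse at the nearest integer pixel.
    """

    kind: str = "gaussian"
    sigma: float = 0.45
    support_radius: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "delta"):
            raise ValueError(f"unknown PSF kind {self.kind!r}")
        if self.kind == "gaussian" and self.sigma <= 0:
            raise ValueError("sigma must be > 0 for a gaussian PSF")

    @property
    def radius(self) -> int:
        if self.support_radius is not None:
            return int(self.support_radius)
        if self.kind == "delta":
            return 0
        return max(1, int(math.ceil(4.0 * self.sigma)))

    def kernel(self) -> np.ndarray:
        """Discrete kernel on its support, normalised to unit mass."""
        if self.kind == "delta":
            return np.ones((1, 1))
        r = self.radius
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        k = np.exp(-(xx**2 + yy**2) / (2.0 * self.sigma**2))
        return k / k.sum()


@dataclass
class SyntheticFrame:
    """A rendered frame with its generating ground truth."""

    intensities: np.ndarray
    truth_phi: float
    truth_v: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("frame intensities must be finite")
        if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
            raise ValueError("frame intensities must lie in [0, 1]")
        self.intensities = np.clip(arr, 0.0, 1.0)


def trajectory(params: MotionParameters, t):
    """Object position (x, y) in pixels at time ``t`` (oscillation + drift).

    Accepts a scalar or array ``t`` in [0, T].  The drift term is subtracted,
    i.e. the object moves toward φ+180°; only the axis of motion matters for
    direction estimation.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > params.T):
        raise ValueError("t must lie within [0, T]")
    phi = math.radians(params.phi)
    x = params.A * np.cos(params.omega * t) - params.v_pix * t * math.cos(phi)
    y = params.A * np.sin(params.omega * t) - params.v_pix * t * math.sin(phi)
    return x, y


def _speed(params: MotionParameters, t: np.ndarray) -> np.ndarray:
    # |dr/dt| of the trajectory above; cross term follows from differentiation.
    phi = math.radians(params.phi)
    aw = params.A * params.omega
    vp = params.v_pix
    return np.sqrt(
        aw**2 + vp**2 + 2.0 * aw * vp * np.sin(params.omega * t - phi)
    )


def arc_length(params: MotionParameters) -> float:
    """Total trajectory path length over the exposure, in pixels.

    Closed-form limits: A·ω·T when v = 0 (pure oscillation) and v_pix·T when
    A = 0 or ω = 0 (pure drift).
    """
    aw = params.A * params.omega
    vp = params.v_pix
    if vp == 0:
        return aw * params.T
    if aw == 0:
        return vp * params.T
    val, _ = integrate.quad(
        lambda t: _speed(params, np.asarray(t)), 0.0, params.T, limit=400
    )
    return float(val)


def _sample_positions(params: MotionParameters, shape) -> tuple[np.ndarray, np.ndarray]:
    n = params.n_samples
    if n < 1:
        raise ValueError("no trajectory samples: need floor(T/s) >= 1")
    t = np.arange(n) * params.s
    x, y = trajectory(params, t)
    cy, cx = shape[0] // 2, shape[1] // 2
    return x + cx, y + cy


def _splat_counts(x, y, shape, warn_clip: bool = True) -> np.ndarray:
    """Nearest-integer accumulation of sample positions into a count image."""
    acc = np.zeros(shape, dtype=float)
    xi = np.round(x).astype(int)
    yi = np.round(y).astype(int)
    inside = (xi >= 0) & (xi < shape[1]) & (yi >= 0) & (yi < shape[0])
    if warn_clip and not inside.all():
        logger.warning(
            "trajectory leaves the frame: dropping %d of %d samples",
            int((~inside).sum()), len(xi),
        )
    np.add.at(acc, (yi[inside], xi[inside]), 1.0)
    return acc


def render_point_trail(
    params: MotionParameters, psf: PSFSpec, shape: tuple[int, int] = (256, 256)
) -> SyntheticFrame:
    """Accumulate the PSF at every trajectory sample (bright trail on black).

    Delta kernels are placed at nearest-integer positions; gaussian kernels
    are evaluated at the true sub-pixel offsets.  The accumulated image is
    rescaled to [0, 1] by its maximum.
    """
    n = params.n_samples
    if n < 1:
        raise ValueError("no trajectory samples: need floor(T/s) >= 1")
    x, y = _sample_positions(params, shape)
    acc = np.zeros(shape, dtype=float)
    if psf.kind == "delta":
        acc = _splat_counts(x, y, shape)
    else:
        r = psf.radius
        dropped = 0
        for xs, ys in zip(x, y):
            x0, y0 = int(math.floor(xs)), int(math.floor(ys))
            cols = np.arange(x0 - r, x0 + r + 2)
            rows = np.arange(y0 - r, y0 + r + 2)
            kx = np.exp(-((cols - xs) ** 2) / (2 * psf.sigma**2))
            ky = np.exp(-((rows - ys) ** 2) / (2 * psf.sigma**2))
            patch = np.outer(ky, kx)
            patch /= patch.sum()
            rs = rows[(rows >= 0) & (rows < shape[0])]
            cs = cols[(cols >= 0) & (cols < shape[1])]
            if len(rs) < len(rows) or len(cs) < len(cols):
                dropped += 1
            sub = patch[np.isin(rows, rs)][:, np.isin(cols, cs)]
            acc[np.ix_(rs, cs)] += sub
        if dropped:
            logger.warning("PSF support clipped at the frame border for %d samples", dropped)
    peak = acc.max()
    img = acc / peak if peak > 0 else acc
    return SyntheticFrame(
        img, params.phi, params.v,
        meta={"params": asdict(params), "psf": asdict(psf), "kind": "point_trail",
              "convention": CONVENTION, "pre_rescale_mass": float(acc.sum())},
    )


def _disk_kernel(radius: float) -> np.ndarray:
    r = int(math.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx**2 + yy**2 <= radius**2).astype(float)


def render_object_trail(
    params: MotionParameters,
    psf: PSFSpec,
    object_radius: float = 1.1,
    shape: tuple[int, int] = (256, 256),
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> SyntheticFrame:
    """Exposure-averaged occlusion of a dark disk swept along the trajectory.

    Each pixel's intensity is 1 minus the fraction of the exposure during
    which the disk covers it — the discrete form of accumulating the object
    indicator along the trajectory measure.  A stationary object therefore
    renders as a solid black disk on white, while a moving object leaves a
    gray smear whose dwell points (trajectory speed minima) appear as darker
    replicas.  Gaussian PSFs additionally smooth the result; an optional
    additive zero-mean gaussian pixel noise term is off by default.
    """
    if object_radius <= 0:
        raise ValueError("object_radius must be > 0")
    if 2 * object_radius >= min(shape):
        raise ValueError("object larger than the frame")
    x, y = _sample_positions(params, shape)
    counts = _splat_counts(x, y, shape)
    coverage = signal.fftconvolve(counts, _disk_kernel(object_radius), mode="same")
    coverage = np.clip(coverage / params.n_samples, 0.0, 1.0)
    coverage[coverage < 1e-9] = 0.0  # FFT round-off; background stays exactly white
    img = 1.0 - coverage
    if psf.kind == "gaussian":
        img = ndimage.gaussian_filter(img, psf.sigma)
        img[img > 1.0 - 1e-9] = 1.0  # filter round-off on the white background
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return SyntheticFrame(
        img, params.phi, params.v,
        meta={"params": asdict(params), "psf": asdict(psf),
              "object_radius": object_radius, "kind": "object_trail",
              "noise_sigma": noise_sigma, "seed": seed, "convention": CONVENTION},
    )


def make_fixture_grid(
    phis: Sequence[float],
    vs: Sequence[float],
    common: MotionParameters | None = None,
    psf: PSFSpec | None = None,
    shape: tuple[int, int] = (256, 256),
    object_radius: float = 1.1,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> list[SyntheticFrame]:
    """One object-trail frame per (phi, v) pair; deterministic without noise."""
    if len(phis) == 0 or len(vs) == 0:
        raise ValueError("phis and vs must be nonempty")
    common = common or MotionParameters()
    psf = psf or PSFSpec()
    frames = []
    for i, phi in enumerate(phis):
        for j, v in enumerate(vs):
            p = MotionParameters(
                A=common.A, omega=common.omega, v=float(v), phi=float(phi),
                T=common.T, s=common.s, pixels_per_meter=common.pixels_per_meter,
            )
            frame_seed = None if seed is None else seed + 1000 * i + j
            frames.append(
                render_object_trail(
                    p, psf, object_radius=object_radius, shape=shape,
                    noise_sigma=noise_sigma, seed=frame_seed,
                )
            )
    return frames


def dataset_size_bounds(
    n_phi: int = 12, n_v: int = 11, max_repetitions: int = 10
) -> tuple[int, int]:
    """(min, max) dataset cardinality for a grid with 1..max_repetitions
    acquisitions per (phi, v) cell."""
    cells = n_phi * n_v
    return cells, cells * max_repetitions
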