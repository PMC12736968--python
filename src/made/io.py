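"""Image and tabular I/O for frames, estimates and sweep results."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .geometry import DirectionEstimate
from .simulate import SyntheticFrame

__all__ = [
    "ImageReadError",
    "read_image",
    "write_frame",
    "estimate_to_dict",
    "write_results",
    "read_results",
]


class ImageReadError(IOError):
    """Raised for unreadable or unsupported image files."""


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF as a float matrix in [0, 1].

    RGB(A) inputs are converted to a single channel by averaging the colour
    channels; integer images are scaled by their bit-depth maximum.
    """
    path = Path(path)
    if path.suffix.lower() not in (".png", ".tif", ".tiff"):
        raise ImageReadError(f"unsupported format {path.suffix!r} (PNG/TIFF only)")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various OSError/ValueError types
        raise ImageReadError(f"cannot read image {path}: {exc}") from exc
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    return np.clip(arr, 0.0, 1.0)


def write_frame(frame: SyntheticFrame, path: str | Path, bit_depth: int = 8) -> Path:
    """Write a frame as 8- or 16-bit grayscale PNG/TIFF plus a ground-truth
    JSON sidecar (same stem, ``.json``)."""
    path = Path(path)
    if bit_depth == 8:
        img = np.round(frame.intensities * 255).astype(np.uint8)
    elif bit_depth == 16:
        img = np.round(frame.intensities * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(path, img)
    sidecar = {"phi_deg": frame.truth_phi, "v_mps": frame.truth_v, **frame.meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def estimate_to_dict(est: DirectionEstimate) -> dict:
    """Stable JSON-ready representation of a direction estimate."""
    return {
        "theta_deg": est.theta,
        "theta_complement_deg": est.theta_complement,
        "q_px": est.q,
        "per_direction": est.stats.per_direction(),
        "triplet_indices": list(est.triplet.indices),
        "segment_index": est.segment,
        "center_of_mass": [float(c) for c in est.center_of_mass],
        "convention": est.config.convention if est.config else None,
    }


def write_results(obj, path: str | Path, fmt: str | None = None) -> Path:
    """Write a DirectionEstimate (json) or sweep DataFrame (csv/json).

    Field order is stable and floats are written at 6 decimals, so output is
    byte-deterministic for fixed input and round-trips through
    :func:`read_results`.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt not in ("json", "csv"):
        raise ValueError("format must be 'json' or 'csv'")
    if isinstance(obj, DirectionEstimate):
        if fmt != "json":
            raise ValueError("direction estimates are written as JSON")
        payload = _round_floats(estimate_to_dict(obj))
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif isinstance(obj, pd.DataFrame):
        if fmt == "csv":
            path.write_text(obj.to_csv(index=False, float_format="%.6f"))
        else:
            path.write_text(obj.round(6).to_json(orient="records") + "\n")
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    return path


def read_results(path: str | Path):
    """Inverse of :func:`write_results` (dict for JSON, DataFrame for CSV)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())
    return pd.read_csv(path)
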