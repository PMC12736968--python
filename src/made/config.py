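"""Pipeline configuration: validated parameter container and flat-file loader."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

from .simulate import CONVENTION

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the estimation pipeline.

    alpha : EMA smoothing factor for ROPE, in (0, 1].
    tau_rope : relative slope-retention threshold, in (0, 1].
    tau_maq : plausibility threshold on |q| in pixels (> 0); defaults to
        half the crop side — artifacts longer than half the frame are outside
        the model's regime.
    beta : boost factor applied to directional dispersions before the
        reliability swap (> 0).
    min_prominence : peak prominence threshold as a fraction of r[0], (0, 1).
    crop_side : side of the square analysis window, pixels.
    epsilon_parallel : determinant cutoff for the ray/edge parallel fallback.
    lag_mapping : strategy converting MAPE lags to candidate positions.
    convention : coordinate/angle convention tag recorded in outputs.
    """

    alpha: float = 0.3
    tau_rope: float = 0.3
    tau_maq: float = 112.0
    beta: float = 1.0
    min_prominence: float = 0.1
    crop_side: int = 224
    epsilon_parallel: float = 1e-10
    lag_mapping: str = "origin_offset"
    convention: str = field(default=CONVENTION)

    def __post_init__(self) -> None:
        checks = {
            "alpha": (0 < self.alpha <= 1, "(0, 1]"),
            "tau_rope": (0 < self.tau_rope <= 1, "(0, 1]"),
            "tau_maq": (self.tau_maq > 0, "(0, inf)"),
            "beta": (self.beta > 0, "(0, inf)"),
            "min_prominence": (0 < self.min_prominence < 1, "(0, 1)"),
            "crop_side": (self.crop_side >= 8, "[8, inf)"),
            "epsilon_parallel": (self.epsilon_parallel > 0, "(0, inf)"),
            "lag_mapping": (self.lag_mapping == "origin_offset", "{origin_offset}"),
        }
        for key, (ok, legal) in checks.items():
            if not ok:
                raise ValueError(
                    f"config value {key}={getattr(self, key)!r} outside legal range {legal}"
                )

    def as_dict(self) -> dict:
        return asdict(self)


_FIELD_TYPES = {f.name: f.type for f in fields(PipelineConfig)}
_FLOAT_KEYS = {"alpha", "tau_rope", "tau_maq", "beta", "min_prominence", "epsilon_parallel"}
_INT_KEYS = {"crop_side"}


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from a flat ``key = value`` text file plus overrides.

    Overrides win over file values.  Unknown keys raise a named error;
    out-of-range values raise naming the key and its legal range.
    """
    values: dict = {}
    if path is not None:
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (part.strip() for part in line.split("=", 1))
            values[key] = val
    values.update({k: v for k, v in overrides.items() if v is not None})
    kwargs: dict = {}
    for key, val in values.items():
        if key not in _FIELD_TYPES:
            raise KeyError(f"unknown config key {key!r}")
        if key in _FLOAT_KEYS:
            kwargs[key] = float(val)
        elif key in _INT_KEYS:
            kwargs[key] = int(val)
        else:
            kwargs[key] = str(val)
    return PipelineConfig(**kwargs)
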