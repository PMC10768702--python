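"""Pipeline configuration: one serializable object fixing every free choice.

Every analysis output embeds ``config_hash`` so results can be traced to the
exact parameter set that produced them.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

from .colorimetry import WhitePoint, get_white_point, REC709_LUMA_WEIGHTS

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters controlling the image-statistics and perception pipeline.

    Attributes
    ----------
    white_point:
        Display white point name ('D65', 'D40', ...) or explicit (x, y) pair;
        RGB = (1, 1, 1) maps to this chromaticity.
    gamma:
        Exponent of the power-law transfer function ``I = v**gamma``.
    cct_t_min, cct_t_max:
        Planckian locus search range in kelvin (1 K table resolution).
    cct_pixel_cap, cct_stride:
        Per-pixel CCT maps are computed on a strided grid; the stride is
        chosen to keep at most ``cct_pixel_cap`` pixels unless an explicit
        ``cct_stride`` is set.
    duv_cap:
        Chromaticities farther than this from the locus get no CCT.
    min_luminance:
        Pixels darker than this carry no usable chromaticity; excluded
        from CCT statistics.
    airlight_patch, airlight_top_frac:
        Dark-channel patch side length (odd) and the candidate quantile
        fraction for airlight estimation.
    scale:
        Rating scale name: 'seven_point', 'four_point_merged', or 'binary'.
    resize_target:
        Longer image side after standardization, in pixels.
    seed:
        Seed for every stochastic step downstream.
    """

    white_point: str | tuple = "D65"
    gamma: float = 2.2
    cct_t_min: float = 1000.0
    cct_t_max: float = 25000.0
    cct_pixel_cap: int = 100_000
    cct_stride: int | None = None
    duv_cap: float = 0.05
    min_luminance: float = 1e-4
    airlight_patch: int = 15
    airlight_top_frac: float = 0.001
    scale: str = "four_point_merged"
    resize_target: int = 1000
    seed: int = 0
    luma_weights: tuple = field(default=REC709_LUMA_WEIGHTS)

    def resolved_white_point(self) -> WhitePoint:
        return get_white_point(self.white_point)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["white_point"] = (
            list(self.white_point)
            if isinstance(self.white_point, (tuple, list))
            else self.white_point
        )
        d["luma_weights"] = list(self.luma_weights)
        return d

    @property
    def config_hash(self) -> str:
        """Stable 12-hex-digit digest of the full parameter set."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "white_point" in raw and isinstance(raw["white_point"], list):
            raw["white_point"] = tuple(raw["white_point"])
        if "luma_weights" in raw:
            raw["luma_weights"] = tuple(raw["luma_weights"])
        return cls(**raw)

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
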