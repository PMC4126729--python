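"""Analysis configuration: defaults, YAML loading, validation, hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["AnalysisConfig", "load_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of one end-to-end fingerprint analysis.

    ``roi`` is a pixel rectangle ``(x0, y0, x1, y1)`` (half-open, row 0 at
    the image top); the default covers the upper-left region where the
    asthma-series crescent void and hot spot are planted.
    """

    resolution: int = 512
    diameter_mm: float = 20.0
    roi: tuple[int, int, int, int] = (77, 128, 179, 230)
    scales: tuple[int, ...] | None = None  # None = module defaults (dyadic)
    q_min: float = -5.0
    q_max: float = 5.0
    q_step: float = 0.25
    n_bins: int = 50
    n_sectors: int = 36
    n_particles: int = 100_000
    replicates: int = 5
    seed: int = 0
    tiles: tuple[int, int] = (6, 6)
    spike_prominence: float = 2.0
    smooth_sigma_px: float = 4.0
    output_dir: str = "afpq_out"

    def validate(self) -> "AnalysisConfig":
        if self.resolution < 8:
            raise ValidationError("resolution must be >= 8")
        if self.diameter_mm <= 0:
            raise ValidationError("diameter_mm must be positive")
        x0, y0, x1, y1 = self.roi
        if not (0 <= x0 < x1 <= self.resolution and 0 <= y0 < y1 <= self.resolution):
            raise ValidationError(f"roi {self.roi} outside the {self.resolution}px image")
        if self.q_min >= 0 or self.q_max <= 0 or self.q_step <= 0:
            raise ValidationError("q grid must span negative and positive exponents")
        if self.n_bins < 4 or self.n_sectors < 4:
            raise ValidationError("bin counts must be >= 4")
        if self.replicates < 2:
            raise ValidationError("need >= 2 replicates for mean +/- SD")
        if self.n_particles < 1:
            raise ValidationError("n_particles must be >= 1")
        if self.smooth_sigma_px < 0:
            raise ValidationError("smooth_sigma_px must be >= 0")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scales"] = list(self.scales) if self.scales is not None else None
        d["roi"] = list(self.roi)
        d["tiles"] = list(self.tiles)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path | None, **overrides) -> AnalysisConfig:
    """Build a config from an optional YAML file plus keyword overrides.

    CLI flags override file values; unknown keys in the file are rejected.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must be a mapping")
        data.update(raw)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("roi", "tiles", "scales"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return AnalysisConfig(**data).validate()
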