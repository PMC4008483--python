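"""Run configuration: every pipeline tunable with its default.

Defaults mirror the algorithm's published operating point: threshold
search j from 5 down to 3, 60% z-extent acceptance, 8 candidate objects,
A-P derivative axis, 10-sample template padding, minimum segment length 2,
5-point tangent window.  Unknown keys are rejected so a typo in a config
file cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    j_high: int = 5
    j_low: int = 3
    length_fraction: float = 0.6
    n_candidates: int = 8
    connectivity_3d: int = 26
    connectivity_2d: int = 8
    axis: str = "AP"  # transverse axis of the derivative profile
    dz: float | None = None  # profile sampling (mm); None = slice spacing
    pad: int = 10  # template padding (samples)
    lmin: int = 2  # minimum changepoint segment length (samples)
    window: int = 5  # tangent-fit half-window (centerline points)
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    seed: int = 0

    def __post_init__(self) -> None:
        if self.j_high < self.j_low or self.j_low < 1:
            raise ValueError("need j_high >= j_low >= 1")
        if not 0 < self.length_fraction <= 1:
            raise ValueError("length_fraction must be in (0, 1]")
        if self.connectivity_3d != 26 or self.connectivity_2d != 8:
            raise ValueError("only 26-connectivity (3-D) and 8-connectivity (2-D) are supported")
        if self.axis not in ("AP", "LR"):
            raise ValueError("axis must be 'AP' or 'LR'")
        if self.lmin < 1 or self.pad < 0 or self.window < 1:
            raise ValueError("lmin >= 1, pad >= 0, window >= 1 required")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a key: value mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the effective configuration, for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
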