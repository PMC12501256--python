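"""Run configuration: one validated record driving the end-to-end workflows.

Defaults reflect the bench system: twin primes (11, 13), 91-pattern
compressed scan, 250 um encoding pixels demagnified 4:1 from the object
plane, emissivity 0.98.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import sympy
import yaml

from .masks import (
    DEFAULT_MAGNIFICATION,
    DEFAULT_PIXEL_PITCH_MM,
    DEFAULT_STRIPE_SEPARATION_MM,
    CodingScheme,
    FlipConfig,
)
from .radiometry import DEFAULT_EMISSIVITY

__all__ = ["RunConfig", "CONFIG_SCHEMA_VERSION"]

CONFIG_SCHEMA_VERSION = 1

_REQUIRED = ("p", "q", "m")


@dataclass
class RunConfig:
    """Validated configuration for mask design and simulation runs."""

    p: int = 11
    q: int = 13
    m: int = 91
    noise_sigma: float = 0.0
    gain: float = 1.0
    seed: int = 0
    emissivity: float = DEFAULT_EMISSIVITY
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM
    magnification: float = DEFAULT_MAGNIFICATION
    stripe_separation_mm: float = DEFAULT_STRIPE_SEPARATION_MM
    phantom: dict[str, Any] = field(default_factory=lambda: {"kind": "uniform", "temperature_C": 37.0})
    output_dir: str = "thermopix_out"
    schema_version: int = CONFIG_SCHEMA_VERSION

    def validate(self) -> None:
        errors = []
        if not sympy.isprime(self.p):
            errors.append(f"p={self.p} is not prime")
        if not sympy.isprime(self.q):
            errors.append(f"q={self.q} is not prime")
        if self.q != self.p + 2:
            errors.append(f"q={self.q} != p+2={self.p + 2}")
        if not 1 <= self.m <= self.p * self.q:
            errors.append(f"m={self.m} outside [1, {self.p * self.q}]")
        if self.noise_sigma < 0:
            errors.append("noise_sigma must be >= 0")
        if self.gain <= 0:
            errors.append("gain must be > 0")
        if not 0 < self.emissivity <= 1:
            errors.append("emissivity must be in (0, 1]")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    def scheme(self) -> CodingScheme:
        self.validate()
        return CodingScheme(
            p=self.p,
            q=self.q,
            m=self.m,
            flip_config=FlipConfig(),
            pixel_pitch_mm=self.pixel_pitch_mm,
            magnification=self.magnification,
            stripe_separation_mm=self.stripe_separation_mm,
        )

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        missing = [k for k in _REQUIRED if k not in d]
        if missing:
            raise ValueError(f"missing required config keys: {missing}")
        unknown = set(d) - set(cls().to_dict())
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=1))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
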