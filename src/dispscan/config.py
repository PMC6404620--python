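"""Run configuration: thresholds, Tobit variant, residualization mode."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for an invalid run configuration."""


@dataclass
class RunConfig:
    """All tunable thresholds of a scan, serialized into every output.

    alpha_fdr     BH false-discovery rate across markers per trait.
    floor         nominal hard floor: rejection also needs P <= floor.
    alpha_label   per-contrast threshold for architecture labels.
    mlh_probe_p   threshold for including MLH as a covariate.
    tobit_variant "truncated" (density renormalized above 0, matches the
                  displayed likelihood) or "censored".
    residualization "per-marker" (dispersion recomputed from the model
                  containing each locus) or "global" (one PD vector per
                  trait from the covariate-only model).
    min_class_n   minimum individuals per present genotype class.
    window_mb     consensus-locus grouping window across cohorts.
    """

    alpha_fdr: float = 0.05
    floor: float = 0.01
    alpha_label: float = 0.05
    mlh_probe_p: float = 0.1
    tobit_variant: str = "truncated"
    residualization: str = "per-marker"
    min_class_n: int = 5
    seed: int = 0
    window_mb: float = 10.0
    require_same_allele: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha_fdr", "floor", "alpha_label", "mlh_probe_p"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name}={v} outside (0, 1]")
        if self.tobit_variant not in ("truncated", "censored"):
            raise ConfigError(f"unknown tobit_variant {self.tobit_variant!r}")
        if self.residualization not in ("per-marker", "global"):
            raise ConfigError(f"unknown residualization {self.residualization!r}")
        if self.min_class_n < 1:
            raise ConfigError("min_class_n must be >= 1")
        if self.window_mb <= 0:
            raise ConfigError("window_mb must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        lines = [f"config_hash: {self.hash}"]
        lines += [f"{k}: {v}" for k, v in sorted(self.to_dict().items())]
        return lines
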