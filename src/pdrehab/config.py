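"""Run configuration: a flat, validated, YAML-serializable description of one experiment.

Every simulation is fully specified by a RunConfig; the CLI reads one from
a YAML file, applies dotted-path overrides (``condition.sigma=30``), and
writes the fully resolved copy next to the outputs so any run can be
reproduced exactly from its own directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .conditions import REGIMES, ConfigurationError
from .population import STANDARD_TARGETS


@dataclass
class PopulationBlock:
    n: int = 500
    layout: str = "grid"  # "grid" | "random"
    depth: float = 1.0


@dataclass
class LesionBlock:
    center: float = 90.0
    fraction: float = 0.5


@dataclass
class ConditionBlock:
    regime: str = "bimanual_quenched"
    sigma: float = 60.0
    depth_sigma: float = 0.5


@dataclass
class LearningBlock:
    eta_sup: float = 0.1
    eta_unsup: float = 0.1
    lam: float = 0.01
    drift_sigma: float = 0.0
    gradient_mode: str = "analytic"
    update_targets: str = "encoding_only"


@dataclass
class ProtocolBlock:
    targets: list = field(default_factory=lambda: list(STANDARD_TARGETS))
    target_probs: list | None = None
    n_trials: int = 3000
    snapshots: list = field(default_factory=lambda: [1000, 2000, 3000])


@dataclass
class NoiseBlock:
    k: float = 0.1


@dataclass
class RunConfig:
    population: PopulationBlock = field(default_factory=PopulationBlock)
    lesion: LesionBlock = field(default_factory=LesionBlock)
    condition: ConditionBlock = field(default_factory=ConditionBlock)
    learning: LearningBlock = field(default_factory=LearningBlock)
    protocol: ProtocolBlock = field(default_factory=ProtocolBlock)
    noise: NoiseBlock = field(default_factory=NoiseBlock)
    seed: int = 0
    scenario: str = "bimanual_quenched"
    eval_reps: int = 200
    outdir: str = "runs/out"

    def validate(self) -> None:
        """Range-check every field before any simulation runs."""
        err = []
        if self.population.n < 1:
            err.append("population.n must be >= 1")
        if self.population.layout not in ("grid", "random"):
            err.append("population.layout must be 'grid' or 'random'")
        if self.population.depth < 0:
            err.append("population.depth must be >= 0")
        if not (0.0 <= self.lesion.fraction < 1.0):
            err.append("lesion.fraction must be in [0, 1)")
        if self.condition.regime not in REGIMES:
            err.append(f"condition.regime must be one of {REGIMES}")
        if self.condition.sigma < 0:
            err.append("condition.sigma must be >= 0")
        if self.condition.depth_sigma < 0:
            err.append("condition.depth_sigma must be >= 0")
        for nm in ("eta_sup", "eta_unsup", "lam", "drift_sigma"):
            if getattr(self.learning, nm) < 0:
                err.append(f"learning.{nm} must be >= 0")
        if self.learning.gradient_mode not in ("analytic", "finite_difference"):
            err.append("learning.gradient_mode must be 'analytic' or 'finite_difference'")
        if self.learning.update_targets not in ("encoding_only", "encoding_and_decoding"):
            err.append("learning.update_targets invalid")
        if self.protocol.n_trials < 0:
            err.append("protocol.n_trials must be >= 0")
        if self.noise.k < 0:
            err.append("noise.k must be >= 0")
        if self.eval_reps < 1:
            err.append("eval_reps must be >= 1")
        if err:
            raise ConfigurationError("; ".join(err))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(d) - set(known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, f in known.items():
            if name not in d:
                continue
            v = d[name]
            if dataclasses.is_dataclass(f.type) or name in (
                "population", "lesion", "condition", "learning", "protocol", "noise"
            ):
                block_cls = {
                    "population": PopulationBlock,
                    "lesion": LesionBlock,
                    "condition": ConditionBlock,
                    "learning": LearningBlock,
                    "protocol": ProtocolBlock,
                    "noise": NoiseBlock,
                }[name]
                bad = set(v) - {bf.name for bf in dataclasses.fields(block_cls)}
                if bad:
                    raise ConfigurationError(
                        f"unknown config keys under {name!r}: {sorted(bad)}"
                    )
                kwargs[name] = block_cls(**v)
            else:
                kwargs[name] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        data = yaml.safe_load(p.read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the fully resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def apply_override(self, dotted: str) -> None:
        """Apply a single ``block.key=value`` override in place."""
        if "=" not in dotted:
            raise ConfigurationError(f"override must look like key=value: {dotted!r}")
        path, raw = dotted.split("=", 1)
        parts = path.strip().split(".")
        obj = self
        for part in parts[:-1]:
            if not hasattr(obj, part):
                raise ConfigurationError(f"unknown config path: {path!r}")
            obj = getattr(obj, part)
        leaf = parts[-1]
        if not hasattr(obj, leaf):
            raise ConfigurationError(f"unknown config path: {path!r}")
        current = getattr(obj, leaf)
        value = yaml.safe_load(raw)
        if current is not None and not isinstance(value, type(current)):
            # allow int -> float promotion, reject the rest
            if isinstance(current, float) and isinstance(value, int):
                value = float(value)
            elif isinstance(current, (list, tuple)) and isinstance(value, list):
                pass
            else:
                raise ConfigurationError(
                    f"override {path!r}: expected {type(current).__name__}, got {type(value).__name__}"
                )
        setattr(obj, leaf, value)
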