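"""One validated run-configuration document for the whole pipeline.

Every parameter that affects results — architecture, pretraining, adaptation
schedules and ablation switches, augmentation ranges, evaluation threshold,
the master seed — lives in a single :class:`RunConfig`, serializable to YAML
and flattenable into a log header so a finished run records its provenance
exactly once.  Validation is delegated to the component dataclasses (for
example a gamma schedule with a < b is rejected on construction).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .augment import AugmentConfig
from .engine import AdaptationConfig, PretrainConfig
from .model import ModelConfig


@dataclass(frozen=True)
class EvalConfig:
    threshold: float = 0.5
    restrict_to_fov: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must be in [0, 1]")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    model: ModelConfig = ModelConfig()
    pretrain: PretrainConfig = PretrainConfig()
    adapt: AdaptationConfig = AdaptationConfig()
    augment: AugmentConfig = AugmentConfig()
    evaluation: EvalConfig = EvalConfig()

    def with_ablation(self, name: str) -> "RunConfig":
        from .engine import ablation_config

        return replace(self, adapt=ablation_config(name, self.adapt))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"]["sigmas"] = list(self.model.sigmas)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, payload):
            if payload is None:
                return klass()
            names = {f.name for f in fields(klass)}
            unknown = set(payload) - names
            if unknown:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            kwargs = dict(payload)
            for key in ("sigmas", "gamma_schedule", "beta_schedule", "channel_mix"):
                if key in kwargs and isinstance(kwargs[key], list):
                    kwargs[key] = tuple(kwargs[key])
            for sub, subklass in (("model", ModelConfig), ("augment", AugmentConfig)):
                if sub in kwargs and isinstance(kwargs[sub], dict):
                    kwargs[sub] = build(subklass, kwargs[sub])
            return klass(**kwargs)

        return cls(
            seed=int(d.get("seed", 0)),
            model=build(ModelConfig, d.get("model")),
            pretrain=build(PretrainConfig, d.get("pretrain")),
            adapt=build(AdaptationConfig, d.get("adapt")),
            augment=build(AugmentConfig, d.get("augment")),
            evaluation=build(EvalConfig, d.get("evaluation")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def flat_params(self) -> dict[str, object]:
        """Flatten to dotted keys for a run-log header (each parameter once)."""
        out: dict[str, object] = {}

        def walk(prefix: str, obj: dict) -> None:
            for k, v in obj.items():
                key = f"{prefix}.{k}" if prefix else k
                if isinstance(v, dict):
                    walk(key, v)
                else:
                    out[key] = tuple(v) if isinstance(v, list) else v

        walk("", self.to_dict())
        return out
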