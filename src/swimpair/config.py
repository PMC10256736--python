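"""Structured run configuration with YAML round-trip.

Defaults reproduce the study conditions: reward bounds d_lower/d_soft/
d_upper = 5/6/70 with penalties -0.3/-1, episode cap 16,384 steps,
discount 0.9997, and the published optimizer settings (learning rate 1e-4,
rollout 16,384, batch 256, 10 epochs, clip 0.2, no target-KL stop).
"""

from __future__ import annotations

from dataclasses import MISSING, dataclass, field, asdict, fields, is_dataclass
from pathlib import Path

import yaml

from .environment import EpisodeSpec, RewardSpec
from .hydro import HydroParams
from .ppo import NetworkSpec, PPOSpec


@dataclass
class BenchmarkConfig:
    delays: tuple[int, ...] = (0, 1, 2, 3)
    min_d: float = 6.0
    cycles: int = 50
    measure_cycles: int = 20


@dataclass
class TrainConfig:
    total_steps: int = 5_400_000
    eval_every: int = 200_000
    eval_episodes: int = 5


@dataclass
class EvaluateConfig:
    mode: str = "stochastic"
    steps: int = 2000
    initial_d: float = 20.0
    start_extended: bool = True


@dataclass
class RunConfig:
    hydro: HydroParams = field(default_factory=HydroParams)
    reward: RewardSpec = field(default_factory=RewardSpec)
    episode: EpisodeSpec = field(default_factory=EpisodeSpec)
    ppo: PPOSpec = field(default_factory=PPOSpec)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)
    seed: int = 0
    output_dir: str = "runs"

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return plain(asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = {}
        errors = []
        known = {f.name: f for f in fields(cls)}
        for key in data:
            if key not in known:
                errors.append(f"unknown field {key!r}")
        for name, f in known.items():
            if name not in data:
                continue
            value = data[name]
            typ = f.default_factory if f.default_factory is not MISSING else None
            if typ is not None and is_dataclass(typ()):
                sub = typ()
                subfields = {sf.name for sf in fields(sub)}
                bad = set(value) - subfields
                if bad:
                    errors.append(f"unknown field(s) {sorted(bad)} in section {name!r}")
                    continue
                coerced = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                }
                try:
                    kwargs[name] = type(sub)(**coerced)
                except (TypeError, ValueError) as exc:
                    errors.append(f"invalid section {name!r}: {exc}")
            else:
                kwargs[name] = value
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def resolve_output_dir(path, force: bool = False) -> Path:
    """Create the output directory; refuse to reuse a non-empty one
    unless forced."""
    p = Path(path)
    if p.exists() and any(p.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {p} exists and is not empty (use --force to reuse)"
        )
    p.mkdir(parents=True, exist_ok=True)
    return p
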