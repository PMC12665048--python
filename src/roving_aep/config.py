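"""YAML run configuration: paradigm + simulation + analysis parameters.

A :class:`RunConfig` bundles every tunable of a run so that outputs can
embed a config echo and hash, and a re-run from the same file reproduces
identical results (all stochastic stages are seeded from ``seed``).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from roving_aep.paradigm import ParadigmConfig
from roving_aep.pipeline import AnalysisConfig
from roving_aep.simulate import SimConfig

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class RunConfig:
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "paradigm": asdict(self.paradigm),
            "sim": asdict(self.sim),
            "analysis": asdict(self.analysis),
            "seed": self.seed,
        }
        return _tuples_to_lists(d)


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def _build(cls, data: dict):
    """Instantiate a (frozen) dataclass from a dict, restoring tuple fields."""
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(
        paradigm=_build(ParadigmConfig, raw.get("paradigm", {})),
        sim=_build(SimConfig, raw.get("sim", {})),
        analysis=_build(AnalysisConfig, raw.get("analysis", {})),
        seed=int(raw.get("seed", 0)),
    )


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonical YAML serialization."""
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
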