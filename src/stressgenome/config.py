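"""Pipeline configuration: one block per stage, defaults equal to the
study's stated thresholds (CPM 3, FDR 0.05, 3x ratio, 5 focal genes, 70%
identity, 5 kb window, 15,822 bp, bit score 50). Unknown keys are
rejected."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .de import DEConfig
from .decontam import DecontamRuleSet
from .synthetic import SimSpec


@dataclass
class OrthoConfig:
    min_focal: int = 5
    ratio: float = 3.0
    zero_comparator_as_unique: bool = False


@dataclass
class EnrichConfig:
    alpha: float = 0.05
    propagate: bool = True
    direction: str = "over"


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "demo_output"
    simulate: SimSpec = field(default_factory=SimSpec)
    decontam: DecontamRuleSet = field(default_factory=DecontamRuleSet)
    ortho: OrthoConfig = field(default_factory=OrthoConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    de: DEConfig = field(default_factory=DEConfig)


def _build(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys in [{context}]: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            value = data[f.name]
            if f.name == "lib_size_range":
                value = tuple(value)
            coerced[f.name] = value
    return cls(**coerced)


def load_config(path: str | Path | None = None, seed: int | None = None) -> PipelineConfig:
    """Load a TOML config; missing blocks take the defaults above."""
    data: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    blocks = {
        "simulate": SimSpec,
        "decontam": DecontamRuleSet,
        "ortho": OrthoConfig,
        "enrich": EnrichConfig,
        "de": DEConfig,
    }
    top_known = {"seed", "outdir", *blocks}
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    cfg = PipelineConfig(
        seed=int(data.get("seed", 0)),
        outdir=str(data.get("outdir", "demo_output")),
        **{
            name: _build(cls, data.get(name, {}), name)
            for name, cls in blocks.items()
        },
    )
    if seed is not None:
        cfg.seed = seed
        cfg.simulate.seed = seed
    else:
        cfg.simulate.seed = cfg.seed
    return cfg
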