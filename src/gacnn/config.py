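"""Plain-text (YAML) round-tripping of the pipeline configuration.

One file holds every tunable of the four stages — graph building,
backbone, GCN/attention, fusion, training — so a run is reproducible
from a single artifact.
"""

from __future__ import annotations

import os
from dataclasses import asdict

import yaml

from .graphbuild import GraphBuildConfig
from .network import BackboneConfig, FusionConfig, GCNConfig
from .preprocess import PreprocessConfig
from .train import TrainConfig

__all__ = ["PipelineConfig", "save_config", "load_config"]


class PipelineConfig(dict):
    """Mapping of stage name -> config dataclass."""

    _SECTIONS = {"preprocess": PreprocessConfig, "graph": GraphBuildConfig,
                 "backbone": BackboneConfig, "gcn": GCNConfig,
                 "fusion": FusionConfig, "train": TrainConfig}

    @classmethod
    def defaults(cls) -> "PipelineConfig":
        return cls({name: typ() for name, typ in cls._SECTIONS.items()})


def save_config(cfg: PipelineConfig, path: str | os.PathLike):
    payload = {}
    for name, section in cfg.items():
        d = asdict(section)
        for key, val in d.items():
            if isinstance(val, (tuple, frozenset)):
                d[key] = list(sorted(val)) if isinstance(val, frozenset) \
                    else [list(v) if isinstance(v, tuple) else v for v in val]
        payload[name] = d
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_config(path: str | os.PathLike) -> PipelineConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    out = PipelineConfig()
    for name, typ in PipelineConfig._SECTIONS.items():
        d = dict(payload.get(name, {}))
        if name == "backbone" and "conv_plan" in d:
            d["conv_plan"] = tuple(tuple(p) for p in d["conv_plan"])
        if name == "preprocess":
            if "blend_weights" in d:
                d["blend_weights"] = tuple(d["blend_weights"])
            if "augmentations" in d:
                d["augmentations"] = frozenset(d["augmentations"])
        out[name] = typ(**d)
    return out
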