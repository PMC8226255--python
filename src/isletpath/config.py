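"""YAML (de)serialization of run configurations and slide specs."""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .cells import CellDetectionConfig
from .pipeline import RunConfig
from .quantify import InsulitisCriteria
from .spatial import DistanceBins
from .synthetic import SlideSpec
from .tissue import ThresholderConfig


def _build(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**data)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "thresholder" in kwargs:
        kwargs["thresholder"] = _build(ThresholderConfig, kwargs["thresholder"])
    if "cell_detection" in kwargs:
        kwargs["cell_detection"] = _build(CellDetectionConfig,
                                          kwargs["cell_detection"])
    if "insulitis" in kwargs:
        kwargs["insulitis"] = _build(InsulitisCriteria, kwargs["insulitis"])
    if "bins" in kwargs:
        kwargs["bins"] = DistanceBins(edges=tuple(kwargs["bins"]))
    cfg = _build(RunConfig, kwargs)
    cfg.validate()
    return cfg


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    data = asdict(cfg)
    data["bins"] = list(cfg.bins.edges)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_slide_spec(path: str | Path) -> SlideSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "channels" in raw:
        raw["channels"] = tuple(raw["channels"])
    if "immune_distance_weights" in raw:
        raw["immune_distance_weights"] = tuple(raw["immune_distance_weights"])
    spec = _build(SlideSpec, raw)
    spec.validate()
    return spec


def save_slide_spec(spec: SlideSpec, path: str | Path) -> None:
    data = asdict(spec)
    data["channels"] = list(spec.channels)
    data["immune_distance_weights"] = [float(w) for w in
                                       spec.immune_distance_weights]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
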