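"""Run configuration: one YAML file drives every pipeline stage.

Sections mirror the pipeline: ``phantom`` (synthetic data recipe),
``network`` (architecture), ``training`` (optimization), ``ensemble``
(size and fusion rule), ``postprocess`` (cleanup), ``generate`` /
``evaluate`` (stage options).  A single top-level ``seed`` feeds every
random draw; stage seeds are derived from it deterministically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .network import NetworkSpec
from .phantoms import PhantomSpec
from .trainer import TrainConfig

__all__ = ["RunConfig", "load_config", "default_config", "config_hash"]


@dataclass
class RunConfig:
    seed: int = 0
    n_cases: int = 60
    holdout: int = 20
    k: int = 3
    binarize_threshold: float = 0.5
    vote_on_probabilities: bool = False
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    network: NetworkSpec = field(default_factory=lambda: NetworkSpec(depth=2, base_filters=8))
    training: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=20))
    postprocess: dict = field(
        default_factory=lambda: dict(n_keep=2, connectivity=26, iterations=5,
                                     max_volume_change=0.05)
    )

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["phantom"] = {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in d["phantom"].items()}
        return d


def _build_section(cls, payload: dict, **overrides):
    return cls(**{**payload, **overrides})


def load_config(path) -> RunConfig:
    """Parse a YAML run config; omitted keys fall back to defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    seed = int(raw.get("seed", 0))

    phantom_raw = dict(raw.get("phantom", {}))
    for key in ("grid_shape", "kidney_axis_range_mm", "cyst_count_range",
                "cyst_radius_range_mm"):
        if key in phantom_raw:
            phantom_raw[key] = tuple(phantom_raw[key])
    phantom = _build_section(PhantomSpec, phantom_raw, seed=seed)

    network = _build_section(NetworkSpec, dict(raw.get("network", {})))
    training = _build_section(TrainConfig, dict(raw.get("training", {})), seed=seed)

    ens = dict(raw.get("ensemble", {}))
    post = {**dict(n_keep=2, connectivity=26, iterations=5, max_volume_change=0.05),
            **dict(raw.get("postprocess", {}))}
    gen = dict(raw.get("generate", {}))
    ev = dict(raw.get("evaluate", {}))

    return RunConfig(
        seed=seed,
        n_cases=int(gen.get("n_cases", 60)),
        holdout=int(ev.get("holdout", 20)),
        k=int(ens.get("k", 3)),
        binarize_threshold=float(ens.get("binarize_threshold", 0.5)),
        vote_on_probabilities=bool(ens.get("vote_on_probabilities", False)),
        phantom=phantom,
        network=network,
        training=training,
        postprocess=post,
    )


def default_config(seed: int = 0) -> RunConfig:
    cfg = RunConfig(seed=seed)
    cfg.phantom = PhantomSpec(seed=seed)
    cfg.training = TrainConfig(epochs=20, seed=seed)
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration, for run logs."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
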