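"""Run configuration: YAML schema, validation and resolution.

A run configuration describes where the connectome comes from (files or
the synthetic generator), the model parameters, the envelope/FC pipeline
settings, the fitness batch, and the optimizer budget.  Validation errors
carry the dotted path of the offending field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .connectome import Connectome, load_connectome, synthesize_connectome
from .fitness import ConstraintBounds
from .model import ModelParams

__all__ = ["RunConfig", "load_config", "resolve_connectome"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration."""

    raw: dict
    connectome_spec: dict
    model: dict
    pipeline: dict = field(default_factory=dict)
    fitness: dict = field(default_factory=dict)
    optimizer: dict = field(default_factory=dict)
    output_dir: str = "oanet_out"
    log_level: str = "INFO"

    def model_params(self, n_regions: int | None = None, **overrides) -> ModelParams:
        kw = dict(self.model)
        kw.update(overrides)
        L = kw.get("L", 0.0)
        if isinstance(L, (list, tuple)):
            kw["L"] = np.asarray(L, dtype=float)
        v = kw.get("v", np.inf)
        if v in ("inf", "infinite", None):
            kw["v"] = np.inf
        try:
            p = ModelParams(**kw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"model: {exc}") from exc
        if n_regions is not None:
            p.local_couplings(n_regions)  # raises on length mismatch
        return p

    def bounds(self) -> ConstraintBounds:
        b = self.fitness.get("bounds")
        if not b:
            return ConstraintBounds()
        try:
            return ConstraintBounds(
                mean_R=tuple(b.get("mean_R", (0.25, 0.8))),
                global_meta_min=b.get("global_meta_min", 0.05),
                mean_local=tuple(b.get("mean_local", (0.25, 0.8))),
                local_meta_min=b.get("local_meta_min", 0.05),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"fitness.bounds: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    conn = raw.get("connectome")
    if not isinstance(conn, dict):
        raise ConfigError("connectome: section is required")
    if "synth" in conn:
        synth = conn["synth"]
        if "n_regions" not in synth:
            raise ConfigError("connectome.synth.n_regions: required")
    else:
        for key in ("weights", "distances"):
            if key not in conn:
                raise ConfigError(f"connectome.{key}: required when not synthesizing")
            f = Path(conn[key])
            if not f.exists():
                raise ConfigError(f"connectome.{key}: file not found: {f}")
        sidecar = conn.get("sidecar")
        if sidecar and not Path(sidecar).exists():
            raise ConfigError(f"connectome.sidecar: file not found: {sidecar}")
    return RunConfig(
        raw=raw,
        connectome_spec=conn,
        model=dict(raw.get("model", {})),
        pipeline=dict(raw.get("pipeline", {})),
        fitness=dict(raw.get("fitness", {})),
        optimizer=dict(raw.get("optimizer", {})),
        output_dir=raw.get("output_dir", "oanet_out"),
        log_level=raw.get("log_level", "INFO"),
    )


def resolve_connectome(cfg: RunConfig) -> Connectome:
    spec = cfg.connectome_spec
    if "synth" in spec:
        synth = spec["synth"]
        return synthesize_connectome(int(synth["n_regions"]), int(synth.get("seed", 0)))
    return load_connectome(spec["weights"], spec["distances"], spec.get("sidecar"))


def dump_resolved(cfg: RunConfig, out_dir: Path, version: str) -> None:
    """Copy the resolved configuration and a version stamp into the output."""
    out_dir.mkdir(parents=True, exist_ok=True)
    resolved = dict(cfg.raw)
    resolved["_oanet_version"] = version
    (out_dir / "resolved_config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=False))
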