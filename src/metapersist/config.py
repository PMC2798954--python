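"""Run configuration, fixtures and serialization.

A :class:`RunConfig` bundles everything a simulation or sweep needs: the
local map, the patch topology, migration rate(s), seeds, run lengths and
noise. Configs load from YAML or JSON files (identical schema), are
validated exhaustively (unknown keys rejected, the stochastic
integer-fecundity rule enforced at construction time) and carry a stable
content hash that is recorded in every output.

The named fixtures cover the canonical experiment geometries (two-patch,
four-patch ring, 16-patch chain, 4x4 and 10x10 lattices with a central
defect). Their map parameters (logistic lam = 4, Ricker r = ln 50,
host-parasitoid lam = 2, a = 1, c = 1) and the modest N / replicate
counts are this package's own desk-scale choices, made once; see
docs/methods.md for the constraints behind each.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .local_maps import ConfigurationError, LocalMapSpec, integer_fecundity
from .stochastic import EnvNoiseSpec, RNGSpec
from .topology import Topology, build_topology

__all__ = ["RunConfig", "load_config", "dump_config", "config_hash", "make_fixture", "FIXTURES"]


class MapCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")

    family: Literal["logistic", "ricker", "nicholson_bailey"]
    N: int = 1000
    lam: Optional[float] = None
    r: Optional[float] = None
    a: Optional[float] = None
    c: Optional[int] = None

    def to_spec(self) -> LocalMapSpec:
        return LocalMapSpec(family=self.family, N=self.N, lam=self.lam, r=self.r, a=self.a, c=self.c)


class TopologyCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["two_patch", "chain_1d", "lattice_2d", "equal_coupling"]
    dims: Optional[Union[int, tuple[int, int]]] = None
    boundary: Literal["periodic", "open"] = "periodic"
    defects: list = []

    def to_topology(self) -> Topology:
        return build_topology(self.kind, dims=self.dims, boundary=self.boundary, defect_mask=self.defects)


class EnvCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")

    amplitude: float = 0.0
    scope: Literal["per_patch", "global"] = "per_patch"
    law: Literal["uniform_multiplicative", "lognormal_multiplicative"] = "uniform_multiplicative"

    def to_spec(self) -> EnvNoiseSpec:
        return EnvNoiseSpec(amplitude=self.amplitude, scope=self.scope, law=self.law)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    map: MapCfg
    topology: TopologyCfg
    D: Optional[float] = None
    D_grid: Optional[list[float]] = None
    init_rule: Literal["uniform_random", "fixed", "near_attractor"] = "uniform_random"
    init_counts: Optional[list] = None
    seed: int = 0
    stream: int = 0
    max_gen: int = 10_000
    reps: int = 200
    env: EnvCfg = EnvCfg()
    record_every: int = 0
    record_window: int = 0
    label: str = ""

    @field_validator("D")
    @classmethod
    def _check_d(cls, v):
        if v is not None and not 0.0 <= v <= 1.0:
            raise ValueError("D must lie in [0, 1]")
        return v

    @field_validator("D_grid")
    @classmethod
    def _check_grid(cls, v):
        if v is not None:
            if any(not 0.0 <= d <= 1.0 for d in v):
                raise ValueError("all D_grid values must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _check_stochastic_rule(self):
        try:
            integer_fecundity(self.map.to_spec())
        except ConfigurationError as err:
            raise ValueError(str(err)) from err
        return self

    # -- convenience accessors -------------------------------------------
    def spec(self) -> LocalMapSpec:
        return self.map.to_spec()

    def to_topology(self) -> Topology:
        return self.topology.to_topology()

    def env_spec(self) -> Optional[EnvNoiseSpec]:
        e = self.env.to_spec()
        return e if e.amplitude > 0 else None

    def rng(self, stream_offset: int = 0) -> np.random.Generator:
        return RNGSpec(self.seed, self.stream + stream_offset).generator()


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run config (exhaustive error report)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False))


def _grid(n: int = 21, hi: float = 1.0) -> list[float]:
    return [round(float(d), 6) for d in np.linspace(0.0, hi, n)]


# Desk-scale experiment configurations: two patches; four-patch ring;
# 16-patch chain; 4x4 torus; 10x10 torus with a central 2x2 defect block.
# Map parameters and sizes per the module docstring.
FIXTURES = (
    "logistic_2patch",
    "logistic_4ring",
    "ricker_2patch",
    "ricker_4ring",
    "nb_2patch",
    "nb_4ring",
    "chain16",
    "lattice4x4",
    "lattice10x10_defect",
)

_LOG_R50 = float(np.log(50.0))


def make_fixture(name: str) -> RunConfig:
    """Named run configurations for the canonical geometries."""
    logistic = dict(family="logistic", lam=4.0, N=300)
    ricker = dict(family="ricker", r=_LOG_R50, N=200)
    nb = dict(family="nicholson_bailey", lam=2.0, a=1.0, c=1, N=500)
    if name == "logistic_2patch":
        # two-patch dynamics at D and 1-D are exactly conjugate (swap the
        # patch labels every generation), so the grid covers [0, 0.5] only
        return RunConfig(map=MapCfg(**logistic), topology=TopologyCfg(kind="two_patch"),
                         D_grid=_grid(hi=0.5), reps=200, max_gen=30_000, label=name)
    if name == "logistic_4ring":
        return RunConfig(map=MapCfg(**logistic), topology=TopologyCfg(kind="chain_1d", dims=4),
                         D_grid=_grid(), reps=200, max_gen=30_000, label=name)
    if name == "ricker_2patch":
        return RunConfig(map=MapCfg(**ricker), topology=TopologyCfg(kind="two_patch"),
                         D_grid=_grid(hi=0.5), reps=200, max_gen=20_000, label=name)
    if name == "ricker_4ring":
        return RunConfig(map=MapCfg(**ricker), topology=TopologyCfg(kind="chain_1d", dims=4),
                         D_grid=_grid(), reps=200, max_gen=20_000, label=name)
    if name == "nb_2patch":
        return RunConfig(map=MapCfg(**nb), topology=TopologyCfg(kind="two_patch"),
                         D_grid=_grid(), reps=100, max_gen=5_000, label=name)
    if name == "nb_4ring":
        return RunConfig(map=MapCfg(**nb), topology=TopologyCfg(kind="chain_1d", dims=4),
                         D_grid=_grid(), reps=100, max_gen=5_000, label=name)
    if name == "chain16":
        return RunConfig(map=MapCfg(family="logistic", lam=4.0, N=50),
                         topology=TopologyCfg(kind="chain_1d", dims=16),
                         D_grid=_grid(), reps=100, max_gen=10_000, label=name)
    if name == "lattice4x4":
        return RunConfig(map=MapCfg(family="logistic", lam=4.0, N=100),
                         topology=TopologyCfg(kind="lattice_2d", dims=(4, 4)),
                         D_grid=_grid(), reps=100, max_gen=10_000, label=name)
    if name == "lattice10x10_defect":
        defects = [[4, 4], [4, 5], [5, 4], [5, 5]]
        return RunConfig(map=MapCfg(family="ricker", r=_LOG_R50, N=100),
                         topology=TopologyCfg(kind="lattice_2d", dims=(10, 10), defects=defects),
                         D=0.05, reps=50, max_gen=5_000, record_window=400, label=name)
    raise ValueError(f"unknown fixture {name!r}; known fixtures: {', '.join(FIXTURES)}")
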