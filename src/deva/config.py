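"""TOML run-configuration loading.

A run file has up to three tables::

    [ga]          # GAConfig fields: population_size, generations, ...
    [surrogate]   # SurrogateParams fields: d_min, alpha, donor_propensity, ...
    [objectives]  # names = ["metal_site", "sequence"]  (registration order)

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path

from .evolution import GAConfig
from .objectives import ObjectiveSpec, SurrogateParams, default_objectives

__all__ = ["RunConfig", "load_config"]


@dataclasses.dataclass
class RunConfig:
    ga: GAConfig
    surrogate: SurrogateParams
    objectives: list[ObjectiveSpec]


def _build(cls, table: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(table) - valid
    if unknown:
        raise ValueError(f"unknown [{section}] keys: {sorted(unknown)}")
    return cls(**table)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a TOML run config; omitted sections fall back to defaults."""
    data: dict = {}
    if path is not None:
        data = tomllib.loads(Path(path).read_text())
    ga = _build(GAConfig, data.get("ga", {}), "ga")
    surrogate = _build(SurrogateParams, data.get("surrogate", {}), "surrogate")
    available = {spec.name: spec for spec in default_objectives(surrogate)}
    names = data.get("objectives", {}).get("names", list(available))
    try:
        objectives = [available[n] for n in names]
    except KeyError as exc:
        raise ValueError(
            f"unknown objective {exc.args[0]!r}; available: {sorted(available)}"
        ) from None
    return RunConfig(ga=ga, surrogate=surrogate, objectives=objectives)
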