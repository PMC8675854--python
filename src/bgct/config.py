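"""Run configuration: parameter files, overrides, manifests.

A run configuration resolves the typical parameter table merged with
explicit overrides, carries stage selection and the global seed, and can
echo itself as a manifest so any run is exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import WEIGHT_NAMES, ModelParameters

__all__ = ["RunConfig", "load_config", "stage_seed"]

_STAGES = ("census", "scan1d", "scan2d", "landscape", "fixtures")
#: weights were only explored on [0, 7]; values outside warn but pass
EXPLORED_RANGE = (0.0, 7.0)

_KNOWN_KEYS = {"params_file", "overrides", "stages", "out", "seed",
               "tolerances"}


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run."""

    params: ModelParameters = field(default_factory=ModelParameters)
    overrides: dict = field(default_factory=dict)
    stages: tuple[str, ...] = _STAGES
    out: Path = Path("bgct-out")
    seed: int = 0
    tolerances: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        from . import __version__
        return {
            "version": __version__,
            "parameters": self.params.to_dict(),
            "overrides": dict(self.overrides),
            "stages": list(self.stages),
            "out": str(self.out),
            "seed": int(self.seed),
            "tolerances": dict(self.tolerances),
        }

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2))


def apply_overrides(params: ModelParameters, overrides: dict) -> ModelParameters:
    """Apply overrides, warning when a weight leaves the explored range."""
    for key, value in overrides.items():
        if key in WEIGHT_NAMES and not (
                EXPLORED_RANGE[0] <= float(value) <= EXPLORED_RANGE[1]):
            warnings.warn(
                f"{key}={value} lies outside the explored range "
                f"{EXPLORED_RANGE}; results are extrapolation", stacklevel=2)
    return params.replace(**overrides)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration.

    Recognized keys: ``params_file`` (flat parameter YAML), ``overrides``
    (mapping of parameter names to values), ``stages``, ``out``, ``seed``,
    ``tolerances``.  Unknown keys, unknown parameter names and invalid
    values (e.g. n = 0) raise with the offending key named.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise KeyError(f"{path}: unknown configuration keys {sorted(unknown)}")
    params = ModelParameters.load(raw["params_file"]) if "params_file" in raw \
        else ModelParameters()
    overrides = raw.get("overrides", {}) or {}
    try:
        params = apply_overrides(params, overrides)
    except (KeyError, ValueError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc
    stages = tuple(raw.get("stages", _STAGES))
    bad = set(stages) - set(_STAGES)
    if bad:
        raise KeyError(f"{path}: unknown stages {sorted(bad)}")
    return RunConfig(params=params, overrides=dict(overrides), stages=stages,
                     out=Path(raw.get("out", "bgct-out")),
                     seed=int(raw.get("seed", 0)),
                     tolerances=dict(raw.get("tolerances", {}) or {}))


def stage_seed(global_seed: int, stage: str) -> int:
    """Fan a single global seed out to per-stage seeds.

    Each stage gets ``global_seed * 8 + index`` (stages indexed in their
    pipeline order), so stages are independently reproducible from the
    one number a run records.  Kept below 2**31.
    """
    return (int(global_seed) * 8 + _STAGES.index(stage)) % (2 ** 31)
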