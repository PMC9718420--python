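"""Configuration loading, validation, snapshots and fixture generation.

Runs are configured through a flat-sectioned YAML file, one section per
parameter block::

    model:       { rho_E: 2.0, rho_I: 0.5, w_IE: 0.5, dt: 0.1, ... }
    plasticity:  { inhibitory_rule: nonlinear, tau_w_E: 1.0, ... }
    drive:       { target: rho_add, kind: sinusoid, amplitude: 0.25, ... }
    circuit:     { n_inputs: 10, pattern_rate_hi: 4.0, ... }
    recurrent:   { n_post: 30, pattern_correlation: 0.5, ... }
    experiment:  { name: simulate, T: 100.0, ... }

Every key must name a field of the corresponding parameter dataclass;
unknown keys are rejected with the offending key named, and omitted
keys fall back to the parameter-table defaults.  Each CLI run writes a
resolved-config snapshot next to its outputs so that any run is
reproducible from the snapshot plus its seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circuits import MultiInputParams, RecurrentParams, pattern_sequence
from .model import DriveSpec, FeedforwardParams
from .plasticity import PlasticityParams

__all__ = ["RunConfig", "ConfigError", "load_config", "make_fixtures", "write_snapshot"]

_SECTIONS = {
    "model": FeedforwardParams,
    "plasticity": PlasticityParams,
    "drive": DriveSpec,
    "circuit": MultiInputParams,
    "recurrent": RecurrentParams,
}

_TOP_LEVEL = {"experiment", "seed", "out_dir", "log_level"}


class ConfigError(ValueError):
    """Raised for unparsable, unknown or invalid configuration entries."""


@dataclass
class RunConfig:
    """Fully resolved configuration of one run."""

    model: FeedforwardParams = field(default_factory=FeedforwardParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    drive: DriveSpec = field(default_factory=DriveSpec)
    circuit: MultiInputParams = field(default_factory=MultiInputParams)
    recurrent: RecurrentParams = field(default_factory=RecurrentParams)
    experiment: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        out = {}
        for name, cls in _SECTIONS.items():
            block = dataclasses.asdict(getattr(self, name))
            out[name] = block
        out["experiment"] = dict(self.experiment)
        out["seed"] = self.seed
        out["out_dir"] = str(self.out_dir)
        out["log_level"] = self.log_level
        return out


def _build_section(name: str, cls, values: dict):
    valid = {f.name for f in fields(cls)}
    for key in values:
        if key not in valid:
            raise ConfigError(f"unknown key {key!r} in section {name!r}")
    try:
        return cls(**values)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section {name!r}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a YAML config file.

    An empty file yields the all-defaults configuration (the
    single-neuron feedforward regime).  Errors name the offending key.
    """
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")

    known = set(_SECTIONS) | _TOP_LEVEL
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown top-level key {key!r}")

    kwargs = {}
    for name, cls in _SECTIONS.items():
        block = raw.get(name, {}) or {}
        if not isinstance(block, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        # tuples arrive from YAML as lists
        for f in fields(cls):
            if f.name in block and isinstance(block[f.name], list):
                block[f.name] = tuple(block[f.name])
        kwargs[name] = _build_section(name, cls, block)

    exp = raw.get("experiment", {}) or {}
    if isinstance(exp, str):
        exp = {"name": exp}
    if not isinstance(exp, dict):
        raise ConfigError("section 'experiment' must be a mapping or a name")
    return RunConfig(
        **kwargs,
        experiment=exp,
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", ".")),
        log_level=str(raw.get("log_level", "INFO")),
    )


def write_snapshot(config: RunConfig, path) -> None:
    """Write the resolved configuration as YAML next to the outputs."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def make_fixtures(kind: str, n: int, seed: int, path) -> Path:
    """Write a seeded CSV fixture, reproducible byte-for-byte.

    ``weight_draws``: ``n`` initial ``(w_EE, w_EI)`` pairs drawn
    uniformly from [0, 3] — the initial-weight ensemble of the E/I
    induction experiment.  ``pattern_matrix``: a pattern schedule of
    ``n`` windows for the default multi-input circuit, one row per
    window (chosen input followed by the per-neuron rates).
    """
    path = Path(path)
    rng = np.random.default_rng(seed)
    if kind == "weight_draws":
        draws = rng.uniform(0.0, 3.0, size=(n, 2))
        df = pd.DataFrame(draws, columns=["w_EE", "w_EI"])
    elif kind == "pattern_matrix":
        params = MultiInputParams()
        choices, rates = pattern_sequence(params, T=n * params.pattern_duration, seed=seed)
        df = pd.DataFrame(rates, columns=[f"rho_{j}" for j in range(params.n_pre_E)])
        df.insert(0, "input", choices)
    else:
        raise ConfigError(f"unknown fixture kind {kind!r}")
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def dump_report(obj, path) -> None:
    """Serialise a report object (or dict) as JSON."""
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
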