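"""Run configuration: YAML round-trip and construction of model objects."""

from __future__ import annotations

import copy
import hashlib
import importlib.resources as resources

import yaml

from .anatomy import HeadDimensions, PelvisDimensions
from .errors import InvalidInputError
from .kinematics import TrajectoryConfig
from .ogden import OgdenParameters
from .solver import SolverSettings

__all__ = ["default_config", "load_config", "save_config", "config_hash",
           "material_from_config", "head_dims_from_config",
           "pelvis_dims_from_config", "trajectory_from_config",
           "solver_settings_from_config"]


def default_config():
    """Deep copy of the packaged default configuration dictionary."""
    text = resources.files("lamsim.data").joinpath("default_config.yaml").read_text()
    return yaml.safe_load(text)


def _merge(base, override):
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None):
    """Load a run config, overlaying the packaged defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise InvalidInputError(f"config {path} is not a mapping")
        cfg = _merge(cfg, user)
    return cfg


def save_config(cfg, path):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg):
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:16]


def material_from_config(cfg):
    m = cfg["material"]
    return OgdenParameters.from_poisson(m["mu"], m["alpha"], m["poisson"])


def head_dims_from_config(cfg):
    return HeadDimensions(**cfg["geometry"]["head"])


def pelvis_dims_from_config(cfg):
    return PelvisDimensions(**cfg["geometry"]["pelvis"])


def trajectory_from_config(cfg):
    return TrajectoryConfig(**cfg["trajectory"])


def solver_settings_from_config(cfg):
    s = dict(cfg["solver"])
    s.pop("tether_stiffness", None)
    return SolverSettings(**s)
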