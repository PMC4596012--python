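"""Configuration files, result serialization, and reproducibility plumbing.

Configs are flat YAML/JSON key -> value mappings using the parameter
table's symbol names in their printed units (e.g. ``Na-g`` in S/cm2,
``T-g`` in mS/cm2, ``SK-Ca`` in nM), plus kinetic-default keys, calcium
keys (``ca.*``), synapse keys (``syn.*``), homeostasis keys (``hom.*``)
and integrator settings.  Unknown keys are an error listing the valid
vocabulary; omitted keys fall back to the table defaults.

Every run directory receives a JSON manifest (config, seed, package
version, wall time) from which the deterministic outputs can be
reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biophysics import KINETIC_DEFAULTS, PARAM_TABLE, Geometry, ModelParameters
from .calcium import CalciumParams
from .homeostasis import HomeostasisParams
from .synapses import IonConcentrations, SynapseParams

__all__ = ["RunConfig", "load_config", "config_to_dict", "write_results",
           "load_manifest", "ConfigError"]


class ConfigError(ValueError):
    pass


_CA_KEYS = {f.name for f in dataclasses.fields(CalciumParams)}
_SYN_KEYS = {"P_AMPAR": "p_ampar", "NAR": "nar", "P_Ca": "p_ca_nmdar"}
_ION_KEYS = {f.name for f in dataclasses.fields(IonConcentrations)}
_HOM_KEYS = {f.name for f in dataclasses.fields(HomeostasisParams)}
_TOP_KEYS = {"dt", "seed", "diameter", "length", "stimulus", "out_dir",
             "log_level"}


@dataclasses.dataclass
class RunConfig:
    """Fully resolved configuration for one experiment."""

    model: ModelParameters
    calcium: CalciumParams
    synapse: SynapseParams
    homeostasis: HomeostasisParams
    dt: float = 0.025
    seed: int = 0
    stimulus: str = "theta"
    warnings: list[str] = dataclasses.field(default_factory=list)


def _valid_keys():
    keys = set(PARAM_TABLE) | set(KINETIC_DEFAULTS) | _TOP_KEYS
    keys |= {f"ca.{k}" for k in _CA_KEYS}
    keys |= {f"syn.{k}" for k in _SYN_KEYS}
    keys |= {f"syn.{k}" for k in _ION_KEYS}
    keys |= {f"hom.{k}" for k in _HOM_KEYS}
    return keys


def load_config(path_or_mapping) -> RunConfig:
    """Resolve a config file (YAML/JSON) or mapping against the defaults.

    Values for table symbols are interpreted in their printed units and
    converted to canonical units.  Out-of-range explicit values are
    accepted with a warning recorded on the returned config.
    """
    if isinstance(path_or_mapping, (str, Path)):
        text = Path(path_or_mapping).read_text()
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path_or_mapping}: {exc}") from exc
    else:
        raw = dict(path_or_mapping)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a flat key -> value mapping")

    valid = _valid_keys()
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(
            f"unknown config keys {sorted(unknown)}; valid keys include "
            f"{sorted(list(valid))[:12]} ... ({len(valid)} total)")

    warnings: list[str] = []
    values = {}
    for sym, row in PARAM_TABLE.items():
        if sym in raw:
            printed = float(raw[sym])
            if not (row.low <= printed <= row.high):
                warnings.append(
                    f"{sym} = {printed} outside testing range "
                    f"[{row.low}, {row.high}] (accepted: explicit override)")
            values[sym] = printed * row.scale
        else:
            values[sym] = row.default * row.scale
    kinetics = dict(KINETIC_DEFAULTS)
    for k in KINETIC_DEFAULTS:
        if k in raw:
            kinetics[k] = float(raw[k])
    geometry = Geometry(float(raw.get("diameter", 100.0)),
                        float(raw.get("length", 100.0)))
    model = ModelParameters(values=values, kinetics=kinetics, geometry=geometry,
                            seed=raw.get("seed"))

    ca_kwargs = {k: raw[f"ca.{k}"] for k in _CA_KEYS if f"ca.{k}" in raw}
    calcium = CalciumParams(**ca_kwargs)
    syn_kwargs = {attr: float(raw[f"syn.{key}"])
                  for key, attr in _SYN_KEYS.items() if f"syn.{key}" in raw}
    ion_kwargs = {k: float(raw[f"syn.{k}"]) for k in _ION_KEYS if f"syn.{k}" in raw}
    synapse = SynapseParams(concentrations=IonConcentrations(**ion_kwargs),
                            **syn_kwargs)
    hom_kwargs = {k: raw[f"hom.{k}"] for k in _HOM_KEYS if f"hom.{k}" in raw}
    homeostasis = HomeostasisParams(**hom_kwargs)

    dt = float(raw.get("dt", 0.025))
    if dt <= 0:
        raise ConfigError("dt must be > 0")
    return RunConfig(model, calcium, synapse, homeostasis, dt,
                     int(raw.get("seed", 0)), raw.get("stimulus", "theta"),
                     warnings)


def config_to_dict(cfg: RunConfig) -> dict:
    """Flat printed-unit dict that round-trips through load_config."""
    out = {}
    for sym, row in PARAM_TABLE.items():
        out[sym] = cfg.model.values[sym] / row.scale
    for k, v in cfg.model.kinetics.items():
        out[k] = v
    for f in dataclasses.fields(CalciumParams):
        v = getattr(cfg.calcium, f.name)
        if v is not None:
            out[f"ca.{f.name}"] = v
    out["syn.P_AMPAR"] = cfg.synapse.p_ampar
    out["syn.NAR"] = cfg.synapse.nar
    out["syn.P_Ca"] = cfg.synapse.p_ca_nmdar
    for f in dataclasses.fields(IonConcentrations):
        out[f"syn.{f.name}"] = getattr(cfg.synapse.concentrations, f.name)
    for f in dataclasses.fields(HomeostasisParams):
        v = getattr(cfg.homeostasis, f.name)
        if v is not None:
            out[f"hom.{f.name}"] = v
    out["dt"] = cfg.dt
    out["seed"] = cfg.seed
    out["stimulus"] = cfg.stimulus
    out["diameter"] = cfg.model.geometry.diameter
    out["length"] = cfg.model.geometry.length
    return out


def write_trajectory_csv(path, t, v, ca, extra: dict | None = None) -> None:
    df = pd.DataFrame({"time_ms": t, "v_mV": v, "ca_nM": np.asarray(ca) * 1e6})
    for name, col in (extra or {}).items():
        df[name] = col
    df.to_csv(path, index=False, float_format="%.6g")


def write_results(outputs: dict, directory, config: RunConfig | None = None,
                  seed: int | None = None, errors: dict | None = None) -> Path:
    """Write tables/arrays plus a JSON manifest; returns the manifest path.

    ``outputs`` maps relative file names to pandas DataFrames (written as
    CSV) or arrays (written via numpy .txt).  The manifest records the
    resolved config, its hash, the seed, the package version and wall
    time, and any per-model error strings.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, obj in outputs.items():
        p = directory / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(p, float_format="%.10g")
        else:
            np.savetxt(p, np.asarray(obj))
        written[name] = p.name
    cfg_dict = config_to_dict(config) if config is not None else {}
    blob = json.dumps(cfg_dict, sort_keys=True).encode()
    manifest = {
        "version": __version__,
        "seed": seed if seed is not None else (config.seed if config else None),
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "outputs": written,
        "errors": errors or {},
        "wall_time_unix": time.time(),
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def load_manifest(path) -> RunConfig:
    """Rebuild the exact RunConfig recorded in a manifest."""
    manifest = json.loads(Path(path).read_text())
    return load_config(manifest["config"])
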