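"""Configuration files and run manifests.

Configs are flat YAML with the parameter-table names (``f``,
``permeation_rate``, ``domain_area`` in mm², ``water_volume`` in mm³,
attachment parameters at top level next to a ``strategy: PA|RA`` key).
Omitted keys take the model defaults; unknown keys are rejected with the
offending name.  The manifest written next to every output records the
fully resolved parameters, the seed and the package version — enough to
reproduce the output byte-for-byte.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .params import SimulationParams, StrategySpec

__all__ = ["load_config", "save_config", "params_from_config_dict",
           "params_to_config_dict", "write_manifest", "read_manifest"]

# config key -> (internal field, to-internal, to-config) unit conversions
_RENAME = {"f": "f_sessile", "permeation_rate": "k_perm"}
_STRATEGY_KEYS = ("A_PA", "A_RA", "Q_PA", "n_hill")
_DIRECT_KEYS = (
    "mu_max", "K_s", "M_div", "C_div", "R", "V", "dt",
    "S_L", "S_H", "S_B", "Q_L", "Q_H", "D", "N_c", "H", "n_days", "N0",
    "stress_mode", "cell_diameter", "contact_dist", "div_mass_cv",
    "grow_during_dry", "motion_mode",
)
_KNOWN = set(_DIRECT_KEYS) | set(_RENAME) | set(_STRATEGY_KEYS) | {
    "strategy", "domain_area", "water_volume", "seed"}


def params_from_config_dict(cfg: dict) -> tuple[SimulationParams, int | None]:
    """Resolve a config mapping into parameters (and the seed, if given)."""
    cfg = dict(cfg or {})
    unknown = set(cfg) - _KNOWN
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    seed = cfg.pop("seed", None)
    kw: dict = {}
    for key in _DIRECT_KEYS:
        if key in cfg:
            kw[key] = cfg.pop(key)
    for cfg_key, field in _RENAME.items():
        if cfg_key in cfg:
            kw[field] = cfg.pop(cfg_key)
    if "domain_area" in cfg:            # mm^2 -> side in um
        kw["domain_side"] = float(cfg.pop("domain_area")) ** 0.5 * 1000.0
    if "water_volume" in cfg:           # mm^3 -> m^3 (divide: exact
        # inverse of the serialization below for representable values)
        kw["water_volume"] = float(cfg.pop("water_volume")) / 1e9
    defaults = StrategySpec()
    kind = cfg.pop("strategy", defaults.kind)
    strat_kw = {k: cfg.pop(k) for k in _STRATEGY_KEYS if k in cfg}
    kw["strategy"] = StrategySpec(kind=kind, **{
        k: strat_kw.get(k, getattr(defaults, k)) for k in _STRATEGY_KEYS})
    return SimulationParams(**kw), (int(seed) if seed is not None else None)


def params_to_config_dict(params: SimulationParams,
                          seed: int | None = None) -> dict:
    """Inverse of :func:`params_from_config_dict` (round-trip identity)."""
    cfg: dict = {key: getattr(params, key) for key in _DIRECT_KEYS}
    cfg["f"] = params.f_sessile
    cfg["permeation_rate"] = params.k_perm
    cfg["domain_area"] = (params.domain_side / 1000.0) ** 2   # mm^2
    cfg["water_volume"] = params.water_volume * 1e9           # mm^3
    s = params.strategy
    cfg["strategy"] = s.kind
    for k in _STRATEGY_KEYS:
        cfg[k] = getattr(s, k)
    if seed is not None:
        cfg["seed"] = seed
    return cfg


def load_config(path) -> SimulationParams:
    """Load and validate a YAML config; omitted keys take the defaults."""
    params, _ = load_config_with_seed(path)
    return params


def load_config_with_seed(path) -> tuple[SimulationParams, int | None]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return params_from_config_dict(cfg)


def save_config(params: SimulationParams, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_config_dict(params, seed), fh,
                       sort_keys=True, default_flow_style=False)


def write_manifest(path, params: SimulationParams, seed: int,
                   extra: dict | None = None) -> None:
    """Record everything needed to reproduce an output byte-for-byte."""
    from . import __version__
    manifest = {
        "software": {"name": "surfcol", "version": __version__},
        "seed": int(seed),
        "parameters": params_to_config_dict(params),
        "units": {
            "length": "um", "time": "h", "mass": "g",
            "concentration": "g m^-3", "rates": "h^-1 unless noted",
            "A_PA": "per time step (dt)",
        },
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path) -> tuple[SimulationParams, int]:
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    params, _ = params_from_config_dict(manifest["parameters"])
    return params, int(manifest["seed"])
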