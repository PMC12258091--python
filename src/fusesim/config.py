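"""YAML run configuration: one file is the single source of truth for a run.

Sections (all optional; defaults are the study conditions):

construct:   ConstructParams fields
materials:   name -> [E_MPa, nu] overrides
rules:       RuleThresholds fields plus n_min, front_rule, combine_mode
diffusion:   D (omit to calibrate), dt, coverage_threshold
protocol:    name (compression|hybrid), force, flex_duty, target_rom_deg,
             n_iterations, rom_tolerance_deg
run:         cage_material, seed
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .construct import ConstructParams
from .diffusion import DiffusionParams
from .errors import ParameterError
from .materials import MaterialLibrary
from .pipeline import (
    ProtocolConfig,
    make_compression_protocol,
    make_hybrid_protocol,
)
from .regulation import RuleThresholds


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ParameterError(f"config root must be a mapping, got {type(cfg)}")
    return cfg


def construct_params(cfg: dict) -> ConstructParams:
    return ConstructParams(**cfg.get("construct", {}))


def material_library(cfg: dict) -> MaterialLibrary:
    lib = MaterialLibrary()
    for name, pair in cfg.get("materials", {}).items():
        lib.table[name] = (float(pair[0]), float(pair[1]))
    return MaterialLibrary(lib.table)  # re-validate


def rule_thresholds(cfg: dict) -> RuleThresholds:
    rules = dict(cfg.get("rules", {}))
    rules.pop("n_min", None)
    rules.pop("front_rule", None)
    rules.pop("combine_mode", None)
    return RuleThresholds(**rules)


def diffusion_params(cfg: dict) -> tuple[DiffusionParams, float | None]:
    """(base params, pinned D or None to trigger calibration)."""
    d = dict(cfg.get("diffusion", {}))
    D = d.pop("D", None)
    if D is not None:
        d["D"] = float(D)
    return DiffusionParams(**d), (float(D) if D is not None else None)


def protocol_config(cfg: dict, override_name: str | None = None) -> ProtocolConfig:
    p = dict(cfg.get("protocol", {}))
    name = override_name or p.pop("name", "compression")
    if override_name:
        p.pop("name", None)
    common = {k: p[k] for k in ("force", "n_iterations") if k in p}
    if name == "compression":
        proto = make_compression_protocol(**common)
    elif name == "hybrid":
        hybrid_keys = ("flex_duty", "target_rom_deg", "adjacent_flexibility")
        proto = make_hybrid_protocol(
            **common, **{k: p[k] for k in hybrid_keys if k in p}
        )
    else:
        raise ParameterError(f"unknown protocol {name!r}")
    if "rom_tolerance_deg" in p:
        from dataclasses import replace

        proto = replace(proto, rom_tolerance_deg=float(p["rom_tolerance_deg"]))
    return proto


def run_settings(cfg: dict) -> dict:
    r = dict(cfg.get("run", {}))
    rules = cfg.get("rules", {})
    return {
        "cage_material": r.get("cage_material", "peek"),
        "seed": int(r.get("seed", 0)),
        "n_min": float(rules.get("n_min", 0.25)),
        "front_rule": bool(rules.get("front_rule", True)),
        "combine_mode": rules.get("combine_mode", "weighted"),
    }
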