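"""Run configuration: packaged defaults, YAML loading, validation.

Every packaged default is a constant of the underlying analysis (trial
design, economic constants, amendment doses and prices, finance settings),
tagged with a source description in :data:`CONSTANT_SOURCES` so reports can
trace each number.  Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass

import yaml

__all__ = [
    "DEFAULT_CONFIG",
    "CONSTANT_SOURCES",
    "default_config",
    "load_config",
    "config_hash",
    "Finding",
    "validate_config",
]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "design": {
        "grasses": ["brachiaria", "panicum"],
        "setting": "pot",
        "replicates": None,  # null -> per-design default (5 pot; 3/4 field)
        "n_simulations": 200,
    },
    "effects": {
        "matter_type": "dry",
        "n_permutations": 999,
        "factors": ["biochar", "fertilizer"],
    },
    "economics": {
        "delta_b": None,  # null -> measured from the simulated biochar effect
        "r": 0.026,
        "f_min": 10.0,
        "f_max": 17.0,
        "meat_price_local": 9.42,
        "fx": 3.51,
        "c_avoided": 443.7,
        "sparing_method": "direct",
        "land_sparing_per_ha": 91.0,
        "soil_seq_per_ha": 13.0,
        "carbon_price": 5.0,
        "intensified_area": 180000.0,
    },
    "costs": {
        "wage": 1.25,
        "include_labour": True,
        "kiln_preset": "brick_small",
        "target_mass_kg": 15000.0,
        "deadline_days": 10,
        "amendments": None,  # null -> packaged dose/price table
    },
    "finance": {
        "discount_rate": 0.06,
        "horizon_years": 10,
        "carbon_basis": "land_plus_soil",  # or "land_only"
        "upfront_cost": None,  # null -> biochar amendment total
    },
    "output": {"dir": "results"},
}

#: traceability of every packaged numeric constant
CONSTANT_SOURCES: dict = {
    "economics.r": "0.026 t carcass-equivalent per t DM ingested; modal "
    "full-cycle beef system of the Atlantic Forest at 100% efficiency",
    "economics.f_min": "10 t DM/ha/yr, minimum productivity of Brachiaria cv. Marandu",
    "economics.f_max": "17 t DM/ha/yr, maximum productivity of Brachiaria cv. Marandu",
    "economics.meat_price_local": "R$9.42/kg carcass, Rio de Janeiro producer "
    "price over the trial period",
    "economics.fx": "R$3.51 per US$, trial-period exchange rate",
    "economics.c_avoided": "443.7 tCO2eq/ha avoided emissions per hectare of "
    "Atlantic Forest spared from conversion",
    "economics.land_sparing_per_ha": "91 tCO2eq/ha credited to land sparing "
    "per hectare intensified with biochar",
    "economics.soil_seq_per_ha": "13 tCO2eq/ha sequestered in soil by the "
    "biochar amendment",
    "economics.carbon_price": "US$5 per tCO2eq unit carbon price",
    "economics.intensified_area": "180,000 ha pasture-intensification target "
    "of the state of Rio de Janeiro",
    "costs.labour_law": "Brazilian labour law: up to 44 h/week, 8 h/day",
    "costs.amendments": "trial doses and totals: biochar 15 t/ha US$6,410; "
    "fertilizer 682.5 kg/ha US$893; inoculant 10 kg/ha US$473; lime 3 t/ha US$74",
    "finance.discount_rate": "6%/yr attractiveness rate",
    "trial.design": "2^3 factorial (Brachiaria) / 2^2 (Panicum), 5 replicate "
    "pots, 6 harvests at 68/139/207/269/361/454 days after sowing",
    "trial.calibration": "treatment multipliers set to the observed cumulative "
    "dry-matter differences vs control (biochar-only Brachiaria +27.4%, "
    "biochar+fertilizer Panicum +25.5%, ...)",
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}{key}"
        if key not in base:
            raise KeyError(f"unknown configuration key: {where}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, where + ".")
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Packaged defaults, deep-merged with a YAML file and/or a dict.

    Unknown keys at any level raise ``KeyError``.
    """
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("configuration YAML must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(config: dict) -> str:
    """sha256 of the canonical JSON form (provenance)."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


@dataclass(frozen=True)
class Finding:
    level: str  # "error" | "warning"
    key: str
    message: str


def validate_config(config: dict) -> list[Finding]:
    """Errors and warnings for a config; a clean default yields warnings only
    (the documented source inconsistencies), never errors."""
    findings: list[Finding] = []

    def err(key, msg):
        findings.append(Finding("error", key, msg))

    def warn(key, msg):
        findings.append(Finding("warning", key, msg))

    try:
        config = _merge(DEFAULT_CONFIG, config)
    except KeyError as exc:
        err("config", str(exc))
        return findings

    design = config["design"]
    for grass in design["grasses"]:
        if grass not in ("brachiaria", "panicum"):
            err("design.grasses", f"unknown grass {grass!r}")
    if design["setting"] not in ("pot", "field"):
        err("design.setting", f"unknown setting {design['setting']!r}")
    reps = design["replicates"]
    if reps is not None and reps < 2:
        err("design.replicates", "at least 2 replicates required")
    if design["n_simulations"] < 1:
        err("design.n_simulations", "need at least one simulation")

    eff = config["effects"]
    if eff["matter_type"] not in ("dry", "fresh"):
        err("effects.matter_type", "must be 'dry' or 'fresh'")
    if eff["n_permutations"] < 99:
        err("effects.n_permutations", "at least 99 permutations required")
    if "inoculant" in eff["factors"] and "panicum" in design["grasses"] and \
            "brachiaria" not in design["grasses"]:
        err("effects.factors", "inoculant is a brachiaria-only factor")

    econ = config["economics"]
    for key in ("r", "f_min", "f_max", "meat_price_local", "fx", "carbon_price"):
        if econ[key] is not None and econ[key] <= 0:
            err(f"economics.{key}", "must be positive")
    if econ["f_min"] > econ["f_max"]:
        err("economics.f_min", "f_min exceeds f_max")
    if econ["sparing_method"] not in ("direct", "proportional", "naive"):
        err("economics.sparing_method", "unknown sparing method")

    costs = config["costs"]
    if costs["wage"] < 0:
        err("costs.wage", "wage must be >= 0")
    if costs["deadline_days"] <= 0:
        err("costs.deadline_days", "deadline must be positive")
    if costs["target_mass_kg"] < 0:
        err("costs.target_mass_kg", "target mass must be >= 0")

    fin = config["finance"]
    if fin["discount_rate"] <= -1:
        err("finance.discount_rate", "rate must exceed -1")
    if fin["horizon_years"] < 1:
        err("finance.horizon_years", "horizon must be >= 1")
    if fin["carbon_basis"] not in ("land_plus_soil", "land_only"):
        err("finance.carbon_basis", "unknown carbon basis")

    # documented inconsistencies in the packaged constants
    from .costs import AMENDMENT_DEFAULTS

    amendments = costs["amendments"] or AMENDMENT_DEFAULTS
    for name, spec in amendments.items():
        comp = sum(q * p for q, _u, p in spec.get("components", {}).values())
        if comp > float(spec["total"]):
            warn(
                f"costs.amendments.{name}",
                f"priced components (US${comp:,.0f}) exceed the calibrated "
                f"per-ha total (US${spec['total']:,.0f}); the published dose "
                f"and unit price are mutually inconsistent — the calibrated "
                f"total is used",
            )
    warn(
        "finance",
        "NPV/break-even figures depend on cash-flow timing conventions; see "
        "the methods note before comparing against externally published values",
    )
    return findings
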