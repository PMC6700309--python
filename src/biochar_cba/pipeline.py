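"""End-to-end pipeline: simulate -> effects -> valuation -> costs -> finance.

``run_pipeline`` wires the stages together under one configuration and
seed, producing a :class:`Report` whose payload is deterministic given the
seed (no timestamps).  Each stage is also individually importable and the
CLI exposes them as subcommands, so the composition here adds no logic of
its own.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import costs as costs_mod
from . import effects as effects_mod
from . import finance as finance_mod
from . import trial as trial_mod
from . import valuation as valuation_mod
from .config import CONSTANT_SOURCES, config_hash, default_config, validate_config

__all__ = ["Report", "run_pipeline", "spawn_seeds"]

log = logging.getLogger(__name__)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2^31) from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


@dataclass
class Report:
    """Everything one pipeline run computed, plus provenance."""

    records: dict[str, pd.DataFrame]
    effect_tables: dict[str, dict[str, effects_mod.EffectTable]]
    permutation: list[effects_mod.PermutationResult]
    valuation: dict
    costs: dict
    scenarios: pd.DataFrame
    findings: list
    provenance: dict = field(default_factory=dict)

    def to_payload(self) -> dict:
        """JSON-serializable payload; deterministic given the seed."""
        return {
            "provenance": self.provenance,
            "effects": {
                grass: {
                    matter: tab.to_frame().round(10).to_dict()
                    for matter, tab in per_grass.items()
                }
                for grass, per_grass in self.effect_tables.items()
            },
            "permutation": [r.to_dict() for r in self.permutation],
            "valuation": self.valuation,
            "costs": self.costs,
            "scenarios": self.scenarios.round(10).to_dict(orient="records"),
            "findings": [
                {"level": f.level, "key": f.key, "message": f.message}
                for f in self.findings
            ],
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for grass, df in self.records.items():
            trial_mod.write_harvest_csv(df, outdir / f"harvest_{grass}.csv")
        for grass, per_grass in self.effect_tables.items():
            for matter, tab in per_grass.items():
                tab.to_csv(outdir / f"effects_{grass}_{matter}.csv")
        with open(outdir / "permutation.json", "w") as fh:
            json.dump([r.to_dict() for r in self.permutation], fh, indent=2)
        self.scenarios.to_csv(outdir / "scenarios.csv", index=False)
        pd.DataFrame(self.costs["amendments"]).to_csv(
            outdir / "amendment_costs.csv", index=False
        )
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.to_payload(), fh, indent=2, sort_keys=True)


def run_pipeline(config: dict | None = None, seed: int | None = None,
                 outdir=None) -> Report:
    """Run every stage under one config; idempotent given the seed."""
    cfg = copy.deepcopy(config) if config is not None else default_config()
    if seed is not None:
        cfg["seed"] = int(seed)  # the hash covers the effective seed
    findings = validate_config(cfg)
    errors = [f for f in findings if f.level == "error"]
    if errors:
        raise ValueError(
            "configuration stage failed: "
            + "; ".join(f"{f.key}: {f.message}" for f in errors)
        )
    if seed is None:
        seed = int(cfg["seed"])

    design_cfg = cfg["design"]
    eff_cfg = cfg["effects"]
    econ = cfg["economics"]
    cost_cfg = cfg["costs"]
    fin = cfg["finance"]

    # --- simulate ---------------------------------------------------------
    grasses = list(design_cfg["grasses"])
    child_seeds = spawn_seeds(seed, len(grasses) + 1)
    records: dict[str, pd.DataFrame] = {}
    designs: dict[str, trial_mod.TrialDesign] = {}
    for grass, s in zip(grasses, child_seeds):
        if design_cfg["setting"] == "pot":
            design = trial_mod.TrialDesign.pot_default(grass)
        else:
            design = trial_mod.TrialDesign.field_default(grass)
        if design_cfg["replicates"] is not None:
            design = trial_mod.TrialDesign(
                grass=design.grass, setting=design.setting,
                factors=design.factors, replicates=design_cfg["replicates"],
                harvest_days=design.harvest_days,
                blocks=None if design.setting == "pot" else design_cfg["replicates"],
            )
        model = trial_mod.default_effect_model(design, seed=s)
        log.info("simulate: %s %s seed=%d", grass, design.setting, s)
        records[grass] = trial_mod.generate_trial(design, model)
        designs[grass] = design

    # --- effects ----------------------------------------------------------
    effect_tables = {
        grass: {
            matter: effects_mod.build_effect_table(df, matter)
            for matter in ("dry", "fresh")
        }
        for grass, df in records.items()
    }
    perm_seed = child_seeds[-1]
    permutation = []
    first_grass = grasses[0]
    for factor in eff_cfg["factors"]:
        permutation.append(
            effects_mod.permutation_factorial_test(
                records[first_grass], factor,
                n_permutations=eff_cfg["n_permutations"],
                seed=perm_seed, matter_type=eff_cfg["matter_type"],
            )
        )

    # --- valuation --------------------------------------------------------
    matter = eff_cfg["matter_type"]
    if econ["delta_b"] is not None:
        delta_b = float(econ["delta_b"])
        delta_b_source = "configured"
    else:
        delta_b = float(effect_tables[first_grass][matter].cumulative["B"]) / 100.0
        delta_b_source = f"measured biochar cumulative {matter} diff, {first_grass}"

    def profit(f):
        return valuation_mod.meat_profit(
            valuation_mod.MeatParams(
                delta_b=delta_b, r=econ["r"], f=f,
                meat_price_local=econ["meat_price_local"], fx=econ["fx"],
            )
        )

    m_min, m_max = profit(econ["f_min"]), profit(econ["f_max"])
    carbon = valuation_mod.CarbonParams(
        c_avoided=econ["c_avoided"], sparing_method=econ["sparing_method"],
        land_sparing_per_ha=econ["land_sparing_per_ha"],
        soil_seq_per_ha=econ["soil_seq_per_ha"],
        carbon_price=econ["carbon_price"],
        intensified_area=econ["intensified_area"],
    )
    sparing = valuation_mod.land_sparing_savings(carbon, delta_b)
    valuation = {
        "delta_b": delta_b,
        "delta_b_source": delta_b_source,
        "meat_profit_min_usd_ha": m_min.usd_per_ha,
        "meat_profit_min_usd_ha_floor": m_min.usd_per_ha_floor,
        "meat_profit_max_usd_ha": m_max.usd_per_ha,
        "meat_profit_max_usd_ha_floor": m_max.usd_per_ha_floor,
        "land_sparing_tco2eq_ha": sparing,
        "soil_seq_tco2eq_ha": carbon.soil_seq_per_ha,
        "carbon_payment_usd_ha": valuation_mod.carbon_payment(
            sparing, carbon.carbon_price
        ),
        "state_land_sparing": valuation_mod.state_totals(
            carbon, include_soil=False, delta_b=delta_b
        ),
        "state_with_soil": valuation_mod.state_totals(
            carbon, include_soil=True, delta_b=delta_b
        ),
    }

    # --- costs ------------------------------------------------------------
    labour = costs_mod.LabourPolicy(
        wage=cost_cfg["wage"], include_labour=cost_cfg["include_labour"]
    )
    kiln = costs_mod.KILN_PRESETS[cost_cfg["kiln_preset"]]
    plan = costs_mod.kiln_plan(
        cost_cfg["target_mass_kg"], cost_cfg["deadline_days"], kiln, labour
    )
    amendments = costs_mod.amendment_cost_table(cost_cfg["amendments"])
    totals = {a.name: a.total_per_ha for a in amendments}
    costs = {
        "kiln_plan": {
            "preset": kiln.name,
            "n_kilns": plan.n_kilns,
            "n_workers": plan.n_workers,
            "cycles": plan.cycles,
            "labour_cost_usd": plan.labour_cost,
            "equipment_cost_usd": plan.equipment_cost,
            "total_cost_usd": plan.total_cost,
        },
        "amendments": [
            {
                "name": a.name,
                "dose_per_ha": a.dose_per_ha,
                "dose_unit": a.dose_unit,
                "component_cost_usd": a.component_cost,
                "transport_cost_usd": a.transport_cost,
                "total_per_ha_usd": a.total_per_ha,
            }
            for a in amendments
        ],
        "biochar_vs_fertilizer_pct": round(
            costs_mod.percent_cost_difference(
                totals["biochar"], totals["fertilizer"]
            )
        ),
    }

    # --- finance ----------------------------------------------------------
    upfront = fin["upfront_cost"]
    if upfront is None:
        upfront = totals["biochar"]
    carbon_per_ha = sparing + (
        carbon.soil_seq_per_ha if fin["carbon_basis"] == "land_plus_soil" else 0.0
    )
    scenarios = finance_mod.scenario_report(
        upfront_cost=upfront,
        gain_range=(m_min.usd_per_ha, m_max.usd_per_ha),
        carbon_per_ha=carbon_per_ha,
        discount_rate=fin["discount_rate"],
        horizon_years=fin["horizon_years"],
    )

    report = Report(
        records=records,
        effect_tables=effect_tables,
        permutation=permutation,
        valuation=valuation,
        costs=costs,
        scenarios=scenarios,
        findings=findings,
        provenance={
            "config_hash": config_hash(cfg),
            "seed": seed,
            "child_seeds": child_seeds,
            "constant_sources": CONSTANT_SOURCES,
            "conventions_note": finance_mod.CONVENTIONS_NOTE,
        },
    )
    if outdir is not None:
        report.write(outdir)
    return report
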