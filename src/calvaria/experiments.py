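"""Experiment grid: baseline, material-property tests 1-3, formation-rate
tests 4-5, and the 2x2 CSF-model x formation-scenario comparison.

Each experiment is a fully specified configuration (geometry, materials,
growth schedule, formation rule, contact) run through the same pipeline:
generate the synthetic skull, grow it from 4 to 76 months, and report final
morphometrics, per-lobe contact pressures and patency timelines.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace

import pandas as pd

from .fe_core import ContactSpec, MaterialCard, SolverError
from .growth_formation import FormationRule, GrowthResult, build_schedule, run_growth
from .morphometrics import (
    MorphometricsReport,
    PatencyTimeline,
    PressureReport,
    measure,
    patency,
    pressure_report,
)
from .synthetic_skull import CraniotomySpec, SkullParams, generate_calvaria

log = logging.getLogger("calvaria")


@dataclass
class ExperimentConfig:
    name: str
    csf_present: bool = False                 # Model I (True) vs Model II
    scenario: str = "gradual"                 # Scenario I vs II
    bone: tuple = (3000.0, 0.3)
    suture: tuple = (30.0, 0.3)
    craniotomy: tuple = (30.0, 0.3)
    brain: tuple = (100.0, 0.48)
    csf: tuple = (40.0, 0.48)
    suture_rate: float = 0.1                  # mm/month
    craniotomy_rate: float = 0.8
    rate_overrides: dict = field(default_factory=dict)
    closure_deadlines: dict = field(default_factory=dict)
    mesh_size: float = 9.0
    n_substeps: int = 3
    substep_multiplier: int = 1               # extra substeps for stiff ratios
    seed: int = 0

    def validate(self):
        if self.scenario not in ("gradual", "bulk"):
            raise ValueError(f"{self.name}: unknown scenario {self.scenario!r}")
        for nm in ("bone", "suture", "craniotomy", "brain", "csf"):
            E, nu = getattr(self, nm)
            if E <= 0 or not (-1 < nu < 0.5):
                raise ValueError(f"{self.name}: invalid material {nm}")
        if self.suture_rate < 0 or self.craniotomy_rate < 0:
            raise ValueError(f"{self.name}: negative formation rate")

    def skull_params(self) -> SkullParams:
        return SkullParams(
            csf_thickness=2.5 if self.csf_present else 0.0,
            craniotomy_spec=CraniotomySpec(),
            mesh_size=self.mesh_size,
            seed=self.seed,
        )

    def material_card(self) -> MaterialCard:
        return MaterialCard.baseline(
            bone=self.bone, suture=self.suture, craniotomy=self.craniotomy,
            brain=self.brain, csf=self.csf,
        )

    def formation_rule(self) -> FormationRule:
        return FormationRule(
            scenario=self.scenario,
            suture_rate=self.suture_rate,
            craniotomy_rate=self.craniotomy_rate,
            rate_overrides=dict(self.rate_overrides),
            closure_deadlines=dict(self.closure_deadlines),
            bulk_ramp_start=self.suture[0],
            formed_modulus=self.bone[0],
        )

    def manifest(self) -> dict:
        return {
            "name": self.name,
            "model": "I (CSF present)" if self.csf_present else "II (CSF absent)",
            "scenario": self.scenario,
            "materials_E_nu": {
                "bone": self.bone, "suture": self.suture,
                "craniotomy": self.craniotomy, "brain": self.brain, "csf": self.csf,
            },
            "rates_mm_per_month": {
                "suture": self.suture_rate, "craniotomy": self.craniotomy_rate,
                **self.rate_overrides,
            },
            "closure_deadlines_months": self.closure_deadlines,
            "mesh_size_mm": self.mesh_size,
            "n_substeps": self.n_substeps * self.substep_multiplier,
            "seed": self.seed,
        }


def builtin_configs(mesh_size: float = 9.0, n_substeps: int = 3) -> dict:
    """The experiment grid: baseline + sensitivity tests 1-5 (run as Model II
    under the gradual scenario) + the four Model x Scenario combinations."""
    base = ExperimentConfig("baseline", mesh_size=mesh_size, n_substeps=n_substeps)
    cfgs = {
        "baseline": base,
        # material sensitivity
        "test1": replace(base, name="test1", bone=(421.0, 0.22)),
        "test2": replace(base, name="test2", craniotomy=(0.003, 0.3),
                         substep_multiplier=3),
        "test3": replace(base, name="test3", brain=(0.003, 0.48),
                         substep_multiplier=3),
        # formation-rate sensitivity
        "test4": replace(base, name="test4", suture_rate=0.2),
        "test5": replace(
            base, name="test5", suture_rate=0.2,
            rate_overrides={"metopic": 0.6, "anterior_fontanelle": 0.6},
            closure_deadlines={"metopic": 24.0, "anterior_fontanelle": 24.0},
        ),
        # CSF-model x formation-scenario comparison
        "model1_scenario1": replace(base, name="model1_scenario1", csf_present=True),
        "model2_scenario1": replace(base, name="model2_scenario1"),
        "model1_scenario2": replace(base, name="model1_scenario2",
                                    csf_present=True, scenario="bulk"),
        "model2_scenario2": replace(base, name="model2_scenario2", scenario="bulk"),
    }
    for c in cfgs.values():
        c.validate()
    return cfgs


@dataclass
class ExperimentBundle:
    config: ExperimentConfig
    result: GrowthResult
    morphometrics: MorphometricsReport
    pressures: PressureReport
    patency: PatencyTimeline
    manifest: dict


def run_experiment(config: ExperimentConfig, out_dir=None,
                   keep_states: bool = False) -> ExperimentBundle:
    """Run one experiment end to end; deterministic for a given seed."""
    config.validate()
    log.info("experiment %s: generating skull (mesh_size=%.1f mm)",
             config.name, config.mesh_size)
    mesh = generate_calvaria(config.skull_params())
    schedule = build_schedule()
    rule = config.formation_rule()
    card = config.material_card()
    n_sub = config.n_substeps * config.substep_multiplier
    try:
        result = run_growth(mesh, card, schedule, rule, contact=ContactSpec(),
                            n_substeps=n_sub, keep_states=True)
    except SolverError as e:
        raise SolverError(f"experiment {config.name!r}: {e}") from e
    morpho = measure(result.mesh, age=schedule.end_age)
    press = pressure_report(result.final_state, result.mesh)
    pat = patency(result)
    manifest = config.manifest()
    manifest["n_elements"] = int(len(mesh.tets))
    manifest["final_icv_ml"] = float(result.records[-1].icv_volume_ml)
    bundle = ExperimentBundle(config, result, morpho, press, pat, manifest)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        _write_bundle(bundle, out_dir)
    if not keep_states:
        # keep only the final state (pressure/complementarity checks)
        for r in bundle.result.records[:-1]:
            r.state = None
    return bundle


def _write_bundle(bundle: ExperimentBundle, out_dir):
    from .io import save_vtu

    name = bundle.config.name
    base = os.path.join(out_dir, name)
    with open(base + "_manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    pd.DataFrame([bundle.morphometrics.to_dict()]).to_csv(
        base + "_morphometrics.csv", index=False)
    bundle.pressures.to_frame().to_csv(base + "_pressure.csv")
    bundle.patency.to_frame().to_csv(base + "_patency.csv", index=False)
    save_vtu(bundle.result.mesh, base + "_final.vtu")


def tabulate(bundles) -> dict:
    """Comparison tables across experiments (dimension + pressure shapes)."""
    bundles = list(bundles)
    if not bundles:
        raise ValueError("no bundles to tabulate")
    dims, press = [], []
    for b in sorted(bundles, key=lambda b: b.config.name):
        m = b.morphometrics
        dims.append({
            "experiment": b.config.name,
            "length_mm": m.length, "width_mm": m.width, "height_mm": m.height,
            "cephalic_index": m.cephalic_index, "icv_volume_ml": m.icv_volume,
        })
        row = {"experiment": b.config.name}
        for lobe, v in b.pressures.per_lobe.items():
            for stat in ("min", "max", "mean"):
                row[f"{lobe}_{stat}_MPa"] = v[stat]
        press.append(row)
    dims_df = pd.DataFrame(dims).set_index("experiment")
    press_df = pd.DataFrame(press).set_index("experiment")
    # internal consistency: CI recomputable from the stored columns
    from .morphometrics import cephalic_index

    for name, row in dims_df.iterrows():
        ci = cephalic_index(row["width_mm"], row["length_mm"])
        if abs(ci - row["cephalic_index"]) > 0.011:
            raise ValueError(f"inconsistent CI column for {name}")
    return {"dimensions": dims_df, "pressures": press_df}
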