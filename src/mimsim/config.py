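"""YAML (de)serialization for run configuration objects.

Covers the pieces of a virtual experiment that are not part of the kinetic
network itself: solver settings, promoter wiring, genotypes, inhibitor
panels and treatment plans.  The representation is a plain mapping per
object so files remain hand-editable.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .engine import SolverSettings
from .experiment import Treatment, TreatmentPlan
from .perturb import Genotype, InhibitorSpec, MutationDirective
from .promoter import GeneParams, PromoterConfig, TFBinding, TFBSConfig

__all__ = [
    "solver_settings_to_dict", "solver_settings_from_dict",
    "promoter_to_dict", "promoter_from_dict",
    "genotype_to_dict", "genotype_from_dict",
    "inhibitors_to_dict", "inhibitors_from_dict",
    "plan_to_dict", "plan_from_dict",
    "save_yaml", "load_yaml",
]


def solver_settings_to_dict(s: SolverSettings) -> dict:
    return asdict(s)


def solver_settings_from_dict(d: dict) -> SolverSettings:
    return SolverSettings(**d)


def promoter_to_dict(p: PromoterConfig) -> dict:
    return {
        "rnap_concentration": p.rnap_concentration,
        "k_rnap": p.k_rnap,
        "k_rnap_is_kd": p.k_rnap_is_kd,
        "sites": [
            {
                "site_name": s.site_name,
                "bindings": [
                    {k: v for k, v in asdict(b).items() if v is not None}
                    for b in s.bindings
                ],
            }
            for s in p.sites
        ],
        "genes": {g: asdict(params) for g, params in p.genes.items()},
    }


def promoter_from_dict(d: dict) -> PromoterConfig:
    sites = [
        TFBSConfig(s["site_name"], [TFBinding(**b) for b in s.get("bindings", [])])
        for s in d["sites"]
    ]
    genes = {g: GeneParams(**params) for g, params in d.get("genes", {}).items()}
    return PromoterConfig(
        sites=sites,
        rnap_concentration=d["rnap_concentration"],
        k_rnap=d["k_rnap"],
        k_rnap_is_kd=d.get("k_rnap_is_kd", False),
        genes=genes,
    )


def genotype_to_dict(g: Genotype) -> dict:
    return {
        "name": g.name,
        "directives": [
            {k: v for k, v in asdict(m).items() if v is not None}
            for m in g.directives
        ],
    }


def genotype_from_dict(d: dict) -> Genotype:
    return Genotype(
        d["name"],
        tuple(MutationDirective(**m) for m in d.get("directives", [])),
    )


def inhibitors_to_dict(panel: dict[str, InhibitorSpec]) -> dict:
    return {
        name: {k: v for k, v in asdict(spec).items() if v is not None and k != "name"}
        for name, spec in panel.items()
    }


def inhibitors_from_dict(d: dict) -> dict[str, InhibitorSpec]:
    return {name: InhibitorSpec(name=name, **body) for name, body in d.items()}


def plan_to_dict(plan: TreatmentPlan) -> dict:
    return {
        "protein_readout_time": plan.protein_readout_time,
        "mrna_readout_times": list(plan.mrna_readout_times),
        "include_vehicle_control": plan.include_vehicle_control,
        "treatments": [
            {"label": t.label,
             "inhibitors": [i if isinstance(i, str) else i.name for i in t.inhibitors]}
            for t in plan.treatments
        ],
    }


def plan_from_dict(d: dict) -> TreatmentPlan:
    return TreatmentPlan(
        treatments=[
            Treatment(t["label"], tuple(t.get("inhibitors", ())))
            for t in d.get("treatments", [])
        ],
        protein_readout_time=d.get("protein_readout_time", 1800.0),
        mrna_readout_times=tuple(d.get("mrna_readout_times", (14400.0, 28800.0))),
        include_vehicle_control=d.get("include_vehicle_control", True),
    )


def save_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False), encoding="utf-8")


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text(encoding="utf-8"))
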