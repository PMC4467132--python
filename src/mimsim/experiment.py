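"""Orchestrate control and treated simulations into normalized readouts.

The pipeline mirrors a wet inhibitor experiment: apply the genotype,
initialize every moiety pool to its unbound form, bring the network to its
quasi-stationary baseline, then for each treatment apply the inhibitors and
simulate forward.  Protein endpoints (ppERK/ERK, pAKT/AKT) are read at
30 min, mRNA endpoints (MYC, CCND1) at 4 h and 8 h, and every readout is
divided by the vehicle-control value at the same time, so untreated rows
are exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import (
    SimulationContext,
    SimulationResult,
    SolverSettings,
    equilibrate,
    initialize_state,
    simulate,
)
from .network import NetworkModel, moiety_totals
from .perturb import (
    Genotype,
    InhibitorSpec,
    PRESET_INHIBITORS,
    apply_genotype,
    apply_inhibitor,
    calibrate_inhibitor,
    embed_state,
    targets_mek,
)
from .readout import phospho_fraction

__all__ = [
    "Treatment",
    "TreatmentPlan",
    "READOUT_COLUMNS",
    "phospho_ratio",
    "run_experiment",
    "simulate_actd",
]

READOUT_COLUMNS = ["treatment", "endpoint", "time_s", "value", "flag"]

VEHICLE_LABEL = "vehicle"


@dataclass
class Treatment:
    label: str
    inhibitors: tuple = ()  # names (preset lookup) or InhibitorSpec objects


@dataclass
class TreatmentPlan:
    treatments: list[Treatment] = field(default_factory=list)
    protein_readout_time: float = 1800.0  # 30 min
    mrna_readout_times: tuple[float, ...] = (14400.0, 28800.0)  # 4 h, 8 h
    include_vehicle_control: bool = True

    def __post_init__(self) -> None:
        if self.protein_readout_time <= 0 or any(t <= 0 for t in self.mrna_readout_times):
            raise ValueError("readout times must be positive")

    def all_times(self) -> list[float]:
        return sorted({self.protein_readout_time, *self.mrna_readout_times})


def phospho_ratio(
    model: NetworkModel, result: SimulationResult, moiety: str, time: float
) -> float:
    """Active-form / total-moiety ratio at a trajectory time point."""
    return phospho_fraction(model, result.state_at(time), moiety)


def _resolve(inhibitor) -> InhibitorSpec:
    if isinstance(inhibitor, InhibitorSpec):
        return inhibitor
    try:
        return PRESET_INHIBITORS[inhibitor]
    except KeyError:
        raise KeyError(
            f"unknown inhibitor {inhibitor!r}; presets: {sorted(PRESET_INHIBITORS)}"
        ) from None


def _protein_endpoints(model: NetworkModel) -> list[tuple[str, str]]:
    out = []
    for moiety, endpoint in (("ERK", "ERKPP_ratio"), ("AKT", "AKTP_ratio")):
        if moiety in model.annotations.get("readouts", {}):
            out.append((moiety, endpoint))
    return out


def _mrna_endpoints(model: NetworkModel) -> list[tuple[str, str]]:
    if model.promoter is None:
        return []
    return [(gene, f"{gene}_mRNA") for gene in model.promoter.genes]


def run_experiment(
    model: NetworkModel,
    genotype: Genotype,
    plan: TreatmentPlan,
    settings: SolverSettings | None = None,
    strengths: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate a treatment plan and return the normalized readout table.

    ``strengths`` maps inhibitor names to pre-calibrated mechanistic
    strengths; inhibitors carrying only a documented inhibition level are
    calibrated on the fly (once each) against this model and genotype.
    Endpoints whose control value is zero are emitted with value NaN and
    flag ``undefined_control`` rather than dropped.
    """
    settings = settings or SolverSettings()
    strengths = dict(strengths or {})

    base = apply_genotype(model, genotype)
    eq = equilibrate(base, initialize_state(base), settings)
    t_end = max(plan.all_times())

    control = simulate(base, eq.state, t_end, settings, t_eval=plan.all_times())
    control_vals: dict[tuple[str, float], float] = {}
    for moiety, endpoint in _protein_endpoints(base):
        try:
            cv = phospho_ratio(base, control, moiety, plan.protein_readout_time)
        except ZeroDivisionError:  # moiety nulled by the genotype
            cv = 0.0
        control_vals[(endpoint, plan.protein_readout_time)] = cv
    for gene, endpoint in _mrna_endpoints(base):
        sid = base.promoter.genes[gene].mrna_species
        for t in plan.mrna_readout_times:
            control_vals[(endpoint, t)] = control.value(sid, t)

    erkpp_control = None
    erk_active = base.annotations.get("readouts", {}).get("ERK", {}).get("active", [])
    if erk_active:
        state = dict(zip([s.id for s in base.species], eq.state))
        erkpp_control = sum(state.get(s, 0.0) for s in erk_active)

    rows: list[dict] = []

    def emit(label: str, endpoint: str, t: float, value: float, control_value: float):
        if control_value == 0:
            rows.append(
                dict(treatment=label, endpoint=endpoint, time_s=t,
                     value=np.nan, flag="undefined_control")
            )
        else:
            rows.append(
                dict(treatment=label, endpoint=endpoint, time_s=t,
                     value=value / control_value, flag="")
            )

    if plan.include_vehicle_control:
        for (endpoint, t), cv in control_vals.items():
            emit(VEHICLE_LABEL, endpoint, t, cv, cv)

    for treatment in plan.treatments:
        specs = [_resolve(i) for i in treatment.inhibitors]
        treated = base
        for spec in specs:
            s = strengths.get(spec.name, spec.strength)
            if s is None:
                s = calibrate_inhibitor(model, genotype, spec, settings=settings)
                strengths[spec.name] = s
            treated = apply_inhibitor(treated, spec, strength=s)
        ctx = SimulationContext(
            mek_inhibited=any(targets_mek(treated, s) for s in specs),
            erkpp_control=erkpp_control,
            metadata={"genotype": genotype.name, "treatment": treatment.label},
        )
        y0 = embed_state(base, eq.state, treated)
        res = simulate(treated, y0, t_end, settings, ctx, t_eval=plan.all_times())
        for moiety, endpoint in _protein_endpoints(treated):
            t = plan.protein_readout_time
            try:
                tv = phospho_ratio(treated, res, moiety, t)
            except ZeroDivisionError:
                tv = 0.0
            emit(treatment.label, endpoint, t, tv, control_vals[(endpoint, t)])
        for gene, endpoint in _mrna_endpoints(treated):
            sid = treated.promoter.genes[gene].mrna_species
            for t in plan.mrna_readout_times:
                emit(treatment.label, endpoint, t, res.value(sid, t),
                     control_vals[(endpoint, t)])

    return pd.DataFrame(rows, columns=READOUT_COLUMNS)


def simulate_actd(
    model: NetworkModel,
    genotype: Genotype,
    time_points: tuple[float, ...] = (7200.0, 14400.0, 21600.0),
    inhibitors: tuple = (),
    intermediary_gene_flag: bool = True,
    settings: SolverSettings | None = None,
    strengths: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Actinomycin-D chase: block transcription and follow pre-existing mRNA.

    From the genotype's baseline, mRNA synthesis is zeroed at t=0 and the
    remaining MYC/CCND1 mRNA at each time point is reported normalized to
    t=0.  With a MEK inhibitor co-applied, the CCND1 destabilization term
    is suppressed when ``intermediary_gene_flag`` is on (its action depends
    on transcription of an intermediary gene, which Act D blocks) and
    active when it is off.
    """
    settings = settings or SolverSettings()
    strengths = dict(strengths or {})
    if model.promoter is None:
        raise ValueError("Act D simulation needs a promoter-bearing model")

    base = apply_genotype(model, genotype)
    eq = equilibrate(base, initialize_state(base), settings)

    specs = [_resolve(i) for i in inhibitors]
    treated = base
    for spec in specs:
        s = strengths.get(spec.name, spec.strength)
        if s is None:
            s = calibrate_inhibitor(model, genotype, spec, settings=settings)
        treated = apply_inhibitor(treated, spec, strength=s)

    erkpp_control = None
    erk_active = base.annotations.get("readouts", {}).get("ERK", {}).get("active", [])
    if erk_active:
        state = dict(zip([s.id for s in base.species], eq.state))
        erkpp_control = sum(state.get(s, 0.0) for s in erk_active)

    ctx = SimulationContext(
        actd=True,
        actd_blocks_destabilization=intermediary_gene_flag,
        mek_inhibited=any(targets_mek(treated, s) for s in specs),
        erkpp_control=erkpp_control,
        metadata={"genotype": genotype.name, "treatment": "ActD"},
    )
    y0 = embed_state(base, eq.state, treated)
    t_end = max(time_points)
    res = simulate(treated, y0, t_end, settings, ctx, t_eval=time_points)

    label = "+".join(["ActD", *(s.name for s in specs)])
    rows = []
    for gene, params in treated.promoter.genes.items():
        m0 = res.value(params.mrna_species, 0.0)
        for t in (0.0, *time_points):
            if m0 == 0:
                rows.append(dict(treatment=label, endpoint=f"{gene}_mRNA",
                                 time_s=t, value=np.nan, flag="undefined_control"))
            else:
                rows.append(dict(treatment=label, endpoint=f"{gene}_mRNA", time_s=t,
                                 value=res.value(params.mrna_species, t) / m0, flag=""))
    return pd.DataFrame(rows, columns=READOUT_COLUMNS)
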