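"""Seeded generators: a reduced three-pathway MIM and pseudo-experimental data.

The toy MIM miniaturizes the network regions the package targets —
receptor-driven RAS/RAF/MEK/ERK with double ERK phosphorylation and an
ERK-to-RAF negative feedback, PI3K/AKT with PTEN, and the WNT arm with the
Axin:GSK3B:APC destruction complex — and wires the resulting TF forms
(beta-Catenin:TCF7L2, SMAD complexes, AP1/pAP1, TP53, E2F-DP1/RB) into the
five-site promoter driving MYC and CCND1.  Every rate and total lives in
``TOY_MANIFEST`` so the ground truth is inspectable; construction is
deterministic given the spec.

Pseudo-experimental tables emulate replicate wet measurements by
multiplying each simulated readout with lognormal noise of median 1 and a
stated coefficient of variation, matching the positivity and
log-transformability of qPCR/western data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import SolverSettings, equilibrate, initialize_state
from .network import (
    CatalyticReaction,
    NetworkModel,
    ReversibleReaction,
    SpeciesDecl,
)
from .perturb import (
    Genotype,
    InhibitorSpec,
    apply_genotype,
    apply_inhibitor,
    calibrate_inhibitor,
    embed_state,
)
from .promoter import GeneParams, KDEG_CCND1, KDEG_MYC, KSYNTH_DEFAULT, PromoterConfig, default_sites
from .experiment import TreatmentPlan, run_experiment
from .readout import phospho_fraction

__all__ = [
    "ToySpec",
    "TOY_MANIFEST",
    "make_toy_mim",
    "make_pseudo_experiments",
    "parameter_recovery_harness",
]


@dataclass
class ToySpec:
    seed: int = 0
    egf_mapk: bool = True
    pi3k_akt: bool = True
    wnt: bool = True
    include_feedback: bool = True
    noise_cv: float = 0.10
    n_replicates: int = 2  # biological duplicates

    def __post_init__(self) -> None:
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be > 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")


# The fixture manifest: every ground-truth number the generator uses.
# Kinase/phosphatase kcats are tuned so untreated steady states sit at
# ~30-60% pathway activation (room to move in both directions), and the
# RNAP weight so the untreated RNAP-occupancy probability is ~0.5
# (maximal dynamic range).
TOY_MANIFEST: dict = {
    "totals_nM": {
        "EGF": 100.0, "EGFR": 100.0, "KRAS": 120.0, "GAP": 50.0,
        "BRAF": 100.0, "PP1": 50.0, "MEK": 120.0, "PP2A": 50.0,
        "ERK": 100.0, "DUSP": 50.0, "AP1": 60.0, "PPA": 50.0,
        "PI3K": 100.0, "PTP": 50.0, "ERBB2": 40.0, "AKT": 40.0, "PTEN": 50.0,
        "AXIN": 50.0, "TNKS": 50.0, "GSK3B": 50.0, "APC": 50.0,
        "CTNNB1": 100.0, "PPB": 50.0, "TCF7L2": 50.0, "GROUCHO": 20.0,
        "ECAD": 30.0, "TGFBR2": 30.0, "SMAD2": 50.0, "PPS": 50.0,
        "SMAD4": 60.0, "TP53": 10.0, "E2F_DP1": 20.0, "RB": 15.0,
    },
    "rates": {
        "kon_bind": 1e-3, "koff_bind": 1e-2,  # generic Kd 10 nM binding
        "kon_tight": 1e-3, "koff_tight": 1e-2,  # destruction-complex assembly, Kd 10 nM
        "kcat_kinase": 1e-3, "kcat_phosphatase": 1e-3,
        # AP1 (de)phosphorylation is steep so transcription tracks ppERK
        "kcat_ap1_kinase": 2e-3, "kcat_ap1_phosphatase": 4e-3,
        "kcat_feedback": 5e-4,
        "kcat_pi3k_input": 5e-4,
        "kcat_axin_deg": 1e-3, "k_axin_recover": 1e-3,
        "kcat_dc": 4e-3,
    },
    "promoter": {
        "rnap_nM": 30.0,
        # tuned so z = [RNAP]*k_RNAP*F_reg ~ 1 at the physiologic baseline
        # (baseline F_reg ~ 22.3 with the wiring below)
        "k_rnap_per_nM": 0.00149,
        "slots": {
            # slot: (species, Kd nM, omega) — omega None for repressors
            "x1": ("CTNNB1.TCF7L2", 20.0, 8.0),
            "x2": ("SMAD4.TCF7L2", 20.0, 3.0),
            # pAP1 works in the low-occupancy/high-weight regime so the
            # site factor responds nearly linearly to ppERK changes
            "x3": ("AP1", 200.0, 2.0),
            "x3p": ("AP1_p", 85.0, 40.0),
            "x4": ("E2F_DP1", 10.0, 4.0),
            "y1": ("GROUCHO.TCF7L2", 10.0, None),
            "y2": ("SMAD2p.SMAD4", 10.0, None),
            "y4": ("TP53", 20.0, None),
            "y5": ("RB.E2F_DP1", 10.0, None),
        },
        "ksynth": KSYNTH_DEFAULT,
        "kdeg_MYC": KDEG_MYC,
        "kdeg_CCND1": KDEG_CCND1,
    },
}


def _toy_promoter(present: set[str]) -> PromoterConfig:
    pm = TOY_MANIFEST["promoter"]
    slots = {
        slot: (sid, kd, omega)
        for slot, (sid, kd, omega) in pm["slots"].items()
        if sid in present
    }
    return PromoterConfig(
        sites=default_sites(slots),
        rnap_concentration=pm["rnap_nM"],
        k_rnap=pm["k_rnap_per_nM"],
        genes={
            "MYC": GeneParams("MYC_mRNA", pm["ksynth"], pm["kdeg_MYC"]),
            "CCND1": GeneParams("CCND1_mRNA", pm["ksynth"], pm["kdeg_CCND1"]),
        },
    )


def make_toy_mim(spec: ToySpec | None = None) -> NetworkModel:
    """Build the reduced three-pathway MIM wired into the model promoter."""
    spec = spec or ToySpec()
    if not (spec.egf_mapk or spec.pi3k_akt or spec.wnt):
        raise ValueError("at least one pathway must be enabled")
    T = TOY_MANIFEST["totals_nM"]
    R = TOY_MANIFEST["rates"]

    species: list[SpeciesDecl] = []
    reversible: list[ReversibleReaction] = []
    catalytic: list[CatalyticReaction] = []

    def basic(mid: str):
        species.append(SpeciesDecl(mid, role="basic", initial_concentration=T[mid]))

    def modified(sid: str, moiety: str):
        species.append(SpeciesDecl(sid, role="modified", composition={moiety: 1}))

    def complex_(sid: str, *moieties: str):
        comp: dict[str, int] = {}
        for m in moieties:
            comp[m] = comp.get(m, 0) + 1
        species.append(SpeciesDecl(sid, role="complex", composition=comp))

    def bind(rid, a, b, ab, kon, koff):
        reversible.append(ReversibleReaction(rid, [a, b], [ab], kon=kon, koff=koff))

    def cat(rid, enzyme, substrate, product, kcat):
        catalytic.append(CatalyticReaction(rid, enzyme, substrate, product, kcat=kcat))

    kk = R["kcat_kinase"]
    kp = R["kcat_phosphatase"]

    if spec.egf_mapk:
        for m in ("EGF", "EGFR", "KRAS", "GAP", "BRAF", "PP1", "MEK", "PP2A",
                  "ERK", "DUSP", "AP1", "PPA"):
            basic(m)
        complex_("EGF.EGFR", "EGF", "EGFR")
        for sid, m in (("KRAS_GTP", "KRAS"), ("BRAF_p", "BRAF"), ("MEKPP", "MEK"),
                       ("ERK_P", "ERK"), ("ERKPP", "ERK"), ("AP1_p", "AP1")):
            modified(sid, m)
        bind("r_egf", "EGF", "EGFR", "EGF.EGFR", R["kon_bind"], R["koff_bind"])
        cat("c_ras_act", "EGF.EGFR", "KRAS", "KRAS_GTP", kk)
        cat("c_ras_gap", "GAP", "KRAS_GTP", "KRAS", kp)
        cat("c_raf_act", "KRAS_GTP", "BRAF", "BRAF_p", kk)
        cat("c_raf_pp", "PP1", "BRAF_p", "BRAF", kp)
        if spec.include_feedback:
            cat("c_raf_fb", "ERKPP", "BRAF_p", "BRAF", R["kcat_feedback"])
        cat("c_mek_act", "BRAF_p", "MEK", "MEKPP", kk)
        cat("c_mek_pp", "PP2A", "MEKPP", "MEK", kp)
        cat("c_erk_p1", "MEKPP", "ERK", "ERK_P", kk)
        cat("c_erk_p2", "MEKPP", "ERK_P", "ERKPP", kk)
        cat("c_erk_d2", "DUSP", "ERKPP", "ERK_P", kp)
        cat("c_erk_d1", "DUSP", "ERK_P", "ERK", kp)
        cat("c_ap1_act", "ERKPP", "AP1", "AP1_p", R["kcat_ap1_kinase"])
        cat("c_ap1_pp", "PPA", "AP1_p", "AP1", R["kcat_ap1_phosphatase"])

    if spec.pi3k_akt:
        for m in ("PI3K", "PTP", "ERBB2", "AKT", "PTEN"):
            basic(m)
        modified("PI3K_act", "PI3K")
        modified("AKTP", "AKT")
        if spec.egf_mapk:
            cat("c_pi3k_egfr", "EGF.EGFR", "PI3K", "PI3K_act", R["kcat_pi3k_input"])
        cat("c_pi3k_erbb2", "ERBB2", "PI3K", "PI3K_act", R["kcat_pi3k_input"])
        cat("c_pi3k_ptp", "PTP", "PI3K_act", "PI3K", kp)
        cat("c_akt_act", "PI3K_act", "AKT", "AKTP", kk)
        cat("c_akt_pten", "PTEN", "AKTP", "AKT", kk)

    if spec.wnt:
        for m in ("AXIN", "TNKS", "GSK3B", "APC", "CTNNB1", "PPB", "TCF7L2",
                  "GROUCHO", "ECAD"):
            basic(m)
        modified("AXIN_i", "AXIN")
        modified("CTNNB1_p", "CTNNB1")
        complex_("AXIN.GSK3B", "AXIN", "GSK3B")
        complex_("DC", "AXIN", "GSK3B", "APC")
        complex_("CTNNB1.TCF7L2", "CTNNB1", "TCF7L2")
        complex_("GROUCHO.TCF7L2", "GROUCHO", "TCF7L2")
        complex_("ECAD.CTNNB1", "ECAD", "CTNNB1")
        bind("r_axin_gsk", "AXIN", "GSK3B", "AXIN.GSK3B", R["kon_tight"], R["koff_tight"])
        bind("r_dc", "AXIN.GSK3B", "APC", "DC", R["kon_tight"], R["koff_tight"])
        # Tankyrase marks free Axin for degradation; slow spontaneous recovery
        cat("c_axin_deg", "TNKS", "AXIN", "AXIN_i", R["kcat_axin_deg"])
        reversible.append(
            ReversibleReaction("r_axin_rec", ["AXIN_i"], ["AXIN"],
                               kon=R["k_axin_recover"], koff=0.0)
        )
        cat("c_bcat_p", "DC", "CTNNB1", "CTNNB1_p", R["kcat_dc"])
        cat("c_bcat_rec", "PPB", "CTNNB1_p", "CTNNB1", kp)
        bind("r_bcat_tcf", "CTNNB1", "TCF7L2", "CTNNB1.TCF7L2",
             R["kon_bind"], R["koff_bind"])
        bind("r_groucho", "GROUCHO", "TCF7L2", "GROUCHO.TCF7L2",
             R["kon_bind"], R["koff_bind"])
        bind("r_ecad", "ECAD", "CTNNB1", "ECAD.CTNNB1", R["kon_bind"], R["koff_bind"])
        # TGFbeta/SMAD arm feeding the SMAD4 promoter site
        for m in ("TGFBR2", "SMAD2", "PPS", "SMAD4"):
            basic(m)
        modified("SMAD2_p", "SMAD2")
        complex_("SMAD2p.SMAD4", "SMAD2", "SMAD4")
        complex_("SMAD4.TCF7L2", "SMAD4", "TCF7L2")
        cat("c_smad2_act", "TGFBR2", "SMAD2", "SMAD2_p", kk)
        cat("c_smad2_pp", "PPS", "SMAD2_p", "SMAD2", kp)
        bind("r_smad24", "SMAD2_p", "SMAD4", "SMAD2p.SMAD4",
             R["kon_bind"], R["koff_bind"])
        bind("r_smad4_tcf", "SMAD4", "TCF7L2", "SMAD4.TCF7L2",
             R["kon_bind"], R["koff_bind"])

    # cell-cycle TF background (always present: promoter inputs)
    for m in ("TP53", "E2F_DP1", "RB"):
        basic(m)
    complex_("RB.E2F_DP1", "RB", "E2F_DP1")
    bind("r_rb", "RB", "E2F_DP1", "RB.E2F_DP1", R["kon_bind"], R["koff_bind"])

    species.append(SpeciesDecl("MYC_mRNA", role="mRNA", composition={}))
    species.append(SpeciesDecl("CCND1_mRNA", role="mRNA", composition={}))

    annotations = {
        "seed": spec.seed,
        "readouts": {},
        "active_forms": {},
        "mrna": {"MYC": "MYC_mRNA", "CCND1": "CCND1_mRNA"},
        "manifest": {
            "n_reversible": len(reversible),
            "n_catalytic": len(catalytic),
            "n_processes": 2 * len(reversible) + len(catalytic),
        },
    }
    if spec.egf_mapk:
        annotations["readouts"]["ERK"] = {"active": ["ERKPP"]}
        annotations["active_forms"].update(
            {"KRAS": "KRAS_GTP", "BRAF": "BRAF_p", "MEK": "MEKPP",
             "ERK": "ERKPP", "AP1": "AP1_p"}
        )
    if spec.pi3k_akt:
        annotations["readouts"]["AKT"] = {"active": ["AKTP"]}
        annotations["active_forms"].update({"PI3K": "PI3K_act", "AKT": "AKTP"})
    if spec.wnt:
        annotations["active_forms"].update({"CTNNB1": "CTNNB1", "SMAD2": "SMAD2_p"})

    model = NetworkModel(
        species=species, reversible=reversible, catalytic=catalytic,
        annotations=annotations,
    )
    present = set(model.species_by_id())
    model.promoter = _toy_promoter(present)
    return model.validate()


def make_pseudo_experiments(
    model: NetworkModel,
    genotype: Genotype,
    plan: TreatmentPlan,
    spec: ToySpec | None = None,
    settings: SolverSettings | None = None,
    strengths: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Replicate wet-style readout table: simulated truth x lognormal noise.

    Noise is multiplicative with median 1 and coefficient of variation
    ``spec.noise_cv``; ``spec.n_replicates`` rows are emitted per
    treatment x endpoint x time.  Vehicle rows stay exactly 1 (they are the
    normalization reference).  Reproducible given ``spec.seed``.
    """
    spec = spec or ToySpec()
    truth = run_experiment(model, genotype, plan, settings=settings, strengths=strengths)
    rng = np.random.default_rng(spec.seed)
    sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
    rows = []
    for _, row in truth.iterrows():
        for rep in range(1, spec.n_replicates + 1):
            value = row["value"]
            if row["treatment"] != "vehicle" and np.isfinite(value):
                value = value * float(np.exp(rng.normal(0.0, sigma)))
            rows.append(
                dict(treatment=row["treatment"], endpoint=row["endpoint"],
                     time_s=row["time_s"], replicate=rep, value=value)
            )
    return pd.DataFrame(rows, columns=["treatment", "endpoint", "time_s", "replicate", "value"])


def parameter_recovery_harness(
    model: NetworkModel,
    genotype: Genotype,
    spec: InhibitorSpec,
    f_true: tuple[float, ...] = (0.0, 0.4, 0.7, 0.8),
    readout: str | None = None,
    readout_time: float = 1800.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    settings: SolverSettings | None = None,
) -> pd.DataFrame:
    """Round-trip check for inhibitor calibration.

    For each true strength: apply the inhibitor, measure the achieved
    fractional inhibition of the readout (optionally perturbed with
    lognormal noise of the given CV), recover the strength that reproduces
    that measurement via calibration, and report the absolute error.
    """
    from .engine import simulate

    settings = settings or SolverSettings()
    moiety = readout or spec.readout
    if moiety is None:
        raise ValueError("need a readout moiety")
    rng = np.random.default_rng(seed)

    base = apply_genotype(model, genotype)
    eq = equilibrate(base, initialize_state(base), settings)
    names = [s.id for s in base.species]
    control = phospho_fraction(base, dict(zip(names, eq.state)), moiety)

    rows = []
    for f in f_true:
        if f == 0.0:
            rows.append(dict(f_true=0.0, achieved=0.0, recovered=0.0, abs_error=0.0))
            continue
        treated = apply_inhibitor(base, spec, strength=f)
        y0 = embed_state(base, eq.state, treated)
        res = simulate(treated, y0, readout_time, settings, t_eval=[readout_time])
        ratio = phospho_fraction(treated, res.state_at(readout_time), moiety) / control
        achieved = 1.0 - ratio
        measured = achieved
        if noise_cv > 0:
            sigma = float(np.sqrt(np.log1p(noise_cv**2)))
            measured = 1.0 - ratio * float(np.exp(rng.normal(0.0, sigma)))
            measured = min(max(measured, 0.0), 1.0 - 1e-6)
        recovered = calibrate_inhibitor(
            model, genotype, spec, desired_fraction=measured,
            readout=moiety, readout_time=readout_time, settings=settings,
        )
        rows.append(dict(f_true=f, achieved=achieved, recovered=recovered,
                         abs_error=abs(recovered - f)))
    return pd.DataFrame(rows)
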