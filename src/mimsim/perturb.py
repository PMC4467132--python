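"""Virtual genotypes (mutations/alterations) and virtual inhibitors.

Mutations are model transformations applied before any integration:

* ``constitutive_activation`` — every inactivation (dephosphorylation)
  process acting on the protein's active form is zeroed, so the active
  form accumulates irrespective of upstream signal; this is the in-silico
  analogue of an oncogenic auto-activating mutation and preserves moiety
  conservation (nothing is clamped).
* ``null`` / ``partial_loss`` / ``overexpression`` — the moiety's total
  pool is zeroed or rescaled.

Inhibitors are either ``activity_scaling`` (the target enzyme's catalytic
rate constants are multiplied by ``1 - f``) or ``competitive_binding`` (an
inhibitor species at a fixed concentration reversibly sequesters the
target).  Bundled presets carry the inhibition levels at which each
compound was characterised; :func:`calibrate_inhibitor` finds, by root
bracketing on a monotone dose-response, the mechanistic strength (f or Ki)
that reproduces a desired fractional inhibition of a normalized phospho
readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .engine import SimulationContext, SolverSettings, equilibrate, initialize_state, simulate
from .network import (
    ModelValidationError,
    NetworkModel,
    ReversibleReaction,
    SpeciesDecl,
)
from .readout import phospho_fraction

__all__ = [
    "MutationDirective",
    "Genotype",
    "InhibitorSpec",
    "PRESET_GENOTYPES",
    "PRESET_INHIBITORS",
    "CalibrationError",
    "apply_genotype",
    "apply_inhibitor",
    "calibrate_inhibitor",
    "scale_factors",
    "embed_state",
]

KON_BINDING = 1e-3  # 1/(nM*s), association rate for sequestration reactions


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MutationDirective:
    target: str  # moiety id
    mode: Literal["constitutive_activation", "null", "partial_loss", "overexpression"]
    fraction: float | None = None  # partial_loss, in (0,1)
    fold: float | None = None  # overexpression, > 1

    def __post_init__(self) -> None:
        if self.mode == "partial_loss":
            if self.fraction is None or not (0 < self.fraction < 1):
                raise ValueError(f"{self.target}: partial_loss fraction must be in (0,1)")
        elif self.mode == "overexpression":
            if self.fold is None or self.fold <= 1:
                raise ValueError(f"{self.target}: overexpression fold must be > 1")
        elif self.mode not in ("constitutive_activation", "null"):
            raise ValueError(f"{self.target}: unknown mutation mode {self.mode!r}")

    def key(self) -> str:
        extra = self.fraction if self.mode == "partial_loss" else (
            self.fold if self.mode == "overexpression" else ""
        )
        return f"{self.mode}:{self.target}:{extra}"


@dataclass(frozen=True)
class Genotype:
    name: str
    directives: tuple[MutationDirective, ...] = ()

    def __iter__(self):
        return iter(self.directives)


PRESET_GENOTYPES: dict[str, Genotype] = {
    "physiologic": Genotype("physiologic", ()),
    "HCT116": Genotype(
        "HCT116",
        (
            MutationDirective("KRAS", "constitutive_activation"),
            MutationDirective("CTNNB1", "constitutive_activation"),
            MutationDirective("PI3K", "constitutive_activation"),
            MutationDirective("PTEN", "partial_loss", fraction=0.6),
            MutationDirective("ECAD", "null"),
            MutationDirective("TGFBR2", "null"),
        ),
    ),
    "HT29": Genotype(
        "HT29",
        (
            MutationDirective("BRAF", "constitutive_activation"),
            MutationDirective("PI3K", "constitutive_activation"),
            MutationDirective("APC", "null"),
            MutationDirective("SMAD4", "null"),
            MutationDirective("ERBB2", "overexpression", fold=2.0),
        ),
    ),
}


@dataclass
class InhibitorSpec:
    """A virtual inhibitor.

    ``level`` is the fractional inhibition of the normalized readout the
    compound is documented to achieve (a calibration target); ``strength``
    is the mechanistic parameter actually applied (f for activity_scaling,
    Ki in nM for competitive_binding).  ``concentration`` (nM) is the fixed
    dose of a competitive binder.
    """

    name: str
    target: str  # species id or moiety id
    mechanism: Literal["activity_scaling", "competitive_binding"] = "activity_scaling"
    level: float | None = None
    strength: float | None = None
    concentration: float | None = None
    readout: str | None = None  # moiety whose phospho fraction the level refers to

    def __post_init__(self) -> None:
        if self.mechanism not in ("activity_scaling", "competitive_binding"):
            raise ValueError(f"{self.name}: unknown mechanism {self.mechanism!r}")
        if self.mechanism == "activity_scaling" and self.strength is not None:
            if not (0 <= self.strength < 1):
                raise ValueError(f"{self.name}: inhibition fraction must be in [0,1)")
        if self.mechanism == "competitive_binding":
            if self.concentration is None or self.concentration <= 0:
                raise ValueError(f"{self.name}: competitive binder needs a dose (nM)")
        if self.level is not None and not (0 <= self.level < 1):
            raise ValueError(f"{self.name}: level must be in [0,1)")


PRESET_INHIBITORS: dict[str, InhibitorSpec] = {
    # MEK inhibitor, characterised at 80% ppERK/ERK inhibition
    "CI1040": InhibitorSpec(
        "CI1040", target="MEKPP", mechanism="activity_scaling",
        level=0.80, readout="ERK",
    ),
    # PI3K inhibitor (no documented fractional level; fixed strength)
    "PI103": InhibitorSpec(
        "PI103", target="PI3K_act", mechanism="activity_scaling",
        strength=0.90, readout="AKT",
    ),
    # AKT inhibitor at its two characterised doses / inhibition levels
    "Perifosine_20nM": InhibitorSpec(
        "Perifosine_20nM", target="AKTP", mechanism="competitive_binding",
        concentration=20.0, level=0.40, readout="AKT",
    ),
    "Perifosine_40nM": InhibitorSpec(
        "Perifosine_40nM", target="AKTP", mechanism="competitive_binding",
        concentration=40.0, level=0.70, readout="AKT",
    ),
    # Tankyrase inhibitor: blocks Axin inactivation, raising the
    # destruction complex and promoting beta-Catenin turnover
    "XAV939": InhibitorSpec(
        "XAV939", target="TNKS", mechanism="activity_scaling", strength=0.90,
    ),
    # GSK3beta inhibitor: acts on every enzyme form containing GSK3B
    "Azakenpaullone": InhibitorSpec(
        "Azakenpaullone", target="GSK3B", mechanism="activity_scaling", strength=0.90,
    ),
}


# ---------------------------------------------------------------------------
# genotypes


def scale_factors(model: NetworkModel, genotype: Genotype) -> dict[str, float]:
    """Multiplicative factor on each moiety total implied by the genotype."""
    factors: dict[str, float] = {}
    for d in genotype:
        if d.mode == "null":
            factors[d.target] = 0.0
        elif d.mode == "partial_loss":
            factors[d.target] = factors.get(d.target, 1.0) * d.fraction
        elif d.mode == "overexpression":
            factors[d.target] = factors.get(d.target, 1.0) * d.fold
    return factors


def _inactivation_reactions(model: NetworkModel, moiety: str) -> list:
    active_forms = model.annotations.get("active_forms", {})
    if moiety not in active_forms:
        raise KeyError(
            f"constitutive activation of {moiety!r} needs an active_forms annotation"
        )
    active = active_forms[moiety]
    return [c for c in model.catalytic if c.substrate == active]


def apply_genotype(model: NetworkModel, genotype: Genotype) -> NetworkModel:
    """Return a copy of the model with the genotype's directives applied.

    Applying the same genotype twice is a no-op the second time: each
    directive records itself in the model annotations and already-recorded
    directives are skipped, so concentration rescalings do not compound.
    """
    out = model.copy()
    applied: list[str] = list(out.annotations.get("applied_directives", []))
    moieties = set(out.moiety_ids())
    for d in genotype:
        if d.key() in applied:
            continue
        if d.target not in moieties:
            raise KeyError(f"genotype directive targets unknown moiety {d.target!r}")
        if d.mode == "constitutive_activation":
            hits = _inactivation_reactions(out, d.target)
            if not hits:
                raise ModelValidationError(
                    f"constitutive activation of {d.target!r}: no inactivation "
                    "process acts on its active form"
                )
            for c in hits:
                c.kcat = 0.0
        else:
            factor = {"null": 0.0, "partial_loss": d.fraction, "overexpression": d.fold}[d.mode]
            for s in out.species:
                if d.target in s.composition:
                    s.initial_concentration *= factor
        applied.append(d.key())
    out.annotations["applied_directives"] = applied
    out.annotations["genotype"] = genotype.name
    return out.validate()


# ---------------------------------------------------------------------------
# inhibitors


def _scaled_reactions(model: NetworkModel, target: str) -> list:
    by_id = model.species_by_id()
    hits = []
    for c in model.catalytic:
        enzyme = by_id[c.enzyme]
        if c.enzyme == target or target in enzyme.composition:
            hits.append(c)
    return hits


def apply_inhibitor(
    model: NetworkModel,
    spec: InhibitorSpec,
    strength: float | None = None,
) -> NetworkModel:
    """Return a copy of the model with the inhibitor applied.

    ``strength`` overrides ``spec.strength`` (e.g. a calibrated value).
    activity_scaling multiplies the catalytic rate constants of every
    reaction whose enzyme is the target species — or whose enzyme contains
    the target moiety — by ``1 - f``; f = 0 is the identity transform.
    competitive_binding adds the inhibitor species at its dose and a
    reversible sequestration reaction with Ki = strength (nM).
    """
    s = spec.strength if strength is None else strength
    if s is None:
        raise CalibrationError(
            f"{spec.name}: no strength set; pass one or run calibrate_inhibitor"
        )
    out = model.copy()
    known = set(out.species_by_id()) | set(out.moiety_ids())
    if spec.target not in known:
        raise KeyError(f"inhibitor {spec.name}: unknown target {spec.target!r}")

    if spec.mechanism == "activity_scaling":
        if not (0 <= s < 1):
            raise ValueError(f"{spec.name}: inhibition fraction must be in [0,1)")
        hits = _scaled_reactions(out, spec.target)
        if not hits:
            raise ModelValidationError(
                f"inhibitor {spec.name}: target {spec.target!r} catalyzes nothing"
            )
        for c in hits:
            c.kcat *= 1.0 - s
    else:
        if s <= 0:
            raise ValueError(f"{spec.name}: Ki must be > 0")
        if spec.target not in out.species_by_id():
            raise KeyError(
                f"inhibitor {spec.name}: competitive binding needs a species target"
            )
        target = out.species_by_id()[spec.target]
        comp = dict(target.composition)
        comp[spec.name] = comp.get(spec.name, 0) + 1
        out.species.append(
            SpeciesDecl(
                id=spec.name, name=spec.name, role="inhibitor",
                composition={spec.name: 1},
                initial_concentration=float(spec.concentration),
            )
        )
        out.species.append(
            SpeciesDecl(
                id=f"{spec.target}.{spec.name}", name=f"{spec.target}:{spec.name}",
                role="complex", composition=comp, initial_concentration=0.0,
            )
        )
        out.reversible.append(
            ReversibleReaction(
                id=f"bind_{spec.name}",
                reactants=[spec.target, spec.name],
                products=[f"{spec.target}.{spec.name}"],
                kon=KON_BINDING,
                koff=KON_BINDING * s,
            )
        )
    applied = sorted(set(out.annotations.get("applied_inhibitors", [])) | {spec.name})
    out.annotations["applied_inhibitors"] = applied
    return out.validate()


def targets_mek(model: NetworkModel, spec: InhibitorSpec) -> bool:
    """Whether an inhibitor acts on the MEK moiety (engages CCND1 destabilization)."""
    by_id = model.species_by_id()
    if spec.target == "MEK":
        return True
    sp = by_id.get(spec.target)
    return sp is not None and "MEK" in sp.composition


def embed_state(
    base_model: NetworkModel,
    base_state: np.ndarray,
    target_model: NetworkModel,
) -> np.ndarray:
    """Carry a state over to a model with extra species (e.g. added inhibitors).

    Species shared with the base model keep their concentrations; new
    species start at their declared initial concentrations.
    """
    base_idx = base_model.species_index()
    y = np.zeros(len(target_model.species))
    for i, s in enumerate(target_model.species):
        if s.id in base_idx:
            y[i] = base_state[base_idx[s.id]]
        else:
            y[i] = s.initial_concentration
    return y


def calibrate_inhibitor(
    model: NetworkModel,
    genotype: Genotype,
    spec: InhibitorSpec,
    desired_fraction: float | None = None,
    readout: str | None = None,
    readout_time: float = 1800.0,
    settings: SolverSettings | None = None,
    tol: float = 1e-4,
) -> float:
    """Find the mechanistic strength reproducing a desired readout inhibition.

    Simulates the treated model for ``readout_time`` seconds from the
    genotype's quasi-stationary baseline and compares the phospho fraction
    of the readout moiety to the untreated control at the same time; the
    returned strength achieves ``1 - treated/control = desired_fraction``
    within ``tol`` by Brent root bracketing (the dose-response is checked
    to bracket the target, otherwise CalibrationError).
    """
    desired = spec.level if desired_fraction is None else desired_fraction
    if desired is None:
        raise CalibrationError(f"{spec.name}: no desired inhibition level given")
    if desired == 0:
        return 0.0
    moiety = readout or spec.readout
    if moiety is None:
        raise CalibrationError(f"{spec.name}: no readout moiety given")
    settings = settings or SolverSettings()

    base = apply_genotype(model, genotype)
    eq = equilibrate(base, initialize_state(base), settings)
    control = phospho_fraction(base, dict(zip([s.id for s in base.species], eq.state)), moiety)
    if control <= 0:
        raise CalibrationError(
            f"{spec.name}: control {moiety} readout is zero; nothing to inhibit"
        )

    def achieved(strength: float) -> float:
        treated_model = apply_inhibitor(base, spec, strength=strength)
        y0 = embed_state(base, eq.state, treated_model)
        res = simulate(treated_model, y0, readout_time, settings,
                       t_eval=[readout_time])
        state = res.state_at(readout_time)
        return 1.0 - phospho_fraction(treated_model, state, moiety) / control

    if spec.mechanism == "activity_scaling":
        lo, hi = 0.0, 1.0 - 1e-9
        top = achieved(hi)
        if top < desired:
            raise CalibrationError(
                f"{spec.name}: readout insensitive to target — maximum achievable "
                f"inhibition {top:.3f} < desired {desired:.3f}"
            )
        return float(brentq(lambda f: achieved(f) - desired, lo, hi, xtol=tol / 10))

    # competitive binding: bracket on log10(Ki)
    lo_l, hi_l = -6.0, 6.0
    top = achieved(10.0 ** lo_l)
    bottom = achieved(10.0 ** hi_l)
    if not (bottom < desired < top):
        raise CalibrationError(
            f"{spec.name}: desired inhibition {desired:.3f} outside the reachable "
            f"range [{bottom:.3f}, {top:.3f}] at dose {spec.concentration} nM"
        )
    log_ki = brentq(lambda L: achieved(10.0 ** L) - desired, lo_l, hi_l, xtol=1e-4)
    return float(10.0 ** log_ki)
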