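"""Statistical-thermodynamic transcription-rate function for MYC and CCND1.

The promoter is abstracted as five transcription-factor binding sites
(TCF7L2, SMAD4, AP1, TP53, E2F-DP1), each bound competitively by activator
and repressor TF forms drawn from the signaling network.  Site occupancy is
treated in the thermodynamic (quasi-equilibrium) limit:

    F_site = (1 + sum_a w_a [a]/Kd_a)
             / (1 + sum_a [a]/Kd_a + sum_r [r]/Kd_r)

with activation weights w_a >= 1 for activators and plain competitive
occupancy for repressors; an empty site contributes F = 1.  Sites are
statistically independent, so the promoter regulation factor is the product
of the five site factors, and the probability that RNA polymerase (RNAP)
occupies the promoter is

    P(RNAP bound) = z / (1 + z),     z = [RNAP] * k_RNAP * F_reg

mRNA then follows d(mRNA)/dt = ksynth * P - kdeg * mRNA.  MYC and CCND1
share one promoter architecture and synthesis constant and differ only in
their degradation constants (fast MYC, slow CCND1).  Under MEK inhibition
the CCND1 degradation constant is additionally scaled by the ratio of
control to inhibited doubly-phosphorylated ERK, which empirically captures
the destabilization of pre-existing CCND1 mRNA observed with MEK
inhibitors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

__all__ = [
    "TFBinding",
    "TFBSConfig",
    "GeneParams",
    "PromoterConfig",
    "SITE_NAMES",
    "KSYNTH_DEFAULT",
    "KDEG_MYC",
    "KDEG_CCND1",
    "site_regulation_factor",
    "promoter_regulation_factor",
    "p_rnap_bound",
    "mrna_rate",
    "mrna_half_life",
    "ccnd1_kdeg_modifier",
]

SITE_NAMES = (
    "TFBS_TCF7L2",
    "TFBS_SMAD4",
    "TFBS_AP1",
    "TFBS_TP53",
    "TFBS_E2F-DP1",
)

# per-gene defaults: shared synthesis constant, measured degradation constants
KSYNTH_DEFAULT = 5e-5  # 1/s
KDEG_MYC = 2.7e-4  # 1/s  (half-life ~43 min)
KDEG_CCND1 = 5.7e-6  # 1/s  (half-life ~34 h)


@dataclass
class TFBinding:
    """One TF form competing for a binding site.

    ``omega`` is the activation weight (fold increase of the RNAP weight
    when this activator occupies the site); repressors have none.
    """

    species_id: str
    Kd: float
    mode: Literal["activator", "repressor"] = "activator"
    omega: float | None = None

    def __post_init__(self) -> None:
        if self.Kd <= 0:
            raise ValueError(f"TF {self.species_id!r}: Kd must be > 0")
        if self.mode == "activator":
            if self.omega is None:
                self.omega = 1.0
            if self.omega < 1:
                raise ValueError(f"TF {self.species_id!r}: omega must be >= 1")
        elif self.mode == "repressor":
            if self.omega is not None:
                raise ValueError(f"TF {self.species_id!r}: repressors carry no omega")
        else:
            raise ValueError(f"TF {self.species_id!r}: unknown mode {self.mode!r}")


@dataclass
class TFBSConfig:
    site_name: str
    bindings: list[TFBinding] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.site_name not in SITE_NAMES:
            raise ValueError(f"unknown TFBS {self.site_name!r}; expected one of {SITE_NAMES}")


@dataclass
class GeneParams:
    mrna_species: str
    ksynth: float = KSYNTH_DEFAULT
    kdeg: float = KDEG_MYC

    def __post_init__(self) -> None:
        if self.ksynth < 0 or self.kdeg <= 0:
            raise ValueError("ksynth must be >= 0 and kdeg > 0")


@dataclass
class PromoterConfig:
    """Five TFBS configurations plus RNAP terms and per-gene constants.

    ``k_rnap`` multiplies [RNAP] directly (association-constant convention,
    units 1/nM); set ``k_rnap_is_kd`` to interpret the same number as a
    dissociation constant instead (z = [RNAP]/k * F).
    """

    sites: list[TFBSConfig]
    rnap_concentration: float = 30.0  # nM
    k_rnap: float = 1.0 / 30.0  # 1/nM
    k_rnap_is_kd: bool = False
    genes: dict[str, GeneParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.site_name for s in self.sites]
        if sorted(names) != sorted(SITE_NAMES):
            raise ValueError(
                f"promoter must configure each of {SITE_NAMES} exactly once, got {names}"
            )
        if self.rnap_concentration <= 0 or self.k_rnap <= 0:
            raise ValueError("rnap_concentration and k_rnap must be > 0")

    def rnap_weight(self) -> float:
        """[RNAP]*k_RNAP under the configured convention."""
        if self.k_rnap_is_kd:
            return self.rnap_concentration / self.k_rnap
        return self.rnap_concentration * self.k_rnap

    def tf_species(self) -> list[str]:
        return [b.species_id for s in self.sites for b in s.bindings]


def default_sites(
    slots: Mapping[str, tuple[str, float, float | None]],
) -> list[TFBSConfig]:
    """Build the canonical five-site wiring from slot assignments.

    ``slots`` maps slot names (x1, x1p, x2, x3, x3p, x4 activators; y1..y5
    repressors) to ``(species_id, Kd, omega)`` tuples (omega ignored for
    repressors).  Unassigned slots are simply absent — a TF form the network
    does not produce contributes nothing.  Slot-to-site layout: TCF7L2 site
    {x1, x1p | y1}, SMAD4 site {x2 | y2, y3}, AP1 site {x3, x3p | -},
    TP53 site {- | y4}, E2F-DP1 site {x4 | y5}.
    """
    layout = {
        "TFBS_TCF7L2": (("x1", "x1p"), ("y1",)),
        "TFBS_SMAD4": (("x2",), ("y2", "y3")),
        "TFBS_AP1": (("x3", "x3p"), ()),
        "TFBS_TP53": ((), ("y4",)),
        "TFBS_E2F-DP1": (("x4",), ("y5",)),
    }
    sites = []
    for site_name, (act_slots, rep_slots) in layout.items():
        bindings = []
        for slot in act_slots:
            if slot in slots:
                sid, kd, omega = slots[slot]
                bindings.append(TFBinding(sid, kd, "activator", omega or 1.0))
        for slot in rep_slots:
            if slot in slots:
                sid, kd, _ = slots[slot]
                bindings.append(TFBinding(sid, kd, "repressor"))
        sites.append(TFBSConfig(site_name, bindings))
    return sites


# ---------------------------------------------------------------------------
# operations


def site_regulation_factor(site: TFBSConfig, state: Mapping[str, float]) -> float:
    """Regulation factor of one TFBS given TF concentrations (nM)."""
    act_w = 0.0
    act = 0.0
    rep = 0.0
    for b in site.bindings:
        try:
            conc = float(state[b.species_id])
        except KeyError:
            raise KeyError(
                f"site {site.site_name}: species {b.species_id!r} absent from state"
            ) from None
        if conc < 0:
            raise ValueError(
                f"site {site.site_name}: negative concentration for {b.species_id!r}"
            )
        occ = conc / b.Kd
        if b.mode == "activator":
            act += occ
            act_w += b.omega * occ
        else:
            rep += occ
    return (1.0 + act_w) / (1.0 + act + rep)


def promoter_regulation_factor(config: PromoterConfig, state: Mapping[str, float]) -> float:
    """F_reg: product of the five site factors (independent-sites assumption)."""
    f = 1.0
    for site in config.sites:
        f *= site_regulation_factor(site, state)
    return f


def p_rnap_bound(f_reg: float, config: PromoterConfig) -> float:
    """Probability that RNAP occupies the promoter: z/(1+z), z = [RNAP]*k_RNAP*F_reg."""
    if f_reg < 0:
        raise ValueError("F_reg must be >= 0")
    z = config.rnap_weight() * f_reg
    return z / (1.0 + z)


def mrna_rate(
    gene: GeneParams,
    p_bound: float,
    mrna_level: float,
    kdeg_effective: float | None = None,
) -> float:
    """d(mRNA)/dt = ksynth * P(RNAP bound) - kdeg_eff * mRNA."""
    kdeg = gene.kdeg if kdeg_effective is None else kdeg_effective
    return gene.ksynth * p_bound - kdeg * mrna_level


def mrna_half_life(kdeg: float) -> float:
    """Half-life in hours for first-order decay at rate kdeg (1/s)."""
    if kdeg <= 0:
        raise ValueError("kdeg must be > 0")
    return math.log(2.0) / kdeg / 3600.0


def ccnd1_kdeg_modifier(
    kdeg_control: float,
    erkpp_control: float,
    erkpp_treated: float,
    floor_fraction: float = 1e-6,
) -> float:
    """Effective CCND1 degradation constant under MEK inhibition.

    kdeg_eff = kdeg_control * (ERKPP_control / ERKPP_treated): the more
    completely ppERK is suppressed, the faster pre-existing CCND1 mRNA is
    degraded.  Ratio 1 (no inhibitor effect) leaves kdeg unchanged.  The
    treated level is floored at ``floor_fraction * erkpp_control`` (with a
    warning) so near-total ERK inhibition cannot produce an unbounded rate.
    """
    if kdeg_control <= 0:
        raise ValueError("kdeg_control must be > 0")
    if erkpp_control < 0 or erkpp_treated < 0:
        raise ValueError("ERKPP levels must be >= 0")
    floor = floor_fraction * erkpp_control
    if erkpp_treated < floor:
        warnings.warn(
            "ERKPP under MEK inhibition below floor "
            f"({erkpp_treated:.3g} < {floor:.3g} nM); capping the CCND1 "
            "degradation modifier (near-total ERK inhibition)",
            RuntimeWarning,
            stacklevel=2,
        )
        erkpp_treated = floor
    if erkpp_treated == 0.0:
        # control is exactly 0 too: no signal, no modification
        return kdeg_control
    return kdeg_control * (erkpp_control / erkpp_treated)
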