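"""Small hand-built models and closed-form oracles shared across tests."""

from __future__ import annotations

import math

from mimsim import (
    CatalyticReaction,
    NetworkModel,
    ReversibleReaction,
    SpeciesDecl,
)


def binding_model(a_tot=100.0, b_tot=100.0, kon=1e-3, koff=1e-2) -> NetworkModel:
    """A + B <=> AB, the minimal closed reversible system."""
    return NetworkModel(
        species=[
            SpeciesDecl("A", role="basic", initial_concentration=a_tot),
            SpeciesDecl("B", role="basic", initial_concentration=b_tot),
            SpeciesDecl("AB", role="complex", composition={"A": 1, "B": 1}),
        ],
        reversible=[ReversibleReaction("r1", ["A", "B"], ["AB"], kon=kon, koff=koff)],
    ).validate()


def binding_equilibrium_closed_form(a_tot: float, b_tot: float, kd: float) -> float:
    """Equilibrium [AB] from the bimolecular binding quadratic."""
    s = a_tot + b_tot + kd
    return (s - math.sqrt(s * s - 4.0 * a_tot * b_tot)) / 2.0


def phospho_cycle_model(
    s_tot=100.0, kin_tot=10.0, pho_tot=10.0, kcat_kin=1e-3, kcat_pho=2e-3
) -> NetworkModel:
    """Kinase/phosphatase cycle on one substrate (mass action both ways)."""
    return NetworkModel(
        species=[
            SpeciesDecl("S", role="basic", initial_concentration=s_tot),
            SpeciesDecl("Sp", role="modified", composition={"S": 1}),
            SpeciesDecl("KIN", role="basic", initial_concentration=kin_tot),
            SpeciesDecl("PHO", role="basic", initial_concentration=pho_tot),
        ],
        catalytic=[
            CatalyticReaction("k", "KIN", "S", "Sp", kcat=kcat_kin),
            CatalyticReaction("p", "PHO", "Sp", "S", kcat=kcat_pho),
        ],
        annotations={"readouts": {"S": {"active": ["Sp"]}}},
    ).validate()


def phospho_cycle_fraction(kin_tot, pho_tot, kcat_kin, kcat_pho) -> float:
    """Steady-state phospho fraction of the linear kinase/phosphatase cycle."""
    a = kcat_kin * kin_tot
    b = kcat_pho * pho_tot
    return a / (a + b)
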