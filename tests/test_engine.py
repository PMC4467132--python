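import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

import mimsim
from mimsim import (
    CatalyticReaction,
    NetworkModel,
    SolverSettings,
    SpeciesDecl,
    build_rhs,
    equilibrate,
    initialize_state,
    load_model,
    moiety_totals,
    simulate,
    write_model,
)
from mimsim.perturb import Genotype, MutationDirective

from _helpers import (
    binding_equilibrium_closed_form,
    binding_model,
    phospho_cycle_fraction,
    phospho_cycle_model,
)


# -- right-hand side ---------------------------------------------------------

def test_rhs_reversible_direct_substitution():
    m = binding_model(a_tot=10.0, b_tot=10.0, kon=1e-3, koff=1e-2)
    rhs = build_rhs(m)
    dy = rhs(0.0, np.array([10.0, 10.0, 0.0]))
    assert dy[2] == pytest.approx(0.1)  # kon*A*B - koff*AB = 1e-3*100
    assert dy[0] == pytest.approx(-0.1) and dy[1] == pytest.approx(-0.1)


def test_rhs_mass_action_catalysis():
    m = phospho_cycle_model(s_tot=10.0, kin_tot=10.0, pho_tot=0.0, kcat_kin=1e-3)
    rhs = build_rhs(m)
    dy = rhs(0.0, np.array([10.0, 0.0, 10.0, 0.0]))
    assert dy[1] == pytest.approx(0.1)  # kcat*[E]*[S]


def test_rhs_michaelis_menten_saturates_at_kcat_e():
    m = NetworkModel(
        species=[
            SpeciesDecl("E", role="basic", initial_concentration=2.0),
            SpeciesDecl("S", role="basic", initial_concentration=1e6),
            SpeciesDecl("Sp", role="modified", composition={"S": 1}),
        ],
        catalytic=[CatalyticReaction("c", "E", "S", "Sp", kcat=3.0,
                                     law="michaelis_menten", Km=5.0)],
    ).validate()
    rhs = build_rhs(m)
    dy = rhs(0.0, np.array([2.0, 1e6, 0.0]))
    assert dy[2] == pytest.approx(3.0 * 2.0, rel=1e-4)  # v -> kcat*[E]


def test_zero_rate_model_has_constant_trajectory():
    m = binding_model(kon=0.0, koff=0.0)
    res = simulate(m, initialize_state(m), 1000.0)
    assert np.allclose(res.concentrations, res.concentrations[0], atol=1e-12)


# -- equilibration -----------------------------------------------------------

def test_binding_equilibrium_matches_quadratic_closed_form():
    m = binding_model(a_tot=100.0, b_tot=100.0, kon=1e-3, koff=1e-2)  # Kd 10
    eq = equilibrate(m, initialize_state(m))
    expected = binding_equilibrium_closed_form(100.0, 100.0, 10.0)
    assert expected == pytest.approx(72.98, abs=0.005)
    assert eq.converged
    assert eq.state[2] == pytest.approx(expected, rel=1e-6)


@hsettings(max_examples=15, deadline=None)
@given(
    a_tot=st.floats(1.0, 500.0),
    b_tot=st.floats(1.0, 500.0),
    kd=st.floats(0.1, 1000.0),
)
def test_binding_equilibrium_closed_form_randomized(a_tot, b_tot, kd):
    kon = 1e-3
    m = binding_model(a_tot=a_tot, b_tot=b_tot, kon=kon, koff=kon * kd)
    eq = equilibrate(m, initialize_state(m))
    assert eq.converged
    expected = binding_equilibrium_closed_form(a_tot, b_tot, kd)
    assert eq.state[2] == pytest.approx(expected, rel=1e-6, abs=1e-9)


def test_equilibrate_with_zero_kon_gives_no_complex():
    m = binding_model(kon=0.0, koff=1e-2)
    eq = equilibrate(m, initialize_state(m))
    assert eq.state[2] == pytest.approx(0.0, abs=1e-9)


def test_equilibrate_is_idempotent():
    m = binding_model()
    eq1 = equilibrate(m, initialize_state(m))
    eq2 = equilibrate(m, eq1.state)
    assert np.allclose(eq1.state, eq2.state, rtol=1e-6, atol=1e-9)
    assert eq2.time == 0.0  # already stationary on re-entry


def test_phospho_cycle_steady_state_matches_rate_ratio():
    m = phospho_cycle_model(s_tot=100.0, kin_tot=10.0, pho_tot=10.0,
                            kcat_kin=1e-3, kcat_pho=2e-3)
    eq = equilibrate(m, initialize_state(m))
    frac = phospho_cycle_fraction(10.0, 10.0, 1e-3, 2e-3)
    state = dict(zip([s.id for s in m.species], eq.state))
    assert state["Sp"] / 100.0 == pytest.approx(frac, rel=1e-6)


# -- trajectories ------------------------------------------------------------

def test_moiety_conservation_along_toy_trajectory(toy_model):
    """mRNA species carry no moiety, so the protein totals of the full toy
    network are conserved along the whole trajectory to < 1e-6 relative."""
    y0 = initialize_state(toy_model)
    names = [s.id for s in toy_model.species]
    totals0 = moiety_totals(toy_model, dict(zip(names, y0)))
    res = simulate(toy_model, y0, 28800.0)
    for k in (50, 100, 200):
        totals = moiety_totals(toy_model, dict(zip(names, res.concentrations[k])))
        for m_id, t0 in totals0.items():
            if t0 > 0:
                assert abs(totals[m_id] - t0) / t0 < 1e-6


def test_trajectories_are_nonnegative(toy_model, toy_equilibrium):
    res = simulate(toy_model, toy_equilibrium.state, 3600.0)
    assert np.all(res.concentrations >= 0.0)


def test_endpoint_stable_under_tolerance_halving():
    m = binding_model(a_tot=80.0, b_tot=120.0)
    base = SolverSettings()
    tight = SolverSettings(rel_tol=base.rel_tol / 2)
    y0 = initialize_state(m)
    r1 = simulate(m, y0, 500.0, base)
    r2 = simulate(m, y0, 500.0, tight)
    end1, end2 = r1.concentrations[-1], r2.concentrations[-1]
    assert np.all(np.abs(end1 - end2) <= 1e-3 * np.maximum(end1, 1e-9))


# -- initialization ----------------------------------------------------------

def test_initialize_state_pools_to_unbound_basic(toy_model):
    y0 = initialize_state(toy_model)
    st_map = dict(zip([s.id for s in toy_model.species], y0))
    assert st_map["ERK"] == 100.0
    assert st_map["ERKPP"] == 0.0 and st_map["EGF.EGFR"] == 0.0


def test_initialize_state_applies_concentration_directives():
    m = NetworkModel(
        species=[
            SpeciesDecl("PTEN", role="basic", initial_concentration=100.0),
            SpeciesDecl("SMAD4", role="basic", initial_concentration=60.0),
        ],
    ).validate()
    g = Genotype("g", (
        MutationDirective("PTEN", "partial_loss", fraction=0.6),
        MutationDirective("SMAD4", "null"),
    ))
    y0 = initialize_state(m, g)
    assert y0[0] == pytest.approx(60.0)  # 60% of physiological value
    assert y0[1] == 0.0


def test_initialize_state_unknown_directive_target():
    m = binding_model()
    g = Genotype("g", (MutationDirective("NOPE", "null"),))
    with pytest.raises(KeyError, match="NOPE"):
        initialize_state(m, g)


# -- cross-engine oracle -----------------------------------------------------

DESOLVE_SCRIPT = """
library(deSolve)
pars <- c(kon=1e-3, koff=1e-2)
y0 <- c(A=100, B=80, AB=0)
rhs <- function(t, y, p) {
  v <- p["kon"]*y["A"]*y["B"] - p["koff"]*y["AB"]
  list(c(-v, -v, v))
}
times <- seq(0, 600, by=10)
out <- ode(y0, times, rhs, pars, rtol=1e-10, atol=1e-12)
write.csv(as.data.frame(out), file=commandArgs(trailingOnly=TRUE)[1], row.names=FALSE)
"""


def test_trajectory_matches_independent_desolve_integration(tmp_path):
    """The SBML write->load->simulate chain reproduces the trajectory of an
    independent R/deSolve integration of the same rate law to 1e-4 relative."""
    assert shutil.which("Rscript"), "Rscript expected on PATH"
    m = binding_model(a_tot=100.0, b_tot=80.0, kon=1e-3, koff=1e-2)
    sbml_path = tmp_path / "bind.sbml"
    write_model(m, sbml_path, format="sbml")
    m2 = load_model(sbml_path, format="sbml")

    r_file = tmp_path / "ref.R"
    out_csv = tmp_path / "ref.csv"
    r_file.write_text(DESOLVE_SCRIPT)
    subprocess.run(
        ["Rscript", str(r_file), str(out_csv)], check=True, capture_output=True
    )
    ref = np.genfromtxt(out_csv, delimiter=",", names=True)

    res = simulate(m2, initialize_state(m2), 600.0,
                   SolverSettings(rel_tol=1e-10, abs_tol=1e-12),
                   t_eval=ref["time"])
    for col, sid in (("A", "A"), ("B", "B"), ("AB", "AB")):
        ours = np.interp(ref["time"], res.times, res.trajectory(sid))
        denom = np.maximum(np.abs(ref[col]), 1e-6)
        assert np.max(np.abs(ours - ref[col]) / denom) < 1e-4
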