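import numpy as np
import pytest

import mimsim
from mimsim import (
    CalibrationError,
    Genotype,
    InhibitorSpec,
    MutationDirective,
    PRESET_GENOTYPES,
    PRESET_INHIBITORS,
    apply_genotype,
    apply_inhibitor,
    calibrate_inhibitor,
    equilibrate,
    initialize_state,
    moiety_totals,
    simulate,
)
from mimsim.network import ModelValidationError
from mimsim.perturb import embed_state
from mimsim.readout import phospho_fraction

from _helpers import phospho_cycle_model


def _state_map(model, vec):
    return dict(zip([s.id for s in model.species], vec))


# -- genotypes ---------------------------------------------------------------

def test_partial_loss_scales_moiety_total(toy_model):
    g = PRESET_GENOTYPES["HCT116"]
    m = apply_genotype(toy_model, g)
    assert moiety_totals(m)["PTEN"] == pytest.approx(0.6 * moiety_totals(toy_model)["PTEN"])


def test_overexpression_doubles_moiety_total(toy_model):
    m = apply_genotype(toy_model, PRESET_GENOTYPES["HT29"])
    assert moiety_totals(m)["ERBB2"] == pytest.approx(2.0 * moiety_totals(toy_model)["ERBB2"])


def test_null_zeroes_moiety_and_downstream_complexes(toy_model):
    m = apply_genotype(toy_model, PRESET_GENOTYPES["HT29"])  # null(SMAD4)
    assert moiety_totals(m)["SMAD4"] == 0.0
    eq = equilibrate(m, initialize_state(m))
    st = _state_map(m, eq.state)
    assert st["SMAD2p.SMAD4"] == pytest.approx(0.0, abs=1e-9)
    assert st["SMAD4.TCF7L2"] == pytest.approx(0.0, abs=1e-9)


def test_apply_genotype_is_idempotent(toy_model):
    once = apply_genotype(toy_model, PRESET_GENOTYPES["HCT116"])
    twice = apply_genotype(once, PRESET_GENOTYPES["HCT116"])
    assert moiety_totals(twice) == moiety_totals(once)
    assert [c.kcat for c in twice.catalytic] == [c.kcat for c in once.catalytic]


def test_constitutive_activation_zeroes_inactivation_rates(toy_model):
    m = apply_genotype(toy_model, PRESET_GENOTYPES["HCT116"])  # KRAS const
    gap = next(c for c in m.catalytic if c.id == "c_ras_gap")
    assert gap.kcat == 0.0


def test_unknown_genotype_target_errors(toy_model):
    g = Genotype("bad", (MutationDirective("NOPE", "null"),))
    with pytest.raises(KeyError, match="NOPE"):
        apply_genotype(toy_model, g)


def test_constitutive_activation_without_inactivation_process_errors():
    m = phospho_cycle_model(pho_tot=0.0)
    m.catalytic = [c for c in m.catalytic if c.id != "p"]
    m.annotations["active_forms"] = {"S": "Sp"}
    g = Genotype("g", (MutationDirective("S", "constitutive_activation"),))
    with pytest.raises(ModelValidationError, match="no inactivation"):
        apply_genotype(m.validate(), g)


def test_constitutive_mutation_decouples_erk_from_receptor(toy_model, settings):
    """With constitutively active KRAS, receptor-level inhibition no longer
    moves steady-state ppERK (the pathway is switched on downstream)."""
    egfr_i = InhibitorSpec("EGFRi", target="EGF.EGFR",
                           mechanism="activity_scaling", strength=0.9)
    for gname, moves in (("physiologic", True), ("HCT116", False)):
        base = apply_genotype(toy_model, PRESET_GENOTYPES[gname])
        eq = equilibrate(base, initialize_state(base), settings)
        control = phospho_fraction(base, _state_map(base, eq.state), "ERK")
        treated = apply_inhibitor(base, egfr_i)
        eq2 = equilibrate(treated, embed_state(base, eq.state, treated), settings)
        level = phospho_fraction(treated, _state_map(treated, eq2.state), "ERK")
        if moves:
            assert level < 0.9 * control
        else:
            assert level == pytest.approx(control, rel=1e-4)


# -- inhibitors --------------------------------------------------------------

def test_zero_strength_is_identity(toy_model):
    m = apply_inhibitor(toy_model, PRESET_INHIBITORS["CI1040"], strength=0.0)
    assert [c.kcat for c in m.catalytic] == [c.kcat for c in toy_model.catalytic]
    assert len(m.species) == len(toy_model.species)


def test_activity_scaling_hits_moiety_containing_enzymes(toy_model):
    # the GSK3B inhibitor must reach the destruction complex (enzyme DC
    # contains the GSK3B moiety) even though free GSK3B catalyzes nothing
    m = apply_inhibitor(toy_model, PRESET_INHIBITORS["Azakenpaullone"], strength=0.9)
    before = next(c for c in toy_model.catalytic if c.id == "c_bcat_p").kcat
    after = next(c for c in m.catalytic if c.id == "c_bcat_p").kcat
    assert after == pytest.approx(0.1 * before)


def test_unknown_inhibitor_target_errors(toy_model):
    bad = InhibitorSpec("X", target="NOPE", mechanism="activity_scaling", strength=0.5)
    with pytest.raises(KeyError, match="NOPE"):
        apply_inhibitor(toy_model, bad)


def test_inhibitors_on_distinct_targets_commute(toy_model):
    a = PRESET_INHIBITORS["PI103"]
    b = PRESET_INHIBITORS["XAV939"]
    ab = apply_inhibitor(apply_inhibitor(toy_model, a), b)
    ba = apply_inhibitor(apply_inhibitor(toy_model, b), a)
    assert [c.kcat for c in ab.catalytic] == [c.kcat for c in ba.catalytic]
    assert ab.annotations["applied_inhibitors"] == ba.annotations["applied_inhibitors"]


def test_competitive_binding_adds_sequestration_reaction(toy_model):
    m = apply_inhibitor(toy_model, PRESET_INHIBITORS["Perifosine_40nM"], strength=2.0)
    ids = {s.id for s in m.species}
    assert "Perifosine_40nM" in ids and "AKTP.Perifosine_40nM" in ids
    rx = next(r for r in m.reversible if r.id == "bind_Perifosine_40nM")
    assert rx.koff / rx.kon == pytest.approx(2.0)  # Ki
    m.validate()  # complex composition balances


def test_dose_response_is_monotone(toy_model, physiologic, settings, toy_equilibrium):
    spec = PRESET_INHIBITORS["CI1040"]
    base = apply_genotype(toy_model, physiologic)
    control = phospho_fraction(base, _state_map(base, toy_equilibrium.state), "ERK")
    levels = []
    for f in (0.0, 0.3, 0.6, 0.9):
        treated = apply_inhibitor(base, spec, strength=f)
        res = simulate(treated, embed_state(base, toy_equilibrium.state, treated),
                       1800.0, settings, t_eval=[1800.0])
        levels.append(
            phospho_fraction(treated, res.state_at(1800.0), "ERK") / control
        )
    assert all(a >= b - 1e-9 for a, b in zip(levels, levels[1:]))


def test_calibration_reproduces_preset_levels(toy_model, physiologic, settings,
                                              calibrated_strengths):
    """Applying the calibrated strength reproduces each documented level of
    normalized readout inhibition to within 0.1% absolute."""
    base = apply_genotype(toy_model, physiologic)
    eq = equilibrate(base, initialize_state(base), settings)
    for name, level, moiety in (
        ("CI1040", 0.80, "ERK"),
        ("Perifosine_20nM", 0.40, "AKT"),
        ("Perifosine_40nM", 0.70, "AKT"),
    ):
        spec = PRESET_INHIBITORS[name]
        control = phospho_fraction(base, _state_map(base, eq.state), moiety)
        treated = apply_inhibitor(base, spec, strength=calibrated_strengths[name])
        res = simulate(treated, embed_state(base, eq.state, treated), 1800.0,
                       settings, t_eval=[1800.0])
        achieved = 1.0 - phospho_fraction(treated, res.state_at(1800.0), moiety) / control
        assert achieved == pytest.approx(level, abs=1e-3)


def test_calibration_desired_zero_returns_zero(toy_model, physiologic):
    assert calibrate_inhibitor(
        toy_model, physiologic, PRESET_INHIBITORS["CI1040"], desired_fraction=0.0
    ) == 0.0


def test_calibration_insensitive_readout_errors(toy_model, physiologic, settings):
    # XAV939 cannot move the ppERK readout at all
    spec = InhibitorSpec("XAV939", target="TNKS", mechanism="activity_scaling",
                         level=0.5, readout="ERK")
    with pytest.raises(CalibrationError, match="insensitive"):
        calibrate_inhibitor(toy_model, physiologic, spec, settings=settings)
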