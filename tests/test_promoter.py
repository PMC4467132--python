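import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from mimsim.promoter import (
    GeneParams,
    KDEG_CCND1,
    KDEG_MYC,
    KSYNTH_DEFAULT,
    PromoterConfig,
    SITE_NAMES,
    TFBinding,
    TFBSConfig,
    ccnd1_kdeg_modifier,
    mrna_half_life,
    mrna_rate,
    p_rnap_bound,
    promoter_regulation_factor,
    site_regulation_factor,
)


def _site(name, bindings):
    return TFBSConfig(name, bindings)


def _full_promoter(site_overrides=None, **kwargs):
    overrides = site_overrides or {}
    sites = [overrides.get(n, TFBSConfig(n, [])) for n in SITE_NAMES]
    kwargs.setdefault("genes", {
        "MYC": GeneParams("MYC_mRNA", KSYNTH_DEFAULT, KDEG_MYC),
        "CCND1": GeneParams("CCND1_mRNA", KSYNTH_DEFAULT, KDEG_CCND1),
    })
    return PromoterConfig(sites=sites, **kwargs)


# -- site factors ------------------------------------------------------------

def test_empty_occupancy_limit_is_one():
    s = _site("TFBS_AP1", [TFBinding("a", Kd=10.0, mode="activator", omega=5.0),
                           TFBinding("r", Kd=10.0, mode="repressor")])
    assert site_regulation_factor(s, {"a": 0.0, "r": 0.0}) == 1.0


def test_single_activator_at_kd_with_omega_ten():
    s = _site("TFBS_AP1", [TFBinding("a", Kd=10.0, mode="activator", omega=10.0)])
    assert site_regulation_factor(s, {"a": 10.0}) == pytest.approx(5.5)


def test_full_repression_limit():
    s = _site("TFBS_TP53", [TFBinding("r", Kd=1.0, mode="repressor")])
    assert site_regulation_factor(s, {"r": 1e9}) == pytest.approx(0.0, abs=1e-8)


def test_negative_concentration_rejected():
    s = _site("TFBS_TP53", [TFBinding("r", Kd=1.0, mode="repressor")])
    with pytest.raises(ValueError, match="negative"):
        site_regulation_factor(s, {"r": -1.0})


def test_missing_species_raises():
    s = _site("TFBS_TP53", [TFBinding("r", Kd=1.0, mode="repressor")])
    with pytest.raises(KeyError, match="absent"):
        site_regulation_factor(s, {})


def test_repressors_carry_no_omega():
    with pytest.raises(ValueError, match="omega"):
        TFBinding("r", Kd=1.0, mode="repressor", omega=2.0)


# -- promoter factor ---------------------------------------------------------

def test_promoter_factor_is_product_of_sites():
    a = TFBinding("a", Kd=10.0, mode="activator", omega=3.0)
    r = TFBinding("r", Kd=5.0, mode="repressor")
    cfg = _full_promoter({
        "TFBS_TCF7L2": _site("TFBS_TCF7L2", [a]),
        "TFBS_TP53": _site("TFBS_TP53", [r]),
    })
    state = {"a": 10.0, "r": 5.0}
    expected = site_regulation_factor(cfg.sites[0], state) * site_regulation_factor(
        cfg.sites[3], state
    )
    assert promoter_regulation_factor(cfg, state) == pytest.approx(expected)


def test_fully_repressed_site_annihilates_f_reg():
    r = TFBinding("r", Kd=1.0, mode="repressor")
    cfg = _full_promoter({"TFBS_TP53": _site("TFBS_TP53", [r])})
    assert promoter_regulation_factor(cfg, {"r": 1e12}) == pytest.approx(0.0, abs=1e-9)


def brute_force_f_reg(sites, state):
    """Enumerate joint occupancy states of a multi-site promoter.

    Each site is empty, activator-bound or repressor-bound; configuration
    statistical weight is the product of site occupancies, and the
    RNAP-enhancement numerator weights activator-bound sites by omega and
    zeroes repressor-bound ones.  Under site independence the ratio equals
    the product of per-site factors.
    """
    per_site_options = []
    for site in sites:
        opts = [(1.0, 1.0)]  # (weight, rnap numerator weight)
        for b in site.bindings:
            occ = state[b.species_id] / b.Kd
            if b.mode == "activator":
                opts.append((occ, occ * b.omega))
            else:
                opts.append((occ, 0.0))
        per_site_options.append(opts)
    z = 0.0
    z_num = 0.0
    for combo in itertools.product(*per_site_options):
        z += math.prod(w for w, _ in combo)
        z_num += math.prod(wn for _, wn in combo)
    return z_num / z


def test_product_decomposition_matches_occupancy_enumeration():
    """On a 2-site promoter the independence assumption makes the product
    of site factors agree exactly with brute-force joint enumeration."""
    s1 = _site("TFBS_TCF7L2", [TFBinding("a1", Kd=12.0, mode="activator", omega=7.0),
                               TFBinding("r1", Kd=4.0, mode="repressor")])
    s2 = _site("TFBS_AP1", [TFBinding("a2", Kd=30.0, mode="activator", omega=2.5)])
    state = {"a1": 8.0, "r1": 3.0, "a2": 45.0}
    product = site_regulation_factor(s1, state) * site_regulation_factor(s2, state)
    assert product == pytest.approx(brute_force_f_reg([s1, s2], state), rel=1e-12)


@hsettings(max_examples=25, deadline=None)
@given(
    a1=st.floats(0.0, 100.0), r1=st.floats(0.0, 100.0),
    a2=st.floats(0.0, 100.0), r2=st.floats(0.0, 100.0),
)
def test_product_decomposition_randomized(a1, r1, a2, r2):
    s1 = _site("TFBS_SMAD4", [TFBinding("a1", Kd=10.0, mode="activator", omega=4.0),
                              TFBinding("r1", Kd=7.0, mode="repressor")])
    s2 = _site("TFBS_E2F-DP1", [TFBinding("a2", Kd=20.0, mode="activator", omega=9.0),
                                TFBinding("r2", Kd=3.0, mode="repressor")])
    state = {"a1": a1, "r1": r1, "a2": a2, "r2": r2}
    product = site_regulation_factor(s1, state) * site_regulation_factor(s2, state)
    assert product == pytest.approx(brute_force_f_reg([s1, s2], state), rel=1e-10)


# -- RNAP occupancy ----------------------------------------------------------

def test_p_rnap_bound_symmetry_point():
    cfg = _full_promoter(rnap_concentration=30.0, k_rnap=1.0 / 30.0)
    assert p_rnap_bound(1.0, cfg) == pytest.approx(0.5)  # z = 1


def test_p_rnap_bound_limits():
    cfg = _full_promoter()
    assert p_rnap_bound(0.0, cfg) == 0.0
    assert p_rnap_bound(1e12, cfg) == pytest.approx(1.0)


def test_k_rnap_kd_convention_toggle():
    cfg = _full_promoter(rnap_concentration=30.0, k_rnap=30.0, k_rnap_is_kd=True)
    assert p_rnap_bound(1.0, cfg) == pytest.approx(0.5)  # z = [RNAP]/Kd = 1


@hsettings(max_examples=25, deadline=None)
@given(act=st.floats(0.0, 1e4), rep=st.floats(0.0, 1e4))
def test_p_in_unit_interval_and_monotone(act, rep):
    """P(RNAP bound) stays in [0,1]; raising an activator concentration can
    only raise it, raising a repressor concentration can only lower it."""
    s = _site("TFBS_TCF7L2", [TFBinding("a", Kd=10.0, mode="activator", omega=6.0),
                              TFBinding("r", Kd=10.0, mode="repressor")])
    cfg = _full_promoter({"TFBS_TCF7L2": s})

    def p(a, r):
        return p_rnap_bound(promoter_regulation_factor(cfg, {"a": a, "r": r}), cfg)

    base = p(act, rep)
    assert 0.0 <= base <= 1.0
    assert p(act * 2 + 1, rep) >= base - 1e-12
    assert p(act, rep * 2 + 1) <= base + 1e-12


# -- mRNA kinetics -----------------------------------------------------------

def test_mrna_steady_states_from_printed_constants():
    myc = GeneParams("MYC_mRNA", KSYNTH_DEFAULT, KDEG_MYC)
    ccnd1 = GeneParams("CCND1_mRNA", KSYNTH_DEFAULT, KDEG_CCND1)
    # steady state mRNA* = ksynth*P/kdeg; at P=1
    assert KSYNTH_DEFAULT / KDEG_MYC == pytest.approx(0.18519, rel=1e-4)
    assert KSYNTH_DEFAULT / KDEG_CCND1 == pytest.approx(8.7719, rel=1e-4)
    assert mrna_rate(myc, 1.0, KSYNTH_DEFAULT / KDEG_MYC) == pytest.approx(0.0, abs=1e-12)
    assert mrna_rate(ccnd1, 1.0, KSYNTH_DEFAULT / KDEG_CCND1) == pytest.approx(0.0, abs=1e-12)


def test_mrna_pure_decay_closed_form():
    myc = GeneParams("MYC_mRNA", KSYNTH_DEFAULT, KDEG_MYC)
    # with P = 0 the ODE is linear decay: integrate analytically and compare
    m0, t = 3.0, 7200.0
    expected = m0 * math.exp(-KDEG_MYC * t)
    # forward-Euler fine integration of the rate function as an independent path
    m, dt = m0, 0.5
    for _ in range(int(t / dt)):
        m += dt * mrna_rate(myc, 0.0, m)
    assert m == pytest.approx(expected, rel=1e-3)


def test_mrna_converges_to_ratio_from_any_start():
    gene = GeneParams("x", 5e-5, 1e-3)
    target = 5e-5 * 0.7 / 1e-3
    for m0 in (0.0, 0.01, 10.0):
        m, dt = m0, 1.0
        for _ in range(20000):
            m += dt * mrna_rate(gene, 0.7, m)
        assert m == pytest.approx(target, rel=1e-4)


def test_half_life_values_and_bound():
    t_myc = mrna_half_life(KDEG_MYC)
    assert t_myc == pytest.approx(0.713, abs=0.001)
    assert t_myc < 2.0  # fast MYC: below the 2 h bound
    assert mrna_half_life(KDEG_CCND1) == pytest.approx(33.78, abs=0.01)
    assert mrna_half_life(math.log(2) / 3600.0) == pytest.approx(1.0, rel=1e-12)
    with pytest.raises(ValueError):
        mrna_half_life(0.0)


def test_kdeg_asymmetry_ratio():
    # MYC relaxes ~47x faster than CCND1
    assert KDEG_MYC / KDEG_CCND1 == pytest.approx(47.37, abs=0.01)


# -- MEK-inhibitor CCND1 destabilization -------------------------------------

def test_ccnd1_modifier_identity_when_ratio_one():
    assert ccnd1_kdeg_modifier(KDEG_CCND1, 40.0, 40.0) == KDEG_CCND1


def test_ccnd1_modifier_scales_with_erk_suppression():
    # 80% ppERK inhibition -> ratio 5 -> kdeg x5
    assert ccnd1_kdeg_modifier(5.7e-6, 50.0, 10.0) == pytest.approx(2.85e-5)


def test_ccnd1_modifier_floors_near_total_inhibition():
    with pytest.warns(RuntimeWarning, match="floor"):
        k = ccnd1_kdeg_modifier(KDEG_CCND1, 40.0, 0.0)
    assert k == pytest.approx(KDEG_CCND1 / 1e-6)
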