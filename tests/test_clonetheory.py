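"""Clone-level theory: establishment, extinction times, diversity, speed."""

import numpy as np
import pytest
from scipy.integrate import quad

import crisprcoevo as cc
from crisprcoevo.clonetheory import (
    acquisition_time,
    acquisition_time_density,
    branching_extinction_oracle,
    clone_dynamics,
    diversity_a,
    effective_mutation_rate,
    establishment_probability,
    establishment_probability_steady,
    large_clone_extinction_time,
    m_perturbative,
    pest_closed_form,
    predict_diversity,
    predict_speed,
    solve_m_closed_form,
    theory_bundle,
)
from crisprcoevo.meanfield import no_crispr_steady_state, steady_state


def test_establishment_zero_at_no_crispr_background(defaults):
    # alpha nB~ (B pV - 1) = F exactly at the coexistence background
    nB, _ = no_crispr_steady_state(defaults)
    assert establishment_probability(defaults, nB) == pytest.approx(0.0, abs=1e-12)


def test_establishment_plugin_example(defaults):
    got = establishment_probability(defaults, 0.2 * defaults.C0)
    assert got == pytest.approx(2.09e-3, rel=5e-3)
    s0 = defaults.alpha * 0.2 * defaults.C0 * (defaults.B * defaults.pV - 1) - defaults.F
    assert s0 == pytest.approx(2.4e-3, rel=1e-9)


def test_establishment_steady_form_zero_at_e_zero(defaults):
    assert establishment_probability_steady(defaults.with_(e=0.0), 0.5, 10) == 0.0
    # Pest = 2 e nu / (m (B - 1))
    v = establishment_probability_steady(defaults, 0.31, 10.0)
    assert v == pytest.approx(2 * 0.95 * 0.31 / (10 * 169), rel=1e-12)


def test_branching_oracle_b2_closed_form():
    # for B = 2 the fixed point solves exactly: survival = 1 - delta0/beta0
    beta0, delta0 = 1.1, 1.0
    assert branching_extinction_oracle(beta0, delta0, 2) == pytest.approx(
        1 - delta0 / beta0, rel=1e-9)
    # matches direct generating-function iteration
    q = 0.5
    for _ in range(10000):
        q = (delta0 + beta0 * q ** 2) / (delta0 + beta0)
    assert branching_extinction_oracle(beta0, delta0, 2) == pytest.approx(1 - q, abs=1e-6)


def test_branching_oracle_subcritical():
    assert branching_extinction_oracle(0.1, 1.0, 5) == 0.0  # beta0 (B-1) < delta0


def test_establishment_formula_first_order_accuracy(defaults):
    """Within 5% of the exact branching survival in the deployed regime.

    At the self-consistent steady states the mutant growth advantage is
    small (s0 <~ 0.06 delta0) and the first-order formula is accurate; the
    error grows like (2/3) s0/(s0+delta0) beyond that.
    """
    B = defaults.B
    for ratio in np.linspace(0.005, 0.06, 8):
        delta0 = 1.0
        s0 = ratio * delta0
        beta0 = (s0 + delta0) / (B - 1)
        f = 2 * s0 / (B * (s0 + delta0))
        o = branching_extinction_oracle(beta0, delta0, B)
        assert f == pytest.approx(o, rel=0.05)


def test_large_clone_extinction_time_example():
    p = cc.Params(C0=1e4)
    _, nV_t = no_crispr_steady_state(p)
    out = large_clone_extinction_time(p, nVi=nV_t / 10, nV=nV_t, m=10)
    assert out["Text_approx_generations"] == pytest.approx(2.02e3, rel=5e-3)


def test_extinction_time_full_vs_approx_to_order_one_over_B(defaults):
    # evaluated at the low-immunity background the approximation assumes
    p = cc.Params(C0=1e4)
    m = 10.0
    nB_t, nV_t = no_crispr_steady_state(p)
    stt = steady_state(p, 0.0)
    nBs = stt.nu_star * nB_t
    out = large_clone_extinction_time(p, nVi=nV_t / m, nV=nV_t,
                                      nBi=nBs / m, nB=nB_t, m=m)
    rel = abs(out["Text_generations"] - out["Text_approx_generations"]) \
        / out["Text_approx_generations"]
    assert rel < 2.0 / p.B


def test_extinction_time_ln_term_vanishes_at_whole_population(defaults):
    out = large_clone_extinction_time(defaults, nVi=1000.0, nV=1000.0, nB=1500.0)
    B, al, pV, F = defaults.B, defaults.alpha, defaults.pV, defaults.F
    beta = al * pV * 1500.0
    delta = F + al * 1500.0 * (1 - pV)
    assert out["Text_minutes"] == pytest.approx(
        2 * 1000 / ((B - 1) * (2 * beta + delta)), rel=1e-12)
    with pytest.raises(ValueError):
        large_clone_extinction_time(defaults, nVi=2000.0, nV=1000.0)


def test_effective_mutation_rate(defaults):
    assert effective_mutation_rate(defaults.with_(mu=0.0), 1e3, 1e5, 0.3, 10) == 0.0
    # the mutant fraction factor at mu = 1e-4, L = 30
    assert 1 - np.exp(-1e-4 * 30) == pytest.approx(2.9955e-3, rel=1e-4)
    # zeroth-order (e_eff = 0, no-CRISPR totals) within 10% of the full rate
    p = cc.Params(C0=1e4)
    m = 14.0
    stt = steady_state(p, p.e / m)
    tot = stt.counts(p.C0)
    full = effective_mutation_rate(p, tot["nB"], tot["nV"], stt.nu_star, m)
    nB_t, nV_t = no_crispr_steady_state(p)
    zeroth = effective_mutation_rate(p.with_(e=0.0), nB_t, nV_t, 0.0, m)
    assert zeroth == pytest.approx(full, rel=0.10)


def test_diversity_combined_parameter_and_closed_form():
    p = cc.Params(C0=1e4, e=0.95, eta=1e-3, mu=1e-5)
    av = diversity_a(p)
    assert av["a_approx"] == pytest.approx(5.97e3, rel=5e-3)
    m = solve_m_closed_form(av["a_approx"])
    assert m == pytest.approx(29.7, rel=5e-3)
    assert m ** 3 == pytest.approx(av["a_approx"] * (1 + np.log(m)), rel=1e-9)
    assert m_perturbative(av["a_approx"]) == pytest.approx(m, rel=0.01)


def test_diversity_vanishes_without_mutation():
    p = cc.Params(C0=1e4, mu=0.0)
    d = predict_diversity(p)
    assert d["a_approx"] == 0.0
    assert d["m_closed_form"] == 0.0


def test_diversity_scaling_with_mutation_rate():
    p = cc.Params(C0=1e4, mu=1e-6)
    p10 = p.with_(mu=1e-5)
    a1 = diversity_a(p)["a_approx"]
    a10 = diversity_a(p10)["a_approx"]
    assert a10 / a1 == pytest.approx(10.0, rel=1e-6)
    m1, m10 = solve_m_closed_form(a1), solve_m_closed_form(a10)
    # log-corrected 1/3 power: d ln m / d ln a = 1 / (3 - 1/(1 + ln m))
    expo = np.log(m10 / m1) / np.log(10.0)
    mid = np.sqrt(m1 * m10)
    assert expo == pytest.approx(1.0 / (3.0 - 1.0 / (1.0 + np.log(mid))), rel=0.02)


def test_self_consistency_of_predicted_m():
    p = cc.Params(C0=1e4, e=0.95, eta=1e-3, mu=1e-5)
    d = predict_diversity(p)
    m = d["m_solution"]
    assert m is not None
    c = d["components"]
    assert c["Pest"] * c["mu_bar"] * c["Text"] == pytest.approx(m, rel=1e-6)


def test_no_solution_is_flagged_not_raised():
    d = predict_diversity(cc.Params(C0=300, mu=1e-8, eta=1e-5))
    assert d["m_solution"] is None
    assert d["m_closed_form"] < 1.0


def test_clonal_interference_warning():
    """At very low acquisition probability, large clones turn over faster
    than naive bacteria can acquire spacers; the balance is flagged."""
    with pytest.warns(UserWarning, match="clonal-interference"):
        d = predict_diversity(cc.Params(C0=1e3, eta=1e-6, mu=1e-4))
    assert d["clonal_interference"]
    d_ok = predict_diversity(cc.Params(C0=1e4, eta=1e-3, mu=1e-5))
    assert not d_ok["clonal_interference"]


def test_pest_closed_form_composes_from_parts():
    """The closed form equals 2 e nu~ / (m (B-1)) composed with m ~ a^(1/3)
    under the same large-B, small-eta reductions (exact 1/3 mutation-rate
    scaling; level agreement to the order of the dropped terms)."""
    p = cc.Params(C0=1e4, e=0.95, eta=1e-3, mu=1e-5)
    closed = pest_closed_form(p)
    # exact mu^{-1/3} scaling
    r = pest_closed_form(p.with_(mu=1e-4)) / closed
    assert r == pytest.approx(10 ** (-1 / 3), rel=1e-9)
    # compositional value: 2 e nu / (m B) with nu = eta_hat alpha nV~ / r,
    # the large-B phage total alpha nV~ ~ gC0 (1-f)/pV, and m = a^(1/3)
    eta_hat = p.eta * (1 - p.pV)
    nu_lb = eta_hat * (p.gC0 * (1 - p.f) / p.pV) / p.r
    a = diversity_a(p)["a_approx"]
    composed = 2 * p.e * nu_lb / (a ** (1 / 3) * p.B)
    assert closed == pytest.approx(composed, rel=1e-6)


def test_clone_dynamics_phage_exponential_phase():
    p = cc.Params(C0=1e4)
    m = 14.0
    stt = steady_state(p, p.e / m)
    tot = stt.counts(p.C0)
    out = clone_dynamics(p, tot["nB"], tot["nV"], tot["nB0"], tot["C"],
                         horizon_minutes=2000.0, nVi0=1.0, nBi0=0.0)
    # while the matching bacterial clone is ~0, nVi(t) tracks exp(s0 t)
    early = out["t"] < 500
    assert np.allclose(out["nVi"][early], out["nVi_1d"][early], rtol=0.01)
    # equal-clone fixed points: nBi* ~ nBs/m, nVi* ~ nV/m (P0 correction small)
    assert out["nBi_star"] == pytest.approx(tot["nBs"] / m, rel=0.05)
    assert out["nVi_star"] == pytest.approx(tot["nV"] / m, rel=0.05)


def test_acquisition_time_density_and_mean():
    p = cc.Params()  # a_acq is set through nB0 = a_acq / (alpha eta (1 - pV))
    s0, a_acq = 3e-3, 1e-5
    nB0 = a_acq / (p.alpha * p.eta * (1 - p.pV))
    mass, err = quad(lambda t: acquisition_time_density(p, s0, nB0, t),
                     0, 20000, limit=200)
    assert mass == pytest.approx(1.0, abs=1e-6)
    # worked example: s0 = 0.01/min, a_acq = 1e-4/min
    nB0_2 = 1e-4 / (p.alpha * p.eta * (1 - p.pV))
    out = acquisition_time(p, s0=0.01, nB0=nB0_2)
    assert out["a_acq"] == pytest.approx(1e-4, rel=1e-9)
    assert out["t_mean_minutes"] == pytest.approx(407.9, rel=2e-3)
    assert out["size_at_mean"] == pytest.approx(59.1, rel=5e-3)
    # a_acq << s0 implies first acquisition later than 1/s0
    assert out["t_mean_minutes"] > 1 / 0.01
    with pytest.raises(ValueError):
        acquisition_time(p, s0=-1.0, nB0=1.0)


def test_predict_speed(defaults):
    out = predict_speed(defaults, Text_generations=2.02e3)
    assert out["v"] == pytest.approx(4.95e-4, rel=2e-3)
    assert out["v"] * out["Text"] == pytest.approx(1.0, rel=1e-12)
    r = predict_speed(defaults.with_(mu=1e-4), m=10.0)["v_closed_form"] \
        / predict_speed(defaults.with_(mu=1e-5), m=10.0)["v_closed_form"]
    assert r == pytest.approx(10 ** (1 / 3), rel=1e-9)
    assert r == pytest.approx(2.154, rel=1e-3)


def test_speed_closed_form_composes_from_text_and_m():
    """v ~ alpha B f [e mu eta L (1-pV)/(2 alpha^2 B^2 r)]^(1/3) follows from
    v = 1/Text with Text ~ 2 nV~ (1 - 1/(B pV)) / (f (B-1) m) and m^3 ~ a,
    under the same large-B reductions used for a."""
    p = cc.Params(C0=1e4, e=0.95, eta=1e-3, mu=1e-5)
    eta_hat = p.eta * (1 - p.pV)
    v3 = p.alpha * p.B * p.f ** 3 * p.e * p.mu * p.L * eta_hat / (2 * p.r)
    assert predict_speed(p, m=10.0)["v_closed_form"] == pytest.approx(
        v3 ** (1 / 3), rel=1e-9)
    # large-B composition: f B m / (2 nV~) with nV~ ~ g C0 (1-f)/(alpha pV)
    nV_lb = p.gC0 * (1 - p.f) / (p.alpha * p.pV)
    a = diversity_a(p)["a_approx"]
    composed = p.f * p.B * a ** (1 / 3) / (2 * nV_lb)
    assert v3 ** (1 / 3) == pytest.approx(composed, rel=1e-6)


def test_theory_bundle_is_coherent():
    p = cc.Params(C0=1e4, e=0.95, eta=1e-3, mu=1e-5)
    tb = theory_bundle(p)
    assert tb.A == pytest.approx(4.667, abs=5e-4)
    assert 0 <= tb.Pest <= 1
    assert tb.Text > 0 and tb.v_pred == pytest.approx(1 / tb.Text)
    assert tb.m_pred == pytest.approx(14.3, rel=0.01)
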