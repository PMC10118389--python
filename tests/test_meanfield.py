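"""Deterministic total-population layer: thresholds, fixed points, the cubic."""

import numpy as np
import pytest

import crisprcoevo as cc
from crisprcoevo.meanfield import (
    PhageExtinctError,
    critical_effective_e,
    cubic_coefficients,
    no_crispr_steady_state,
    nu_approximations,
    nu_star_cubic,
    ode_rhs,
    phage_threshold,
    steady_state,
)


def test_phage_threshold_defaults(defaults):
    A, pV0 = phage_threshold(defaults)
    assert A == pytest.approx(4.667, abs=5e-4)
    assert pV0 == pytest.approx(8.908e-3, rel=1e-3)
    # A = 1 exactly at pV = pV0
    A1, _ = phage_threshold(defaults.with_(pV=pV0))
    assert A1 == pytest.approx(1.0, abs=1e-12)


def test_no_crispr_totals(defaults):
    nB, nV = no_crispr_steady_state(defaults)
    assert nB / defaults.C0 == pytest.approx(0.15, rel=1e-6)
    assert nV / defaults.C0 == pytest.approx(22.0, rel=1e-3)
    # nB~ = C0 (1-f)/A collapses to C0 f g / ((B pV - 1) alpha)
    A, _ = phage_threshold(defaults)
    assert nB == pytest.approx(defaults.C0 * (1 - defaults.f) / A, rel=1e-12)
    assert nB == pytest.approx(
        defaults.C0 * defaults.f * defaults.g
        / ((defaults.B * defaults.pV - 1) * defaults.alpha), rel=1e-12)
    with pytest.raises(PhageExtinctError):
        no_crispr_steady_state(defaults.with_(pV=0.005))


def test_bacteria_only_fixed_point_is_stationary(defaults):
    # nV = 0, nB0 = C0 (1 - f), C = f C0 makes the bacterial subsystem static
    C0, f = defaults.C0, defaults.f
    rhs = ode_rhs((0.0, 0.0, C0 * (1 - f), f * C0), defaults, 0.0)
    assert max(abs(v) for v in rhs) < 1e-9 * C0


def test_coexistence_fixed_point_has_zero_rhs(defaults):
    for e_eff in (0.0, 0.05, 0.2, 0.5, 0.95):
        stt = steady_state(defaults, e_eff)
        tot = stt.counts(defaults.C0)
        rhs = ode_rhs((tot["nBs"], tot["nV"], tot["nB0"], tot["C"]),
                      defaults, e_eff)
        scale = defaults.F * defaults.C0
        assert max(abs(v) for v in rhs) < 1e-8 * scale


def test_full_immunity_kills_spacer_mediated_phage_growth(defaults):
    # with e_eff = 1, the phage growth from spacer-bearing hosts vanishes
    nBs, nV, nB0, C = 100.0, 50.0, 0.0, 1000.0
    d_nV = ode_rhs((nBs, nV, nB0, C), defaults, 1.0)[1]
    al, F, B = defaults.alpha, defaults.F, defaults.B
    assert d_nV == pytest.approx(-(F + al * nBs) * nV)


def test_cubic_root_equals_nu_tilde_at_zero_immunity(defaults):
    nu, regime, multiple = nu_star_cubic(defaults, 0.0)
    ap = nu_approximations(defaults, 0.0)
    assert nu == pytest.approx(ap["nu_tilde"], rel=1e-9)
    assert nu == pytest.approx(0.310, abs=5e-4)
    assert not multiple


def test_cubic_root_matches_large_e_expansion():
    p = cc.Params(eta=1e-5)
    nu_full, _, _ = nu_star_cubic(p, 1.0)
    ap = nu_approximations(p, 1.0)
    assert nu_full == pytest.approx(ap["large_e"], rel=1e-3)


def test_eta_zero_gives_no_spacers(defaults):
    p = defaults.with_(eta=0.0)
    nu, _, _ = nu_star_cubic(p, 0.2)
    assert nu == pytest.approx(0.0, abs=1e-10)


def test_nu_tilde_monotonic_in_eta_and_loss(defaults):
    vals_eta = [nu_approximations(defaults.with_(eta=eta), 0.0)["nu_tilde"]
                for eta in (1e-5, 1e-4, 1e-3, 1e-2)]
    assert np.all(np.diff(vals_eta) > 0)
    vals_R = [nu_approximations(defaults.with_(R=R), 0.0)["nu_tilde"]
              for R in (0.01, 0.04, 0.16)]
    assert np.all(np.diff(vals_R) < 0)
    # eta_hat -> infinity limit of nu_tilde is 1 (structural)
    big = nu_approximations(defaults.with_(eta=1.0), 0.0)["nu_tilde"]
    assert big > 0.99


def test_critical_effective_e(defaults):
    out = critical_effective_e(defaults)
    # sign-change threshold of the third denominator term
    assert out["eta_sign_threshold"] == pytest.approx(0.0113, abs=5e-5)
    # eta -> 0 limit: em* = r / (alpha nV~ pV) = 0.109
    out0 = critical_effective_e(defaults.with_(eta=1e-12))
    assert out0["em_star_full"] == pytest.approx(0.109, abs=5e-4)
    # series and full agree at small eta
    p = defaults.with_(eta=1e-4)
    o = critical_effective_e(p)
    assert o["em_star_full"] == pytest.approx(o["em_star_series"], rel=0.05)


def test_em_star_recovers_no_crispr_totals():
    p = cc.Params(C0=1e4, eta=1e-6)
    em = critical_effective_e(p)["em_star_full"]
    stt = steady_state(p, em)
    assert stt.x_star == pytest.approx(0.15, rel=0.01)
    assert stt.y_star == pytest.approx(22.0, rel=0.01)


def test_steady_state_consistency_with_no_crispr(defaults):
    stt = steady_state(defaults, 0.0)
    nB, nV = no_crispr_steady_state(defaults)
    assert stt.x_star * defaults.C0 == pytest.approx(nB, rel=1e-8)
    assert stt.y_star * defaults.C0 == pytest.approx(nV, rel=1e-6)


def test_phage_extinct_regime_flagged(defaults):
    stt = steady_state(defaults.with_(pV=0.005), 0.1)
    assert stt.phage_extinct
    assert stt.y_star == 0.0
    assert stt.x_star == pytest.approx(1 - defaults.f)


def test_y_star_nonmonotone_in_pV(defaults):
    """Phage abundance peaks at intermediate infectivity (fixed e_eff)."""
    pVs = np.linspace(0.012, 0.5, 40)
    ys = []
    for pV in pVs:
        stt = steady_state(defaults.with_(pV=pV), 0.2)
        ys.append(stt.y_star)
    ys = np.asarray(ys)
    k = int(np.argmax(ys))
    assert 0 < k < len(ys) - 1
    assert ys[k] > ys[0] and ys[k] > ys[-1]


def test_steady_state_continuous_in_e_eff(defaults):
    es = np.linspace(0.0, 0.9, 60)
    xs = [steady_state(defaults, e).x_star for e in es]
    steps = np.abs(np.diff(xs))
    assert steps.max() < 0.05  # no jumps on a fine grid


def test_measured_average_immunity_reproduces_simulated_totals(recovery_ensemble):
    """Feeding the measured average immunity back into the mean-field
    equations as e_eff reproduces the simulated totals (reduced scale)."""
    import crisprcoevo as cc
    from crisprcoevo.analysis import average_immunity
    from conftest import steady_means

    p = recovery_ensemble["params"]
    lo, _ = recovery_ensemble["window"]
    nBs, nVs, imms = [], [], []
    for r in recovery_ensemble["runs"]:
        sm = steady_means(r, lo)
        nBs.append(sm["nB"])
        nVs.append(sm["nV"])
        imms.append(np.mean([average_immunity(s.bacteria, s.phage, e=p.e)
                             for s in r.snapshots if s.bacteria and s.phage]))
    stt = steady_state(p, float(np.mean(imms)))
    assert stt.x_star * p.C0 == pytest.approx(np.mean(nBs), rel=0.15)
    assert stt.y_star * p.C0 == pytest.approx(np.mean(nVs), rel=0.15)


def test_cubic_coefficients_shape(defaults):
    a, b, c, d = cubic_coefficients(defaults, 0.3)
    # highest-degree coefficient carries e_eff^2; vanishes at e_eff = 0
    a0, b0, _, _ = cubic_coefficients(defaults, 0.0)
    assert a0 == 0.0 and b0 == 0.0
    assert a != 0.0 and d != 0.0


@pytest.mark.parametrize("eta, e_eff, label", [
    (1e-3, 0.02, "drop-cubic&quadratic"),
    (1e-3, 0.075, "drop-a"),
    (1e-2, 0.03, "drop-a"),
    (1e-5, 0.4, "drop-d"),
    (1e-5, 0.7, "drop-d"),
])
def test_regime_lookup_matches_dominant_balance(eta, e_eff, label):
    """Each reduced root tracks the full cubic root inside its regime."""
    p = cc.Params(eta=eta)
    ap = nu_approximations(p, e_eff)
    assert ap["recommended_label"] == label
    nu, _, _ = nu_star_cubic(p, e_eff)
    assert ap["recommended"] == pytest.approx(nu, rel=0.05)


def test_no_reduced_form_in_high_immunity_intermediate_eta(defaults):
    ap = nu_approximations(defaults, 0.4)
    assert ap["recommended_label"] == "full cubic root"
    assert np.isnan(ap["recommended"])
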