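"""Clone-level analytics: establishment, extinction times, and emergent diversity.

A new phage mutant is a single individual in a background of totals at steady
state.  Its early life is a branching process with

    birth-event rate  beta0 = alpha pV nB      (each event yields B offspring)
    death rate        delta0 = F + alpha nB (1 - pV)
    net growth rate   s0 = beta0 (B - 1) - delta0 = alpha nB (B pV - 1) - F

The probability that the clone escapes early stochastic extinction
(establishment) is Pest = 2 s0 / (B (s0 + delta0)) to first order in s0.
Once large, a clone of size nVi in a total phage population nV goes extinct
after a mean time

    Text = 2 nVi (1 - ln(nVi / nV)) / ((B - 1)(2 beta + delta))   [minutes]

with the per-capita clone birth/death rates beta = alpha pV (nB - e nBi) and
delta = F + alpha nB (1 - pV) + alpha pV e nBi.  Multiplying by gC0 converts
to bacterial generations; all internal computation stays in minutes and the
conversion happens only at the reporting boundary.

The steady-state diversity m (number of coexisting bacterial clones, equal to
the number of large phage clones) solves the self-consistency

    m = Pest * mu_bar * Text

where mu_bar is the effective rate of new phage mutants per generation.  A
closed form follows from the low-immunity approximations: m^3 = a (1 + ln m)
with the combined parameter a ~ 4 e mu L eta_hat (g C0 (1-f))^3 /
(B^2 alpha^2 pV^3 r), so m grows like the 1/3 power of (e eta mu).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import exp1

from . import meanfield
from .params import Params

__all__ = [
    "TheoryBundle",
    "establishment_probability",
    "establishment_probability_steady",
    "branching_extinction_oracle",
    "large_clone_extinction_time",
    "effective_mutation_rate",
    "predict_diversity",
    "solve_m_closed_form",
    "m_perturbative",
    "diversity_a",
    "pest_closed_form",
    "clone_dynamics",
    "acquisition_time",
    "predict_speed",
    "theory_bundle",
]


@dataclass(frozen=True)
class TheoryBundle:
    """Derived deterministic and clone-level quantities for one parameter set."""

    A: float
    pV0: float
    nB_tilde: float
    nV_tilde: float
    s0: float                 # min^-1, at the self-consistent steady state
    delta0: float             # min^-1
    beta0: float              # min^-1
    Pest: float
    mu_bar: float             # new mutants per generation
    Text: float               # generations
    m_pred: Optional[float]   # self-consistent diversity (None if no solution)
    diversity_a: float        # combined parameter, approximate (large-B) form
    m_closed_form: float      # root of m^3 = a (1 + ln m)
    v_pred: float             # mutational distance per generation (1 / Text)
    v_closed_form: float
    em_star: float


def _rates(params: Params, nB: float) -> Tuple[float, float, float]:
    al, pV, F, B = params.alpha, params.pV, params.F, params.B
    beta0 = al * nB * pV
    delta0 = F + al * nB * (1.0 - pV)
    s0 = al * nB * (B * pV - 1.0) - F
    return s0, delta0, beta0


def establishment_probability(params: Params, nB: float) -> float:
    """Pest = max(0, 2 s0 / (B (s0 + delta0))) for a lone mutant in background nB."""
    if nB <= 0:
        raise ValueError("nB must be positive")
    s0, delta0, beta0 = _rates(params, nB)
    assert s0 + delta0 > 0, "s0 + delta0 = beta0 (B - 1) must be positive"
    return max(0.0, 2.0 * s0 / (params.B * (s0 + delta0)))


def establishment_probability_steady(params: Params, nu: float, m: float) -> float:
    """Steady-state form Pest = 2 e nu / (m (B - 1)).

    Follows from evaluating s0 and delta0 at the coexistence totals, where
    the phage stationarity ties nB to the average immunity e nu / m.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    return max(0.0, 2.0 * params.e * nu / (m * (params.B - 1.0)))


def branching_extinction_oracle(beta0: float, delta0: float, B: int,
                                tol: float = 1e-13) -> float:
    """Survival probability of a continuous-time burst branching process.

    An individual dies at rate delta0 and at rate beta0 is replaced by B
    copies.  The extinction probability q is the smallest root in [0, 1] of

        delta0 + beta0 q^B = (delta0 + beta0) q

    and the survival probability is 1 - q.  This is the independent oracle
    for the first-order establishment formula.
    """
    if beta0 < 0 or delta0 < 0:
        raise ValueError("rates must be non-negative")
    if beta0 == 0 or beta0 * (B - 1) <= delta0:
        return 0.0

    def phi(q: float) -> float:
        return delta0 + beta0 * q ** B - (delta0 + beta0) * q

    # q = 1 is always a root; the extinction probability is the root below 1.
    lo, hi = 0.0, 1.0 - 1e-12
    if phi(hi) >= 0:  # supercritical guaranteed above, but guard degenerate cases
        return 0.0
    q = brentq(phi, lo, hi, xtol=tol)
    return 1.0 - q


def large_clone_extinction_time(params: Params, nVi: float, nV: float,
                                nBi: Optional[float] = None,
                                m: Optional[float] = None,
                                nB: Optional[float] = None,
                                e_eff: Optional[float] = None) -> Dict[str, float]:
    """Mean extinction time of a large phage clone (full and approximate forms).

    ``nBi`` is the matching bacterial clone size (defaults to nBs/m via the
    equal-clone assumption when ``m`` is given with mean-field totals).
    Returns a dict with the full form in minutes and generations and the
    closed-form approximation (generations)

        Text ~ 2 (1 + ln m) (nV~ / m) (1 - 1/(B pV)) / (f (B - 1)).
    """
    if not 0 < nVi <= nV:
        raise ValueError("need 0 < nVi <= nV")
    B, al, pV, F = params.B, params.alpha, params.pV, params.F
    if nB is None:
        nB_t, _ = meanfield.no_crispr_steady_state(params)
        nB = nB_t
    if nBi is None:
        nBi = 0.0
    beta = al * pV * (nB - params.e * nBi)
    delta = F + al * nB * (1.0 - pV) + al * pV * params.e * nBi
    t_min = 2.0 * nVi * (1.0 - np.log(nVi / nV)) / ((B - 1.0) * (2.0 * beta + delta))
    out = {"Text_minutes": t_min, "Text_generations": t_min * params.gC0}
    if m is not None:
        _, nV_t = meanfield.no_crispr_steady_state(params)
        out["Text_approx_generations"] = (
            2.0 * (1.0 + np.log(m)) * (nV_t / m) * (1.0 - 1.0 / (B * pV))
            / (params.f * (B - 1.0)))
    return out


def effective_mutation_rate(params: Params, nB: float, nV: float, nu: float,
                            m: float) -> float:
    """New phage mutants per bacterial generation.

    mu_bar = alpha B (1 - exp(-mu L)) pV nV nB (1 - e nu / m) / gC0:
    the mean-field phage reproduction rate times the probability of at least
    one flip per burst, converted to per-generation units.
    """
    al, B, pV = params.alpha, params.B, params.pV
    p_mut = 1.0 - np.exp(-params.mu * params.L)
    return al * B * p_mut * pV * nV * nB * (1.0 - params.e * nu / m) / params.gC0


def diversity_a(params: Params) -> Dict[str, float]:
    """Combined diversity parameter a, exact-nu~ and large-B approximate forms.

    exact:  a = 4 e nu~ nV~^2 (1 - exp(-mu L)) / (B - 1)^2
    approx: a ~ 4 e mu L eta_hat (g C0 (1 - f))^3 / (B^2 alpha^2 pV^3 r)
    """
    e, B, mu, L = params.e, params.B, params.mu, params.L
    eta_hat = params.eta * (1.0 - params.pV)
    _, nV_t = meanfield.no_crispr_steady_state(params)
    nu_tilde = 1.0 / (1.0 + params.r / (eta_hat * params.alpha * nV_t))
    a_exact = 4.0 * e * nu_tilde * nV_t ** 2 * (1.0 - np.exp(-mu * L)) / (B - 1.0) ** 2
    a_approx = (4.0 * e * mu * L * eta_hat * (params.gC0 * (1.0 - params.f)) ** 3
                / (B ** 2 * params.alpha ** 2 * params.pV ** 3 * params.r))
    return {"a_exact": a_exact, "a_approx": a_approx}


def solve_m_closed_form(a: float, tol: float = 1e-12) -> float:
    """Numerically solve m^3 = a (1 + ln m) for m >= tiny; returns 0 for a <= 0.

    Values below 1 are still returned (flagged sub-1 by callers): the closed
    form loses meaning when the predicted diversity drops below one clone.
    """
    if a <= 0:
        return 0.0
    m = max(a ** (1.0 / 3.0), 1e-6)
    for _ in range(200):
        m_new = (a * (1.0 + np.log(m))) ** (1.0 / 3.0) if (1.0 + np.log(m)) > 0 else m / 2
        if abs(m_new - m) < tol * max(1.0, m):
            return float(m_new)
        m = m_new
    return float(m)


def m_perturbative(a: float) -> float:
    """Perturbative solution of m^3 = a (1 + ln m) around z0 = (ln a + 3) / 3."""
    if a <= 1.0:
        return float("nan")
    la = np.log(a)
    z0 = (la + 3.0) / 3.0
    return float((a * (la + 3.0) * (la + np.log((la + 3.0) / 3.0) + 2.0)
                  / (3.0 * (la + 2.0))) ** (1.0 / 3.0))


def pest_closed_form(params: Params) -> float:
    """Closed-form establishment probability in the low-immunity, large-B limit.

    Pest ~ [2 (e eta (1 - pV) alpha)^2 / (mu L B r^2)]^(1/3); obtained by
    composing Pest = 2 e nu / (m (B - 1)), the nu~ limit and the closed form
    for m (kept as a unit test).
    """
    eta_hat = params.eta * (1.0 - params.pV)
    num = 2.0 * (params.e * eta_hat * params.alpha) ** 2
    den = params.mu * params.L * params.B * params.r ** 2
    return float((num / den) ** (1.0 / 3.0))


def predict_diversity(params: Params, m_bounds: Tuple[float, float] = (1.0, 1e4),
                      n_grid: int = 120) -> Dict[str, object]:
    """Self-consistent steady-state diversity.

    Solves m = Pest(m) mu_bar(m) Text(m) with equal-clone sizes
    (nVi = nV/m, nBi = nBs/m) and mean-field totals evaluated at
    e_eff = e/m.  Returns a dict with ``m_solution`` (None when no m
    satisfies the balance — typical for parameters with small total
    population sizes), the combined parameter ``a`` in both forms, the closed
    form ``m_closed_form``, its perturbative variant and a
    ``clonal_interference`` flag (Text shorter than the spacer-acquisition
    timescale, where the balance overestimates diversity).
    """
    A, _ = meanfield.phage_threshold(params)
    if A <= 1:
        raise meanfield.PhageExtinctError("A <= 1: no phage coexistence")

    def balance(m: float) -> Tuple[float, Dict[str, float]]:
        st = meanfield.steady_state(params, min(1.0, params.e / m))
        tot = st.counts(params.C0)
        nB, nV, nBs = tot["nB"], tot["nV"], tot["nBs"]
        if st.phage_extinct or nV <= 0:
            return -m, {}
        pest = establishment_probability(params, nB)
        mu_bar = effective_mutation_rate(params, nB, nV, st.nu_star, m)
        text = large_clone_extinction_time(
            params, nVi=nV / m, nV=nV, nBi=nBs / m, nB=nB)["Text_generations"]
        comp = {"Pest": pest, "mu_bar": mu_bar, "Text": text,
                "nB": nB, "nV": nV, "nu": st.nu_star}
        return pest * mu_bar * text - m, comp

    grid = np.geomspace(m_bounds[0], m_bounds[1], n_grid)
    vals = []
    for m in grid:
        v, _ = balance(m)
        vals.append(v)
    vals = np.asarray(vals)
    # roots of Pest mu_bar Text - m; the self-consistent diversity is the
    # stable fixed point of m -> Pest mu_bar Text (balance decreasing through
    # zero); an unstable crossing below it separates the basin.
    roots = []
    for i in range(len(grid) - 1):
        if np.isfinite(vals[i]) and np.isfinite(vals[i + 1]) and vals[i] * vals[i + 1] < 0:
            r = brentq(lambda m: balance(m)[0], grid[i], grid[i + 1], xtol=1e-10)
            roots.append((r, vals[i] > vals[i + 1]))
    m_sol: Optional[float] = None
    comp: Dict[str, float] = {}
    stable = [r for r, s in roots if s]
    if stable:
        m_sol = max(stable)
    elif roots:
        m_sol = max(r for r, _ in roots)
    if m_sol is not None:
        _, comp = balance(m_sol)

    av = diversity_a(params)
    out: Dict[str, object] = {
        "m_solution": m_sol,
        "a_exact": av["a_exact"],
        "a_approx": av["a_approx"],
        "m_closed_form": solve_m_closed_form(av["a_approx"]),
        "m_perturbative": m_perturbative(av["a_approx"]),
        "components": comp,
        "clonal_interference": False,
    }
    if m_sol is not None and comp:
        # acquisition timescale 1/D with D = alpha eta_hat (nV/m) nB0 (per min)
        eta_hat = params.eta * (1.0 - params.pV)
        nB0 = comp["nB"] * (1.0 - comp["nu"])
        D = params.alpha * eta_hat * (comp["nV"] / m_sol) * nB0 / params.gC0
        if D > 0 and comp["Text"] < 1.0 / D:
            out["clonal_interference"] = True
            warnings.warn(
                "phage clones go extinct faster than bacteria acquire spacers "
                "(clonal-interference regime): the diversity balance is unreliable",
                stacklevel=2)
    return out


def clone_dynamics(params: Params, nB: float, nV: float, nB0: float, C: float,
                   horizon_minutes: float, nVi0: float = 1.0, nBi0: float = 0.0,
                   n_eval: int = 200) -> Dict[str, np.ndarray]:
    """Deterministic dynamics of one matching phage/bacteria clone pair.

    Integrates the coupled pair (back-mutation neglected, totals frozen at
    their steady-state values):

        dnVi/dt = -(F + alpha nB) nVi + alpha B P0 pV nVi (nB - e nBi)
        dnBi/dt = (g C - F - r) nBi - alpha pV nBi (nV - e nVi)
                  + alpha eta nB0 nVi (1 - pV)

    Also returns the 1-D analytic solutions (each clone against a frozen
    partner): nVi(t) = nVi(0) exp(s0 t) with s0 = alpha B pV nB e^(-mu L)
    - F - alpha nB, and the bacterial linear-growth solution, plus the fixed
    points nBi* and nVi*.
    """
    al, B, pV, F, g, r, e = (params.alpha, params.B, params.pV, params.F,
                             params.g, params.r, params.e)
    P0 = np.exp(-params.mu * params.L)
    eta = params.eta

    def rhs(t, y):
        nVi, nBi = y
        d_nVi = -(F + al * nB) * nVi + al * B * P0 * pV * nVi * (nB - e * nBi)
        d_nBi = ((g * C - F - r) * nBi - al * pV * nBi * (nV - e * nVi)
                 + al * eta * nB0 * nVi * (1.0 - pV))
        return [d_nVi, d_nBi]

    t_eval = np.linspace(0.0, horizon_minutes, n_eval)
    sol = solve_ivp(rhs, (0.0, horizon_minutes), [nVi0, nBi0], t_eval=t_eval,
                    rtol=1e-8, atol=1e-12)
    s0 = al * B * pV * nB * P0 - F - al * nB
    sB = g * C - F - r - al * pV * (nV - 0.0)
    delta_acq = al * eta * nB0 * nVi0 * (1.0 - pV)
    nVi_1d = nVi0 * np.exp(s0 * t_eval)
    if abs(sB) > 1e-300:
        nBi_1d = nBi0 * np.exp(sB * t_eval) + delta_acq / sB * (np.exp(sB * t_eval) - 1.0)
    else:
        nBi_1d = nBi0 + delta_acq * t_eval
    nBi_star = (nB - (F + al * nB) / (al * B * P0 * pV)) / e
    denom = al * eta * nB0 * (1.0 - pV) + al * pV * e * nBi_star
    nVi_star = nBi_star * (al * pV * nV - (g * C - F - r)) / denom
    return {
        "t": t_eval, "nVi": sol.y[0], "nBi": sol.y[1],
        "nVi_1d": nVi_1d, "nBi_1d": nBi_1d, "s0": s0,
        "nBi_star": float(nBi_star), "nVi_star": float(nVi_star),
    }


def acquisition_time(params: Params, s0: float, nB0: float) -> Dict[str, float]:
    """Timing of the first spacer acquisition from an exponentially growing clone.

    With acquisition rate a_acq = alpha eta (1 - pV) nB0 per phage and clone
    size n(t) = exp(s0 t), the first-acquisition density is

        P(t) = a_acq exp(s0 t) exp(-(a_acq/s0)(exp(s0 t) - 1))

    with mean <t> = (1/s0) exp(a_acq/s0) Gamma(0, a_acq/s0) and mean clone
    size floor n(<t>) = exp(s0 <t>).
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive (no exponential growth phase)")
    a_acq = params.alpha * params.eta * (1.0 - params.pV) * nB0
    if a_acq < 0:
        raise ValueError("acquisition rate must be non-negative")
    x = a_acq / s0
    t_mean = np.exp(x) * exp1(x) / s0
    return {
        "a_acq": a_acq,
        "t_mean_minutes": float(t_mean),
        "t_mean_generations": float(t_mean * params.gC0),
        "size_at_mean": float(np.exp(s0 * t_mean)),
    }


def acquisition_time_density(params: Params, s0: float, nB0: float,
                             t: np.ndarray) -> np.ndarray:
    """First-acquisition probability density P(t) (t in minutes)."""
    a_acq = params.alpha * params.eta * (1.0 - params.pV) * nB0
    t = np.asarray(t, dtype=float)
    return a_acq * np.exp(s0 * t) * np.exp(-(a_acq / s0) * (np.exp(s0 * t) - 1.0))


def predict_speed(params: Params, Text_generations: Optional[float] = None,
                  m: Optional[float] = None) -> Dict[str, float]:
    """Speed of evolution (mutational distance per generation).

    ``v = 1 / Text``: the population advances roughly one further mutation per
    large-clone turnover.  When only ``m`` is given, Text is taken from the
    closed-form approximation.  Also returns the fully closed form

        v ~ alpha B f [e mu eta L (1 - pV) / (2 alpha^2 B^2 r)]^(1/3)

    obtained by composing Text ~ 2 nV~ (1 - 1/(B pV)) / (f (B-1) m) with
    m ~ a^(1/3).
    """
    if Text_generations is None:
        if m is None:
            raise ValueError("give Text_generations or m")
        _, nV_t = meanfield.no_crispr_steady_state(params)
        Text_generations = (2.0 * (1.0 + np.log(m)) * (nV_t / m)
                            * (1.0 - 1.0 / (params.B * params.pV))
                            / (params.f * (params.B - 1.0)))
    if Text_generations <= 0:
        raise ValueError("Text must be positive")
    eta_hat = params.eta * (1.0 - params.pV)
    v_closed = (params.alpha * params.B * params.f
                * (params.e * params.mu * params.L * eta_hat
                   / (2.0 * params.alpha ** 2 * params.B ** 2 * params.r)) ** (1.0 / 3.0))
    return {"v": 1.0 / Text_generations, "Text": Text_generations,
            "v_closed_form": float(v_closed)}


def theory_bundle(params: Params) -> TheoryBundle:
    """Assemble the full set of derived quantities for one parameter set."""
    A, pV0 = meanfield.phage_threshold(params)
    nB_t, nV_t = meanfield.no_crispr_steady_state(params)
    div = predict_diversity(params)
    m = div["m_solution"]
    m_eff = m if m is not None else max(div["m_closed_form"], 1.0)
    st = meanfield.steady_state(params, min(1.0, params.e / m_eff))
    tot = st.counts(params.C0)
    s0, delta0, beta0 = _rates(params, tot["nB"])
    pest = establishment_probability(params, tot["nB"])
    mu_bar = effective_mutation_rate(params, tot["nB"], tot["nV"], st.nu_star, m_eff)
    text = large_clone_extinction_time(
        params, nVi=tot["nV"] / m_eff, nV=tot["nV"], nBi=tot["nBs"] / m_eff,
        nB=tot["nB"])["Text_generations"]
    sp = predict_speed(params, Text_generations=text)
    em = meanfield.critical_effective_e(params)
    return TheoryBundle(
        A=A, pV0=pV0, nB_tilde=nB_t, nV_tilde=nV_t, s0=s0, delta0=delta0,
        beta0=beta0, Pest=pest, mu_bar=mu_bar, Text=text,
        m_pred=m, diversity_a=div["a_approx"], m_closed_form=div["m_closed_form"],
        v_pred=sp["v"], v_closed_form=sp["v_closed_form"],
        em_star=em["em_star_full"])
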