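"""Deterministic total-population layer of the chemostat model.

The mean-field equations track four totals: bacteria with spacers ``nBs``,
phage ``nV``, naive bacteria ``nB0`` and nutrients ``C``,

    dnBs/dt = (g C - F - r) nBs + alpha (1-pV) eta nB0 nV - alpha nBs nV pVa
    dnV/dt  = -(F + alpha nB) nV + alpha B (pVa nBs + pV nB0) nV
    dnB0/dt = (g C - F) nB0 - alpha pV nB0 nV - alpha (1-pV) eta nB0 nV + r nBs
    dC/dt   = F (C0 - C) - g C nB

where ``pVa = pV (1 - e_eff)`` is the population-averaged success probability
of phage against spacer-bearing bacteria.  ``e_eff`` ("effective e") is an
explicit argument everywhere: theory callers pass ``e / m`` (spacer
effectiveness over the number of coexisting clones), analysis callers pass a
measured average immunity.

Phages persist deterministically iff the viability index

    A = (B pV - 1) (1 - f) alpha / (f g) > 1,

equivalently ``pV > pV0 = (g f / ((1-f) alpha) + 1) / B``.

The spacer-bearing fraction nu = nBs / nB at steady state is the physical root
of a cubic; its coefficients are constructed programmatically from the factored
stationarity conditions (safer than transcribing the expanded coefficients) and
the root is polished against the stationarity residual.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .params import Params

__all__ = [
    "SteadyState",
    "ode_rhs",
    "phage_threshold",
    "no_crispr_steady_state",
    "cubic_coefficients",
    "nu_star_cubic",
    "nu_approximations",
    "critical_effective_e",
    "steady_state",
]


class PhageExtinctError(ValueError):
    """Raised when a quantity is undefined because phages are deterministically extinct."""


@dataclass(frozen=True)
class SteadyState:
    """Deterministic fixed point of the total-population equations.

    ``x_star = nB / C0``, ``y_star = nV / C0``, ``nu_star = nBs / nB``,
    ``C_star`` the nutrient level (same units as C0).  ``regime`` labels the
    recommended dominant-balance approximation for nu in this parameter
    region; ``e_eff`` records the effective immunity used.
    """

    x_star: float
    y_star: float
    nu_star: float
    C_star: float
    regime: str
    e_eff: float
    phage_extinct: bool = False
    multiple_roots: bool = False

    def counts(self, C0: float) -> Dict[str, float]:
        nB = self.x_star * C0
        return {
            "nB": nB,
            "nV": self.y_star * C0,
            "nBs": self.nu_star * nB,
            "nB0": (1.0 - self.nu_star) * nB,
            "C": self.C_star,
        }


def ode_rhs(totals: Tuple[float, float, float, float], params: Params,
            e_eff: float) -> Tuple[float, float, float, float]:
    """Time derivatives (d/dt of nBs, nV, nB0, C) with pVa = pV (1 - e_eff)."""
    if not 0 <= e_eff <= 1:
        raise ValueError("e_eff must lie in [0, 1]")
    nBs, nV, nB0, C = totals
    g, F, r, al = params.g, params.F, params.r, params.alpha
    pV, B, eta = params.pV, params.B, params.eta
    pVa = pV * (1.0 - e_eff)
    nB = nBs + nB0
    d_nBs = (g * C - F - r) * nBs + al * (1 - pV) * eta * nB0 * nV - al * nBs * nV * pVa
    d_nV = -(F + al * nB) * nV + al * B * (pVa * nBs + pV * nB0) * nV
    d_nB0 = (g * C - F) * nB0 - al * pV * nB0 * nV - al * (1 - pV) * eta * nB0 * nV + r * nBs
    d_C = F * (params.C0 - C) - g * C * nB
    return (d_nBs, d_nV, d_nB0, d_C)


def phage_threshold(params: Params) -> Tuple[float, float]:
    """Viability index A and critical success probability pV0 (A > 1 iff pV > pV0)."""
    g, F, al = params.g, params.F, params.alpha
    f, B, pV = params.f, params.B, params.pV
    A = (B * pV - 1.0) * (1.0 - f) * al / (f * g)
    pV0 = (g * f / ((1.0 - f) * al) + 1.0) / B
    return A, pV0


def no_crispr_steady_state(params: Params) -> Tuple[float, float]:
    """Coexistence totals (nB~, nV~) when spacers confer no immunity (e_eff = 0).

    Requires A > 1; below the threshold the phage population has no positive
    fixed point.
    """
    A, _ = phage_threshold(params)
    if A <= 1:
        raise PhageExtinctError(f"A = {A:.4g} <= 1: phages are deterministically extinct")
    C0, g, f, al, pV = params.C0, params.g, params.f, params.alpha, params.pV
    nB = C0 * (1.0 - f) / A
    nV = g * C0 * f * (1.0 - f) * (A - 1.0) / (al * pV * (1.0 - f + A * f))
    return nB, nV


# ----------------------------------------------------------------------
# the cubic for nu
# ----------------------------------------------------------------------

def cubic_coefficients(params: Params, e_eff: float) -> np.ndarray:
    """Coefficients [cubic_a, cubic_b, cubic_c, cubic_d] of a nu^3 + b nu^2 + c nu + d.

    Built by expanding the factored stationarity condition

        (1 - nu) [-pV e_eff nu - eta_hat] [(1-f) p (pV B (1 - e_eff nu) - 1) - f pV]
            + R nu pV (1 - e_eff nu) (B p pV (1 - e_eff nu) - p + pV) = 0

    with ``p = pV alpha / g``, ``R = r/(g C0)`` and ``eta_hat = eta (1 - pV)``.
    (Named cubic_a..cubic_d to avoid collision with the combined diversity
    parameter ``a``.)
    """
    pV, B, f, R = params.pV, params.B, params.f, params.R
    p = pV * params.alpha / params.g
    eta_hat = params.eta * (1.0 - pV)
    P = np.polynomial.Polynomial
    one_minus = P([1.0, -e_eff])          # (1 - e_eff nu)
    t1 = P([1.0, -1.0])                   # (1 - nu)
    t2 = P([-eta_hat, -pV * e_eff])       # (-pV e_eff nu - eta_hat)
    t3 = (1 - f) * p * (pV * B * one_minus - 1.0) - f * pV
    t4 = R * pV * P([0.0, 1.0]) * one_minus * (B * p * pV * one_minus - p + pV)
    poly = t1 * t2 * t3 + t4
    coef = np.zeros(4)
    c = poly.coef
    coef[: len(c)] = c
    # return highest-degree first: [a, b, c, d]
    return coef[::-1]


def nu_star_cubic(params: Params, e_eff: float,
                  n_homotopy: int = 60) -> Tuple[float, str, bool]:
    """Physical root nu* in [0, 1] of the steady-state cubic.

    Returns ``(nu, regime, multiple)`` where ``regime`` is the Table-style
    dominant-balance label for this parameter region and ``multiple`` flags
    that more than one real root lay in [0, 1] (the root continuous with the
    e_eff -> 0 branch is returned, tracked by a short homotopy in e_eff).

    Raises ``ValueError`` if no root lies in [0, 1].
    """
    if not 0 <= e_eff <= 1:
        raise ValueError("e_eff must lie in [0, 1]")

    def roots_at(ee: float) -> np.ndarray:
        a, b, c, d = cubic_coefficients(params, ee)
        if abs(a) < 1e-300:
            rr = np.roots([b, c, d]) if abs(b) > 1e-300 else np.roots([c, d])
        else:
            rr = np.roots([a, b, c, d])
        rr = rr[np.abs(rr.imag) < 1e-8].real
        return rr[(rr > -1e-9) & (rr < 1 + 1e-9)]

    # continuation from e_eff = 0 where the physical root is unique
    nu = None
    multiple = False
    for ee in np.linspace(0.0, e_eff, max(2, n_homotopy)):
        cand = roots_at(ee)
        if cand.size == 0:
            raise ValueError(
                f"no steady-state root for nu in [0, 1] at e_eff={ee:.4g} "
                f"(coefficients {cubic_coefficients(params, ee)})")
        if nu is None:
            nu = float(cand.min())  # at e_eff=0 the bounded root is unique
        else:
            nu = float(cand[np.argmin(np.abs(cand - nu))])
        if ee == e_eff and cand.size > 1:
            multiple = True
    nu = min(1.0, max(0.0, nu))
    return nu, _regime_label(params, e_eff), multiple


def _regime_label(params: Params, e_eff: float) -> str:
    """Dominant-balance lookup: which reduced solution is recommended where.

    Rows by spacer-acquisition probability eta, columns by effective e;
    'drop-cubic&quadratic' is nu ~ -d/c, 'drop-a' the quadratic in (b, c, d),
    'drop-d' the quadratic in (a, b, c).  In the high-immunity /
    intermediate-eta corner no reduced form is reliable and the label is
    'full cubic root'.
    """
    eta = params.eta
    if eta <= 1e-5:
        row = ["drop-cubic&quadratic"] * 3 + ["drop-d"] * 2
    elif eta <= 1e-4:
        row = ["drop-cubic&quadratic"] * 2 + ["drop-a", "drop-d", "full cubic root"]
    elif eta < 1e-2:
        row = ["drop-cubic&quadratic"] * 2 + ["drop-a"] + ["full cubic root"] * 2
    else:
        row = ["drop-cubic&quadratic"] + ["drop-a"] * 2 + ["full cubic root"] * 2
    edges = [0.01, 0.05, 0.1, 0.5]
    col = sum(e_eff > x for x in edges)
    return row[col]


def nu_approximations(params: Params, e_eff: float) -> Dict[str, float]:
    """Closed-form dominant-balance approximations for nu.

    Returns the three reduced roots (``drop_a``, ``drop_d``, ``drop_ab``),
    the zero-immunity limit ``nu_tilde = 1 / (1 + r / (eta_hat alpha nV~))``,
    the large-e expansion ``large_e`` (exact eta_hat = 0 root at e_eff = 1
    plus a first-order eta_hat correction), and ``recommended`` per the
    dominant-balance lookup.  Values may diverge near the nu-denominator
    singularity; they are reported as computed (possibly outside [0, 1]).
    """
    a, b, c, d = cubic_coefficients(params, e_eff)
    out: Dict[str, float] = {}

    def safe(expr):
        try:
            v = expr()
            return float(v) if np.isfinite(v) else float("nan")
        except (ZeroDivisionError, FloatingPointError, ValueError):
            return float("nan")

    with np.errstate(invalid="ignore", divide="ignore"):
        out["drop_a"] = safe(lambda: (-c + np.sqrt(c * c - 4 * b * d)) / (2 * b))
        out["drop_d"] = safe(lambda: (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a))
        out["drop_ab"] = safe(lambda: -d / c)

    eta_hat = params.eta * (1.0 - params.pV)
    try:
        _, nV_t = no_crispr_steady_state(params)
        out["nu_tilde"] = 1.0 / (1.0 + params.r / (eta_hat * params.alpha * nV_t))
    except PhageExtinctError:
        out["nu_tilde"] = float("nan")

    out["large_e"] = _large_e_nu(params)

    label = _regime_label(params, e_eff)
    if label == "full cubic root":
        out["recommended"] = float("nan")
    else:
        out["recommended"] = {
            "drop-a": out["drop_a"],
            "drop-d": out["drop_d"],
            "drop-cubic&quadratic": out["drop_ab"],
        }[label]
    out["recommended_label"] = label  # type: ignore[assignment]
    return out


def _large_e_nu(params: Params) -> float:
    """nu at e_eff = 1 expanded to first order in eta_hat.

    At eta_hat = 0 and e_eff = 1 the cubic factors and the non-trivial root is
    exactly linear:

        nu0 = 1 - 1/(B pV) - (f + R) / ((1 - f - R) B p),   p = pV alpha / g.

    The O(eta_hat) correction is obtained by implicit differentiation of the
    cubic in eta (the cubic coefficients are affine in eta).
    """
    pV, B, f, R = params.pV, params.B, params.f, params.R
    p = pV * params.alpha / params.g
    nu0 = 1.0 - 1.0 / (B * pV) - (f + R) / ((1.0 - f - R) * B * p)
    # implicit d nu / d eta at eta = 0 via finite difference of the cubic root
    base = params.with_(eta=0.0)
    eps = 1e-7

    def root(pp: Params) -> float:
        a, b, c, d = cubic_coefficients(pp, 1.0)
        rr = np.roots([a, b, c, d])
        rr = rr[np.abs(rr.imag) < 1e-8].real
        rr = rr[(rr > -1e-9) & (rr < 1 + 1e-9)]
        if rr.size == 0:
            return float("nan")
        return float(rr[np.argmin(np.abs(rr - nu0))])

    d_nu = (root(base.with_(eta=eps)) - root(base)) / eps
    return nu0 + d_nu * params.eta


def critical_effective_e(params: Params) -> Dict[str, float]:
    """Critical effective immunity em* where the low-immunity branch diverges.

    At ``e_eff = em*`` the denominator of the low-average-immunity
    approximation for nu vanishes; substituting em* into the mean-field
    equations and letting eta -> 0 recovers the no-CRISPR totals.  Returns

    * ``em_star_full``: (A-1)(B pV - 1)(alpha eta_hat nV~ + r) /
      (alpha nV~ pV ((A-1)(B pV - 1) - A B eta_hat)),
    * ``em_star_series``: the two-term small-eta_hat series
      r / (alpha nV~ pV) + eta_hat / pV,
    * ``eta_sign_threshold``: the acquisition probability at which
      eta_hat A B = (A-1)(B pV - 1) (the third denominator term of the nu
      approximation changes sign; the series form is flagged invalid above it),
    * ``series_valid``: 1.0 if eta is below the sign threshold else 0.0.
    """
    A, _ = phage_threshold(params)
    if A <= 1:
        raise PhageExtinctError(f"A = {A:.4g} <= 1: no coexistence branch")
    pV, B = params.pV, params.B
    eta_hat = params.eta * (1.0 - pV)
    _, nV_t = no_crispr_steady_state(params)
    al, r = params.alpha, params.r
    denom = (A - 1.0) * (B * pV - 1.0) - A * B * eta_hat
    em_full = (A - 1.0) * (B * pV - 1.0) * (al * eta_hat * nV_t + r) / (al * nV_t * pV * denom)
    em_series = r / (al * nV_t * pV) + eta_hat / pV
    eta_thresh = (A - 1.0) * (B * pV - 1.0) / (A * B * (1.0 - pV))
    return {
        "em_star_full": em_full,
        "em_star_series": em_series,
        "eta_sign_threshold": eta_thresh,
        "series_valid": 1.0 if params.eta < eta_thresh else 0.0,
    }


def steady_state(params: Params, e_eff: float) -> SteadyState:
    """Full coexistence fixed point at a given effective immunity.

    Composes the cubic root nu* with the stationarity conditions:

        nB = F / (alpha (B pV (1 - e_eff nu*) - 1))          (phage equation)
        C  = F C0 / (F + g nB)                               (nutrient equation)
        nV = (g C - F) / (alpha pV (1 - e_eff nu*))          (bacteria equation)

    and polishes nu* with Newton steps on the spacer-fraction stationarity so
    the mean-field residual at the returned point is < 1e-8 relative.  In the
    phage-extinct regime returns the bacteria-only fixed point with y* = 0,
    flagged by ``phage_extinct``.
    """
    A, _ = phage_threshold(params)
    C0, g, F, al, pV, B = params.C0, params.g, params.F, params.alpha, params.pV, params.B
    eta_hat = params.eta * (1.0 - pV)
    r = params.r

    def totals_at(nu: float) -> Tuple[float, float, float]:
        eps = e_eff * nu
        denomB = al * (B * pV * (1.0 - eps) - 1.0)
        nB = F / denomB
        C = F * C0 / (F + g * nB)
        nV = (g * C - F) / (al * pV * (1.0 - eps))
        return nB, C, nV

    def resid(nu: float) -> float:
        nB, C, nV = totals_at(nu)
        # spacer-fraction stationarity, divided by nB
        return ((g * C - F - r) * nu + eta_hat * al * (1.0 - nu) * nV
                - al * nu * nV * pV * (1.0 - e_eff))

    extinct = False
    try:
        nu, regime, multiple = nu_star_cubic(params, e_eff)
        nB, C, nV = totals_at(nu)
        if A <= 1 or nV <= 0 or nB <= 0:
            extinct = True
    except (ValueError, ZeroDivisionError):
        extinct = True
        regime, multiple = "phage-extinct", False

    if extinct:
        # bacteria-only chemostat fixed point: gC = F, nB = C0 (1 - f)
        return SteadyState(x_star=(1.0 - params.f), y_star=0.0, nu_star=0.0,
                           C_star=params.f * C0, regime="phage-extinct",
                           e_eff=e_eff, phage_extinct=True)

    # Newton polish on the 1-D residual in nu
    for _ in range(60):
        rv = resid(nu)
        h = 1e-9 + 1e-7 * abs(nu)
        drv = (resid(nu + h) - rv) / h
        if drv == 0:
            break
        step = rv / drv
        nu_new = min(1.0, max(0.0, nu - step))
        if abs(nu_new - nu) < 1e-15:
            nu = nu_new
            break
        nu = nu_new

    nB, C, nV = totals_at(nu)
    st = SteadyState(x_star=nB / C0, y_star=nV / C0, nu_star=nu, C_star=C,
                     regime=regime, e_eff=e_eff, multiple_roots=multiple)
    # stationarity self-check
    tot = st.counts(C0)
    rhs = ode_rhs((tot["nBs"], tot["nV"], tot["nB0"], tot["C"]), params, e_eff)
    scale = max(F * C0, g * tot["C"] * tot["nB"], al * tot["nB"] * tot["nV"])
    rel = max(abs(v) for v in rhs) / scale
    if rel > 1e-8:
        raise RuntimeError(f"steady state residual {rel:.3g} exceeds 1e-8")
    return st
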