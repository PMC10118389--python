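"""Stochastic simulation of the full reaction catalogue in a chemostat.

Two engines share one reaction catalogue:

* ``gillespie_run`` — the exact stochastic simulation algorithm, tractable
  for small systems (guideline ``C0 <= 1e4``);
* ``tau_leap_run`` — tau-leaping with Poisson counts for the abundant
  channels and exact event-level handling of the rare ones (kills/bursts,
  spacer acquisitions).

Both produce a :class:`SimulationResult` with full clone-resolved snapshots
at the recording times, a dense totals table, and per-clone lifetime records
(birth, parent, establishment-ladder crossings, extinction, maximum size).

Times are minutes internally; reported "generations" are ``t * gC0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _engine
from .params import CrossReactivityMode, Params

__all__ = [
    "PopulationState",
    "CloneRecord",
    "SimulationResult",
    "RecordingSchedule",
    "default_schedule",
    "run_length_rule",
    "channel_rates",
    "gillespie_run",
    "tau_leap_run",
    "record_clones",
]

_XR_CODE = {
    CrossReactivityMode.NONE: 0,
    CrossReactivityMode.EXPONENTIAL: 1,
    CrossReactivityMode.STEP: 2,
}


@dataclass(frozen=True)
class PopulationState:
    """Integer counts of every tracked species at one time point."""

    t: float                       # minutes
    C: int
    nB0: int
    bacteria: Dict[int, int]       # spacer sequence -> count
    phage: Dict[int, int]          # protospacer sequence -> count

    @property
    def nBs(self) -> int:
        return sum(self.bacteria.values())

    @property
    def nB(self) -> int:
        return self.nB0 + self.nBs

    @property
    def nV(self) -> int:
        return sum(self.phage.values())


@dataclass(frozen=True)
class CloneRecord:
    """One clone lifetime (a sequence may have several, with disjoint spans)."""

    population: str                # "bacteria" | "phage"
    sequence: int
    parent: Optional[int]          # phage only (None for bacteria / founders)
    birth: float                   # minutes (first appearance)
    establishment: Optional[float] # minutes, first crossing of the threshold
    extinction: Optional[float]    # minutes (None if alive at run end)
    max_size: int
    ladder: np.ndarray = field(repr=False, default=None)  # first time size >= 2**k


@dataclass
class SimulationResult:
    snapshots: List[PopulationState]
    totals: pd.DataFrame           # t, generations, C, nB0, nBs, nV, m_bact, m_phage
    clones: List[CloneRecord]
    params: Params
    seed: int
    schedule: "RecordingSchedule"
    engine: str
    n_mutants: int                 # mutant phage individuals created
    n_clamped: int                 # tau-leap negative-count clamps (0 for SSA)

    def phage_clones(self) -> List[CloneRecord]:
        return [c for c in self.clones if c.population == "phage"]

    def bacteria_clones(self) -> List[CloneRecord]:
        return [c for c in self.clones if c.population == "bacteria"]


@dataclass(frozen=True)
class RecordingSchedule:
    """Snapshot and totals recording times, in bacterial generations."""

    t_end: float                         # generations
    snapshot_times: Tuple[float, ...]    # generations
    totals_every: float                  # generations
    steady_state_start: float            # generations


def run_length_rule(C0: float) -> Tuple[float, float]:
    """Default run length: max(10000, 10000 (log10 C0 - 3)) generations.

    Rounded half-away-from-zero to the nearest thousand; the steady-state
    analysis window starts at one fifth of the run.
    """
    if C0 <= 0:
        raise ValueError("C0 must be positive")
    raw = 10000.0 * (math.log10(C0) - 3.0)
    rounded = math.floor(abs(raw) / 1000.0 + 0.5) * 1000.0 * (1 if raw >= 0 else -1)
    gens = max(10000.0, rounded)
    return gens, gens / 5.0


def default_schedule(C0: float, n_snapshots: int = 15,
                     totals_every: float = 10.0) -> RecordingSchedule:
    """Default Table-2-style schedule: run-length rule plus ``n_snapshots``
    evenly spaced full snapshots over the steady-state window."""
    gens, ss = run_length_rule(C0)
    snaps = tuple(np.linspace(ss, gens, n_snapshots))
    return RecordingSchedule(t_end=gens, snapshot_times=snaps,
                             totals_every=totals_every, steady_state_start=ss)


def make_schedule(t_end: float, snapshot_times: Sequence[float],
                  totals_every: float = 10.0,
                  steady_state_start: Optional[float] = None) -> RecordingSchedule:
    if steady_state_start is None:
        steady_state_start = t_end / 5.0
    return RecordingSchedule(t_end=float(t_end),
                             snapshot_times=tuple(sorted(snapshot_times)),
                             totals_every=float(totals_every),
                             steady_state_start=float(steady_state_start))


def default_initial_state(params: Params, m_init: int = 1,
                          nV0: Optional[int] = None) -> PopulationState:
    """Chemostat start-up: C = C0, nB0 = C0 (1 - f), a clonal phage inoculum.

    ``m_init`` founder phage clones (single mutational neighbours of the
    all-zero ancestor beyond the first) share a total inoculum ``nV0``
    (default ``C0``, a multiplicity-of-infection-one-like dose).
    """
    C0 = params.C0
    if nV0 is None:
        nV0 = int(round(C0))
    per = max(1, nV0 // m_init)
    phage = {}
    for k in range(m_init):
        seq = 0 if k == 0 else (1 << ((k - 1) % params.L))
        phage[seq] = phage.get(seq, 0) + per
    return PopulationState(t=0.0, C=int(round(C0)),
                           nB0=int(round(C0 * (1.0 - params.f))),
                           bacteria={}, phage=phage)


def channel_rates(state: PopulationState, params: Params) -> Dict[str, float]:
    """Aggregate per-channel propensities (min^-1) at a state.

    The total adsorption propensity is ``alpha nB nV``; every adsorption
    consumes the infecting phage whatever the outcome (the initial mutant
    death rate delta0 = F + alpha nB (1 - pV) contains the full alpha nB).
    """
    g, F, r, al = params.g, params.F, params.r, params.alpha
    C, nB0, nBs, nV = state.C, state.nB0, state.nBs, state.nV
    nB = nB0 + nBs
    return {
        "nutrient_inflow": F * params.C0,
        "nutrient_outflow": F * C,
        "growth_naive": g * C * nB0,
        "growth_spacer": g * C * nBs,
        "outflow_naive": F * nB0,
        "outflow_spacer": F * nBs,
        "outflow_phage": F * nV,
        "spacer_loss": r * nBs,
        "adsorption": al * nB * nV,
    }


# ----------------------------------------------------------------------
# engine driver
# ----------------------------------------------------------------------

def _mutation_tables(params: Params) -> Tuple[float, np.ndarray]:
    """p1 = P(>=1 flip per offspring) and the cumulative distribution of the
    flip count conditioned on >= 1 (index k-1 for k flips)."""
    from scipy.stats import binom

    L, mu = params.L, params.mu
    if mu == 0.0:
        return 0.0, np.ones(L)
    ks = np.arange(1, L + 1)
    pmf = binom.pmf(ks, L, mu)
    p1 = 1.0 - binom.pmf(0, L, mu)
    cond = pmf / p1 if p1 > 0 else np.ones(L) / L
    return float(p1), np.cumsum(cond)


def _derive_seed(seed: int) -> int:
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31 - 1))


def _run(engine: str, params: Params, init: Optional[PopulationState],
         schedule: Optional[RecordingSchedule], seed: int,
         tau: Optional[float], leap_eps: float, adaptive: bool,
         stop_on_phage_extinction: bool,
         log_capacity: Optional[int], active_capacity: int) -> SimulationResult:
    if schedule is None:
        schedule = default_schedule(params.C0)
    if init is None:
        init = default_initial_state(params)
    gen_min = params.generation_minutes
    t_end_min = schedule.t_end * gen_min

    p1, mut_cum = _mutation_tables(params)
    xr_mode = _XR_CODE[params.xr.mode]
    theta = float(params.xr.theta)

    if log_capacity is None:
        # generous budget: expected mutants plus acquisitions plus slack
        exp_mut = (params.alpha * params.B * p1 * params.pV
                   * (25.0 * params.C0) * params.C0 / params.gC0) * schedule.t_end
        log_capacity = int(min(4e6, 8 * exp_mut + 2e4))

    cap_a = active_capacity
    sc = np.array([init.C, init.nB0], dtype=np.int64)
    bseq = np.zeros(cap_a, dtype=np.int64)
    bcount = np.zeros(cap_a, dtype=np.int64)
    brec = np.zeros(cap_a, dtype=np.int64)
    vseq = np.zeros(cap_a, dtype=np.int64)
    vcount = np.zeros(cap_a, dtype=np.int64)
    vrec = np.zeros(cap_a, dtype=np.int64)
    nact = np.zeros(8, dtype=np.int64)

    lpop = np.zeros(log_capacity, dtype=np.int64)
    lseq = np.zeros(log_capacity, dtype=np.int64)
    lparent = np.zeros(log_capacity, dtype=np.int64)
    lbirth = np.zeros(log_capacity, dtype=np.float64)
    lext = np.zeros(log_capacity, dtype=np.float64)
    lmax = np.zeros(log_capacity, dtype=np.int64)
    lcross = np.full((log_capacity, _engine.NLAD), -1.0)

    # initial clones
    for seq, cnt in init.bacteria.items():
        i = nact[_engine.IB]
        bseq[i], bcount[i] = seq, cnt
        rec = nact[_engine.ILOG]
        lpop[rec], lseq[rec], lparent[rec] = 0, seq, -1
        lbirth[rec], lext[rec], lmax[rec] = 0.0, -1.0, cnt
        brec[i] = rec
        nact[_engine.IB] += 1
        nact[_engine.ILOG] += 1
    for seq, cnt in init.phage.items():
        j = nact[_engine.IV]
        vseq[j], vcount[j] = seq, cnt
        rec = nact[_engine.ILOG]
        lpop[rec], lseq[rec], lparent[rec] = 1, seq, -1
        lbirth[rec], lext[rec], lmax[rec] = 0.0, -1.0, cnt
        vrec[j] = rec
        nact[_engine.IV] += 1
        nact[_engine.ILOG] += 1

    _engine.seed_rng(_derive_seed(seed))

    # recording times (minutes): union of totals grid and snapshot times
    tot_times = np.arange(schedule.totals_every, schedule.t_end + 1e-9,
                          schedule.totals_every) * gen_min
    snap_times = np.asarray(schedule.snapshot_times) * gen_min
    stops = np.unique(np.concatenate([tot_times, snap_times, [t_end_min]]))
    snap_set = set(np.round(snap_times, 6))

    args_common = (params.C0, params.g, params.F, params.r, params.alpha,
                   params.pV, params.e, params.eta, params.B, params.L,
                   p1, mut_cum, xr_mode, theta)

    if engine == "tau":
        work_kill = np.zeros(cap_a, dtype=np.int64)
        work_acq = np.zeros(cap_a, dtype=np.int64)
        work_nonkill = np.zeros(cap_a, dtype=np.int64)
        work_grow = np.zeros(cap_a, dtype=np.int64)
        work_out = np.zeros(cap_a, dtype=np.int64)
        work_loss = np.zeros(cap_a, dtype=np.int64)
        work_colsum = np.zeros(cap_a, dtype=np.float64)
        work_acqseq = np.zeros(4096, dtype=np.int64)
        tau_fixed = -1.0 if tau is None else float(tau)

    snapshots: List[PopulationState] = []
    totals_rows = []
    t = 0.0
    status = _engine.STATUS_OK
    for t_stop in stops:
        if engine == "gillespie":
            t, status = _engine.gillespie_core(
                t, t_stop, sc, bseq, bcount, brec, vseq, vcount, vrec, nact,
                lpop, lseq, lparent, lbirth, lext, lmax, lcross,
                *args_common, 4_000_000_000)
        else:
            t, status = _engine.tau_core(
                t, t_stop, sc, bseq, bcount, brec, vseq, vcount, vrec, nact,
                lpop, lseq, lparent, lbirth, lext, lmax, lcross,
                *args_common, tau_fixed, leap_eps, adaptive, 500_000_000,
                work_kill, work_acq, work_nonkill, work_grow, work_out,
                work_loss, work_colsum, work_acqseq)
        if status == _engine.STATUS_LOG_FULL:
            raise RuntimeError(
                "clone log capacity exceeded; re-run with a larger log_capacity")
        if status == _engine.STATUS_EVENT_BUDGET:
            raise RuntimeError("event budget exceeded in one recording segment")

        nb, nv = int(nact[_engine.IB]), int(nact[_engine.IV])
        nBs = int(bcount[:nb].sum())
        nV = int(vcount[:nv].sum())
        totals_rows.append({
            "t_minutes": t, "t_generations": t * params.gC0,
            "C": int(sc[0]), "nB0": int(sc[1]), "nBs": nBs, "nV": nV,
            "m_bacteria": nb, "m_phage": nv,
        })
        if round(t_stop, 6) in snap_set:
            snapshots.append(PopulationState(
                t=t, C=int(sc[0]), nB0=int(sc[1]),
                bacteria={int(bseq[i]): int(bcount[i]) for i in range(nb)},
                phage={int(vseq[j]): int(vcount[j]) for j in range(nv)}))
        if stop_on_phage_extinction and nV == 0:
            break

    nlog = int(nact[_engine.ILOG])
    clones = _records_from_log(
        lpop[:nlog], lseq[:nlog], lparent[:nlog], lbirth[:nlog], lext[:nlog],
        lmax[:nlog], lcross[:nlog])
    totals = pd.DataFrame(totals_rows)
    return SimulationResult(
        snapshots=snapshots, totals=totals, clones=clones, params=params,
        seed=seed, schedule=schedule, engine=engine,
        n_mutants=int(nact[_engine.IMUT]), n_clamped=int(nact[_engine.ICLAMP]))


def _records_from_log(lpop, lseq, lparent, lbirth, lext, lmax, lcross) -> List[CloneRecord]:
    out = []
    for i in range(len(lpop)):
        out.append(CloneRecord(
            population="phage" if lpop[i] == 1 else "bacteria",
            sequence=int(lseq[i]),
            parent=None if lparent[i] < 0 else int(lparent[i]),
            birth=float(lbirth[i]),
            establishment=None,
            extinction=None if lext[i] < 0 else float(lext[i]),
            max_size=int(lmax[i]),
            ladder=lcross[i].copy()))
    return out


def gillespie_run(params: Params, init: Optional[PopulationState] = None,
                  schedule: Optional[RecordingSchedule] = None, seed: int = 0,
                  stop_on_phage_extinction: bool = False,
                  log_capacity: Optional[int] = None,
                  active_capacity: int = 4096) -> SimulationResult:
    """Exact SSA trajectory; reproducible given ``seed``."""
    return _run("gillespie", params, init, schedule, seed, None, 0.1, False,
                stop_on_phage_extinction, log_capacity, active_capacity)


def tau_leap_run(params: Params, init: Optional[PopulationState] = None,
                 schedule: Optional[RecordingSchedule] = None, seed: int = 0,
                 tau: Optional[float] = None, leap_eps: float = 0.1,
                 adaptive: bool = False,
                 stop_on_phage_extinction: bool = False,
                 log_capacity: Optional[int] = None,
                 active_capacity: int = 4096) -> SimulationResult:
    """Tau-leaping trajectory.

    ``tau`` fixes the step (minutes); by default the step is chosen each
    iteration so the expected number of events per individual is at most
    ``leap_eps``.  With ``adaptive=True`` a step that would drive any count
    negative is halved and redrawn; otherwise residual negatives are clamped
    to zero and counted in ``n_clamped``.
    """
    if tau is not None and tau <= 0:
        raise ValueError("tau must be positive")
    return _run("tau", params, init, schedule, seed, tau, leap_eps, adaptive,
                stop_on_phage_extinction, log_capacity, active_capacity)


def record_clones(result: SimulationResult,
                  threshold: Optional[float] = None) -> List[CloneRecord]:
    """Clone records with establishment times filled in at a size threshold.

    ``threshold`` defaults to the measured steady-state mean phage clone size
    (total phage over number of phage clones, averaged over the steady-state
    window of the totals table).  Establishment times are read from the
    power-of-two first-crossing ladder at the smallest rung >= threshold, so
    they are quantized upward to ladder rungs; establishment *fractions* use
    the exact per-clone maximum size.
    """
    if threshold is None:
        threshold = measured_mean_clone_size(result, "phage")
    rung = max(0, int(math.ceil(math.log2(max(threshold, 1.0)))))
    rung = min(rung, _engine.NLAD - 1)
    out = []
    for c in result.clones:
        est = None
        if c.max_size >= threshold and c.ladder is not None:
            tcross = c.ladder[rung]
            est = float(tcross) if tcross >= 0 else None
        out.append(CloneRecord(
            population=c.population, sequence=c.sequence, parent=c.parent,
            birth=c.birth, establishment=est, extinction=c.extinction,
            max_size=c.max_size, ladder=c.ladder))
    return out


def measured_mean_clone_size(result: SimulationResult, population: str = "phage") -> float:
    """Mean clone size over the steady-state window of the totals table."""
    tot = result.totals
    ss = tot[tot["t_generations"] >= result.schedule.steady_state_start]
    if population == "phage":
        sizes = ss["nV"] / ss["m_phage"].clip(lower=1)
    else:
        sizes = ss["nBs"] / ss["m_bacteria"].clip(lower=1)
    return float(sizes.mean()) if len(sizes) else 0.0


def deterministic_clone_threshold(params: Params, m: float) -> float:
    """Alternative establishment threshold: deterministic nV* / m."""
    from . import meanfield
    st = meanfield.steady_state(params, min(1.0, params.e / m))
    return st.y_star * params.C0 / m
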