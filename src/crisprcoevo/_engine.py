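"""Numba cores for the exact (Gillespie) and tau-leaping simulators.

Both engines operate on flat preallocated arrays:

* active clones: parallel arrays of sequence words, counts and an index into
  the clone log (``bseq/bcount/brec`` for spacer-bearing bacteria,
  ``vseq/vcount/vrec`` for phage);
* a clone log holding one record per clone lifetime (population, sequence,
  parent, birth, extinction, maximum size and a power-of-two ladder of
  first-crossing times used to time establishment);
* small scalar carriers: ``sc = [C, nB0]`` and
  ``nact = [n_bact, n_phage, n_log, n_clamped, n_mutants]``.

The tau-leaping step draws Poisson counts for the abundant channels (flows,
growth, spacer loss, phage adsorption removals) and handles the rare channels
(successful infections -> bursts, spacer acquisitions) event by event, so a
kill chooses its victim exactly and bursts draw offspring mutations exactly as
in the SSA.  Adsorption removals are split by Poisson thinning into kill and
non-kill parts so the phage-side and bacteria-side bookkeeping stay
consistent.  Counts that a leap would drive negative are clamped to zero and
counted in ``nact[3]`` (the adaptive policy instead halves tau and redraws).

Engines use numba's global PRNG: seed once per run (``seed_rng``); runs are
reproducible given the seed but two runs must not be interleaved within one
process.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NLAD = 26  # establishment ladder: first time a clone reaches 2**k, k < NLAD

STATUS_OK = 0
STATUS_LOG_FULL = 1
STATUS_EVENT_BUDGET = 2

# indices into nact
IB, IV, ILOG, ICLAMP, IMUT = 0, 1, 2, 3, 4


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _pvij(d, pV, e, mode, theta):
    # mode: 0 none, 1 exponential, 2 step
    if mode == 1 and theta > 0.0:
        return pV * (1.0 - e * np.exp(-d / theta))
    if mode == 2:
        return pV * (1.0 - e) if d <= theta else pV
    return pV * (1.0 - e) if d == 0 else pV


@njit(cache=True, inline="always")
def _popcount(x):
    c = 0
    while x:
        x &= x - 1
        c += 1
    return c


@njit(cache=True)
def _log_new(lpop, lseq, lparent, lbirth, lext, lmax, nact, pop, seq, parent, t):
    i = nact[ILOG]
    if i >= lpop.shape[0]:
        return -1
    lpop[i] = pop
    lseq[i] = seq
    lparent[i] = parent
    lbirth[i] = t
    lext[i] = -1.0
    lmax[i] = 0
    nact[ILOG] = i + 1
    return i


@njit(cache=True, inline="always")
def _ladder(lmax, lcross, rec, count, t):
    if count > lmax[rec]:
        lmax[rec] = count
    k = 0
    while k < NLAD and count >= (1 << k):
        if lcross[rec, k] < 0.0:
            lcross[rec, k] = t
        k += 1


@njit(cache=True)
def _find(seqs, n, seq):
    for i in range(n):
        if seqs[i] == seq:
            return i
    return -1


@njit(cache=True)
def _remove_active(seqs, counts, recs, nact, which, idx, lext, t):
    n = nact[which] - 1
    lext[recs[idx]] = t
    seqs[idx] = seqs[n]
    counts[idx] = counts[n]
    recs[idx] = recs[n]
    nact[which] = n


@njit(cache=True)
def _sample_flip_count(mut_cum):
    u = np.random.random()
    for k in range(mut_cum.shape[0]):
        if u <= mut_cum[k]:
            return k + 1
    return mut_cum.shape[0]


@njit(cache=True)
def _flip_mask(k, L):
    mask = 0
    c = 0
    while c < k:
        bit = 1 << np.random.randint(0, L)
        if mask & bit == 0:
            mask |= bit
            c += 1
    return mask


@njit(cache=True)
def _burst(vseq, vcount, vrec, nact, lpop, lseq, lparent, lbirth, lext, lmax,
           lcross, j, n_events, t, B, p1, mut_cum, L):
    """Add n_events bursts of B offspring from phage clone j (index in actives).

    Returns -1 on log overflow, else 0.  Counts mutant individuals in
    nact[IMUT].
    """
    total = n_events * B
    mutants = np.random.binomial(total, p1) if p1 > 0.0 else 0
    parent_seq = vseq[j]
    vcount[j] += total - mutants
    _ladder(lmax, lcross, vrec[j], vcount[j], t)
    for _ in range(mutants):
        k = _sample_flip_count(mut_cum)
        child = parent_seq ^ _flip_mask(k, L)
        idx = _find(vseq, nact[IV], child)
        if idx < 0:
            rec = _log_new(lpop, lseq, lparent, lbirth, lext, lmax, nact,
                           1, child, parent_seq, t)
            if rec < 0:
                return -1
            idx = nact[IV]
            if idx >= vseq.shape[0]:
                return -1
            vseq[idx] = child
            vcount[idx] = 0
            vrec[idx] = rec
            nact[IV] = idx + 1
        vcount[idx] += 1
        _ladder(lmax, lcross, vrec[idx], vcount[idx], t)
    nact[IMUT] += mutants
    return 0


@njit(cache=True)
def _acquire(bseq, bcount, brec, nact, lpop, lseq, lparent, lbirth, lext, lmax,
             lcross, seq, t):
    """A naive bacterium acquires spacer ``seq`` (caller decrements nB0)."""
    idx = _find(bseq, nact[IB], seq)
    if idx < 0:
        rec = _log_new(lpop, lseq, lparent, lbirth, lext, lmax, nact,
                       0, seq, -1, t)
        if rec < 0:
            return -1
        idx = nact[IB]
        if idx >= bseq.shape[0]:
            return -1
        bseq[idx] = seq
        bcount[idx] = 0
        brec[idx] = rec
        nact[IB] = idx + 1
    bcount[idx] += 1
    _ladder(lmax, lcross, brec[idx], bcount[idx], t)
    return 0


# ----------------------------------------------------------------------
# exact SSA
# ----------------------------------------------------------------------

@njit(cache=True)
def gillespie_core(t0, t_stop, sc, bseq, bcount, brec, vseq, vcount, vrec,
                   nact, lpop, lseq, lparent, lbirth, lext, lmax, lcross,
                   C0, g, F, r, alpha, pV, e, eta, B, L, p1, mut_cum,
                   xr_mode, theta, max_events):
    """Statistically exact trajectory from t0 to t_stop.  Returns (t, status)."""
    t = t0
    events = 0
    while True:
        C = sc[0]
        nB0 = sc[1]
        nb = nact[IB]
        nv = nact[IV]
        SB = 0
        for i in range(nb):
            SB += bcount[i]
        SV = 0
        for j in range(nv):
            SV += vcount[j]
        nB = nB0 + SB

        a_inflow = F * C0
        a_outC = F * C
        a_grow0 = g * C * nB0
        a_growS = g * C * SB
        a_out0 = F * nB0
        a_outS = F * SB
        a_outV = F * SV
        a_loss = r * SB
        a_ads = alpha * nB * SV
        atot = (a_inflow + a_outC + a_grow0 + a_growS + a_out0 + a_outS
                + a_outV + a_loss + a_ads)
        if atot <= 0.0:
            return t_stop, STATUS_OK
        t += np.random.exponential(1.0 / atot)
        if t >= t_stop:
            return t_stop, STATUS_OK
        events += 1
        if events > max_events:
            return t, STATUS_EVENT_BUDGET

        u = np.random.random() * atot
        if u < a_inflow:
            sc[0] = C + 1
            continue
        u -= a_inflow
        if u < a_outC:
            sc[0] = C - 1
            continue
        u -= a_outC
        if u < a_grow0:
            sc[1] = nB0 + 1
            sc[0] = C - 1
            continue
        u -= a_grow0
        if u < a_growS:
            x = np.random.random() * SB
            acc = 0
            for i in range(nb):
                acc += bcount[i]
                if x < acc:
                    bcount[i] += 1
                    _ladder(lmax, lcross, brec[i], bcount[i], t)
                    break
            sc[0] = C - 1
            continue
        u -= a_growS
        if u < a_out0:
            sc[1] = nB0 - 1
            continue
        u -= a_out0
        if u < a_outS:
            x = np.random.random() * SB
            acc = 0
            for i in range(nb):
                acc += bcount[i]
                if x < acc:
                    bcount[i] -= 1
                    if bcount[i] == 0:
                        _remove_active(bseq, bcount, brec, nact, IB, i, lext, t)
                    break
            continue
        u -= a_outS
        if u < a_outV:
            x = np.random.random() * SV
            acc = 0
            for j in range(nv):
                acc += vcount[j]
                if x < acc:
                    vcount[j] -= 1
                    if vcount[j] == 0:
                        _remove_active(vseq, vcount, vrec, nact, IV, j, lext, t)
                    break
            continue
        u -= a_outV
        if u < a_loss:
            x = np.random.random() * SB
            acc = 0
            for i in range(nb):
                acc += bcount[i]
                if x < acc:
                    bcount[i] -= 1
                    sc[1] = nB0 + 1
                    if bcount[i] == 0:
                        _remove_active(bseq, bcount, brec, nact, IB, i, lext, t)
                    break
            continue
        # adsorption: one phage adsorbs to one bacterium and is consumed
        jj = 0
        x = np.random.random() * SV
        acc = 0
        for j in range(nv):
            acc += vcount[j]
            if x < acc:
                jj = j
                break
        pseq = vseq[jj]
        # target bacterium
        naive = False
        ii = -1
        x = np.random.random() * nB
        if x < nB0:
            naive = True
            pv = pV
        else:
            x -= nB0
            acc = 0
            for i in range(nb):
                acc += bcount[i]
                if x < acc:
                    ii = i
                    break
            d = _popcount(bseq[ii] ^ pseq)
            pv = _pvij(d, pV, e, xr_mode, theta)
        u2 = np.random.random()
        if u2 < pv:
            # phage wins: bacterium dies, burst (phage consumed, then B out)
            vcount[jj] -= 1
            if naive:
                sc[1] = nB0 - 1
            else:
                bcount[ii] -= 1
                if bcount[ii] == 0:
                    _remove_active(bseq, bcount, brec, nact, IB, ii, lext, t)
            st = _burst(vseq, vcount, vrec, nact, lpop, lseq, lparent, lbirth,
                        lext, lmax, lcross, jj, 1, t, B, p1, mut_cum, L)
            if st < 0:
                return t, STATUS_LOG_FULL
            if vcount[jj] == 0:
                _remove_active(vseq, vcount, vrec, nact, IV, jj, lext, t)
        else:
            # bacterium survives; phage is consumed regardless
            vcount[jj] -= 1
            if vcount[jj] == 0:
                _remove_active(vseq, vcount, vrec, nact, IV, jj, lext, t)
            if naive and np.random.random() < eta:
                st = _acquire(bseq, bcount, brec, nact, lpop, lseq, lparent,
                              lbirth, lext, lmax, lcross, pseq, t)
                if st < 0:
                    return t, STATUS_LOG_FULL
                sc[1] = nB0 - 1


# ----------------------------------------------------------------------
# tau-leaping
# ----------------------------------------------------------------------

@njit(cache=True)
def tau_core(t0, t_stop, sc, bseq, bcount, brec, vseq, vcount, vrec,
             nact, lpop, lseq, lparent, lbirth, lext, lmax, lcross,
             C0, g, F, r, alpha, pV, e, eta, B, L, p1, mut_cum,
             xr_mode, theta, tau_fixed, leap_eps, adaptive, max_steps,
             work_kill, work_acq, work_nonkill, work_grow, work_out, work_loss,
             work_colsum, work_acqseq):
    """Tau-leaping trajectory from t0 to t_stop.  Returns (t, status)."""
    t = t0
    steps = 0
    eta_hat = eta * (1.0 - pV)
    while t < t_stop:
        steps += 1
        if steps > max_steps:
            return t, STATUS_EVENT_BUDGET
        C = sc[0]
        nB0 = sc[1]
        nb = nact[IB]
        nv = nact[IV]
        SB = 0
        for i in range(nb):
            SB += bcount[i]
        SV = 0
        for j in range(nv):
            SV += vcount[j]
        nB = nB0 + SB

        # per-capita bound for the auto step
        if tau_fixed > 0.0:
            tau = tau_fixed
        else:
            pc = F
            if g * C > pc:
                pc = g * C
            if F + alpha * nB > pc:
                pc = F + alpha * nB
            if r + alpha * pV * SV > pc:
                pc = r + alpha * pV * SV
            if g * nB > pc:
                pc = g * nB
            tau = leap_eps / pc if pc > 0.0 else (t_stop - t)
        if t + tau > t_stop:
            tau = t_stop - t

        # kill-rate column sums per phage clone (spacer-bearing victims)
        for j in range(nv):
            work_colsum[j] = 0.0
        if xr_mode == 0:
            for i in range(nb):
                jm = _find(vseq, nv, bseq[i])
                if jm >= 0:
                    work_colsum[jm] += e * bcount[i]
            for j in range(nv):
                work_colsum[j] = pV * (SB - work_colsum[j])
        else:
            for j in range(nv):
                s = 0.0
                for i in range(nb):
                    d = _popcount(bseq[i] ^ vseq[j])
                    s += _pvij(d, pV, e, xr_mode, theta) * bcount[i]
                work_colsum[j] = s

        while True:  # tau-halving loop (adaptive policy)
            # --- draw all counts from the state at step start ---
            n_inflow = np.random.poisson(F * C0 * tau)
            n_outC = np.random.poisson(F * C * tau)
            n_grow0 = np.random.poisson(g * C * nB0 * tau)
            n_out0 = np.random.poisson(F * nB0 * tau)
            for i in range(nb):
                work_grow[i] = np.random.poisson(g * C * bcount[i] * tau)
                work_out[i] = np.random.poisson(F * bcount[i] * tau)
                work_loss[i] = np.random.poisson(r * bcount[i] * tau)
                work_kill[i] = 0
            n_kill_naive = 0
            for j in range(nv):
                lam_kill = alpha * vcount[j] * (work_colsum[j] + pV * nB0)
                lam_rest = alpha * vcount[j] * nB - lam_kill
                if lam_rest < 0.0:
                    lam_rest = 0.0
                kj = np.random.poisson(lam_kill * tau)
                work_acq[j] = kj  # reuse as kill count per phage clone
                work_nonkill[j] = (np.random.poisson(lam_rest * tau)
                                   + np.random.poisson(F * vcount[j] * tau))
                # choose victims now so bacteria-side totals are known
                for _ in range(kj):
                    x = np.random.random() * (work_colsum[j] + pV * nB0)
                    if x < pV * nB0:
                        n_kill_naive += 1
                    else:
                        x -= pV * nB0
                        acc = 0.0
                        if xr_mode == 0:
                            jmatch = -1
                            for i in range(nb):
                                w = pV * bcount[i]
                                if bseq[i] == vseq[j]:
                                    w = pV * (1.0 - e) * bcount[i]
                                acc += w
                                if x < acc:
                                    work_kill[i] += 1
                                    break
                        else:
                            for i in range(nb):
                                d = _popcount(bseq[i] ^ vseq[j])
                                acc += _pvij(d, pV, e, xr_mode, theta) * bcount[i]
                                if x < acc:
                                    work_kill[i] += 1
                                    break
            n_acq = np.random.poisson(alpha * eta_hat * nB0 * SV * tau) if SV > 0 else 0
            if n_acq > work_acqseq.shape[0]:
                nact[ICLAMP] += n_acq - work_acqseq.shape[0]
                n_acq = work_acqseq.shape[0]
            for k in range(n_acq):
                # spacer source sampled from step-start phage abundances
                x = np.random.random() * SV
                acc = 0
                work_acqseq[k] = vseq[0] if nv > 0 else -1
                for j in range(nv):
                    acc += vcount[j]
                    if x < acc:
                        work_acqseq[k] = vseq[j]
                        break

            # --- validate (adaptive) ---
            if adaptive and tau > 1e-6:
                bad = False
                if C + n_inflow - n_outC - n_grow0 < 0:
                    bad = True
                loss_tot = 0
                for i in range(nb):
                    loss_tot += work_loss[i]
                    if (bcount[i] + work_grow[i] - work_out[i] - work_loss[i]
                            - work_kill[i]) < 0:
                        bad = True
                if nB0 + n_grow0 - n_out0 - n_kill_naive - n_acq + loss_tot < 0:
                    bad = True
                for j in range(nv):
                    if vcount[j] - work_nonkill[j] - work_acq[j] < 0:
                        bad = True
                if bad:
                    tau *= 0.5
                    continue
            break

        t_new = t + tau

        # --- apply: nutrients and naive bacteria ---
        growS_tot = 0
        for i in range(nb):
            growS_tot += work_grow[i]
        newC = C + n_inflow - n_outC - n_grow0 - growS_tot
        if newC < 0:
            nact[ICLAMP] += 1
            newC = 0
        loss_tot = 0
        for i in range(nb):
            loss_tot += work_loss[i]
        newB0 = nB0 + n_grow0 - n_out0 - n_kill_naive + loss_tot
        # acquisitions applied below (bounded by available naive bacteria)
        sc[0] = newC

        # --- apply: bacteria clones ---
        for i in range(nb):
            nc = bcount[i] + work_grow[i] - work_out[i] - work_loss[i] - work_kill[i]
            if nc < 0:
                nact[ICLAMP] += 1
                nc = 0
            bcount[i] = nc
            _ladder(lmax, lcross, brec[i], nc, t_new)

        # --- apply: phage removals, then bursts ---
        for j in range(nv):
            nc = vcount[j] - work_nonkill[j] - work_acq[j]
            if nc < 0:
                nact[ICLAMP] += 1
                nc = 0
            vcount[j] = nc
        for j in range(nv):
            kj = work_acq[j]
            if kj > 0:
                st = _burst(vseq, vcount, vrec, nact, lpop, lseq, lparent,
                            lbirth, lext, lmax, lcross, j, kj, t_new, B, p1,
                            mut_cum, L)
                if st < 0:
                    return t_new, STATUS_LOG_FULL

        # --- acquisitions (spacer = protospacer of the adsorbed phage) ---
        for k in range(n_acq):
            if newB0 <= 0:
                break
            seq = work_acqseq[k]
            if seq < 0:
                continue
            st = _acquire(bseq, bcount, brec, nact, lpop, lseq, lparent,
                          lbirth, lext, lmax, lcross, seq, t_new)
            if st < 0:
                return t_new, STATUS_LOG_FULL
            newB0 -= 1
        if newB0 < 0:
            nact[ICLAMP] += 1
            newB0 = 0
        sc[1] = newB0

        # --- retire extinct clones (iterate from the end: swap-removal) ---
        i = nact[IB] - 1
        while i >= 0:
            if bcount[i] == 0:
                _remove_active(bseq, bcount, brec, nact, IB, i, lext, t_new)
            i -= 1
        j = nact[IV] - 1
        while j >= 0:
            if vcount[j] == 0:
                _remove_active(vseq, vcount, vrec, nact, IV, j, lext, t_new)
            j -= 1

        t = t_new
    return t, STATUS_OK
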