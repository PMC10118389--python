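"""Population-level statistics on clone-resolved abundance data.

The central summary is *average immunity*: the abundance-weighted mean
pairwise immunity between the bacterial and phage populations,

    1 - sum_ij nBi nVj pV(i, j) / (pV sum_ij nBi nVj),

which reduces, for exact type matching with perfect spacers (e = 1), to the
matched-overlap form sum_i nBi nVi / (NB NV).  Everything else here is built
around the same abundance tables: time-shifted immunity (host immunity
against past and future pathogens), type turnover, empirical establishment,
the centre-of-mass speed of evolution and spread in sequence space, clan
clustering, PCA trajectories and the Morisita-Horn similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA

from .params import CrossReactivity, Params
from .sequences import as_seq, kernel_success

__all__ = [
    "AbundanceSeries",
    "ShiftCurve",
    "average_immunity",
    "marginal_immunity",
    "time_shift_immunity",
    "turnover",
    "classify_large_clones",
    "empirical_establishment",
    "speed_and_spread",
    "cluster_clans",
    "pca_trajectories",
    "morisita_horn",
    "shift_asymmetry_test",
]

Counts = Mapping[object, float]


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------

@dataclass
class AbundanceSeries:
    """A time-indexed type x count table for one population.

    ``types`` may be sequence strings (0/1 words) or opaque labels; counts
    are non-negative and may be fractional after interpolation.  ``units``
    declares the time axis ("minutes", "generations", "days", ...).
    """

    times: np.ndarray              # increasing, shape (T,)
    types: List[str]
    counts: np.ndarray             # shape (T, n_types), >= 0
    population: str = "phage"      # "bacteria" | "phage"
    units: str = "generations"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.times), len(self.types)):
            raise ValueError("counts must have shape (n_times, n_types)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.types)) != len(self.types):
            raise ValueError("duplicate type labels")

    def at(self, i: int) -> Dict[str, float]:
        row = self.counts[i]
        return {t: float(c) for t, c in zip(self.types, row) if c > 0}

    def min_interval(self) -> float:
        return float(np.min(np.diff(self.times)))

    def interpolate(self, grid: np.ndarray) -> "AbundanceSeries":
        """Linear interpolation of counts onto ``grid`` (within the time range)."""
        grid = np.asarray(grid, dtype=float)
        if grid.min() < self.times[0] - 1e-9 or grid.max() > self.times[-1] + 1e-9:
            raise ValueError("grid extends beyond the observed time range")
        out = np.empty((len(grid), len(self.types)))
        for k in range(len(self.types)):
            out[:, k] = np.interp(grid, self.times, self.counts[:, k])
        return AbundanceSeries(grid, list(self.types), out, self.population, self.units)

    def trim(self, head: int = 0, tail: int = 0) -> "AbundanceSeries":
        """Drop the first ``head`` and last ``tail`` time points."""
        T = len(self.times)
        if head + tail >= T:
            raise ValueError("trimming removes every time point")
        sl = slice(head, T - tail if tail else T)
        return AbundanceSeries(self.times[sl], list(self.types),
                               self.counts[sl], self.population, self.units)

    @classmethod
    def from_snapshots(cls, snapshots, population: str, params: Params,
                       units: str = "generations") -> "AbundanceSeries":
        """Build a series from simulator snapshots (sequences serialized)."""
        from .sequences import seq_to_string
        tables = []
        times = []
        for s in snapshots:
            d = s.phage if population == "phage" else s.bacteria
            tables.append({seq_to_string(k, params.L): v for k, v in d.items()})
            times.append(s.t * params.gC0 if units == "generations" else s.t)
        types = sorted(set().union(*[set(d) for d in tables]) or set())
        counts = np.zeros((len(times), len(types)))
        idx = {t: k for k, t in enumerate(types)}
        for i, d in enumerate(tables):
            for t, c in d.items():
                counts[i, idx[t]] = c
        return cls(np.asarray(times), types, counts, population, units)


@dataclass(frozen=True)
class ShiftCurve:
    """Mean time-shifted statistic per signed delay."""

    delays: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def at_zero(self) -> float:
        i = int(np.argmin(np.abs(self.delays)))
        return float(self.mean[i])

    def peak_delay(self) -> float:
        return float(self.delays[int(np.argmax(self.mean))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delay": self.delays, "mean": self.mean,
                             "sd": self.sd, "n": self.n})


# ----------------------------------------------------------------------
# immunity statistics
# ----------------------------------------------------------------------

def _kernel_fn(params: Optional[Params], e: float, xr: Optional[CrossReactivity]):
    """Return pv(i, j) on labels: sequence-aware when labels parse as 0/1 words,
    delta-matching otherwise."""
    if params is not None:
        e = params.e
        xr = params.xr

    def pv(i: object, j: object) -> float:
        si, sj = str(i), str(j)
        if set(si) <= {"0", "1"} and set(sj) <= {"0", "1"} and len(si) == len(sj):
            d = bin(as_seq(si) ^ as_seq(sj)).count("1")
        else:
            d = 0 if si == sj else 10 ** 9
        return kernel_success(d, 1.0, e, xr)  # pV factors out of the ratio

    return pv


def average_immunity(bacteria: Counts, phage: Counts,
                     params: Optional[Params] = None, e: float = 1.0,
                     xr: Optional[CrossReactivity] = None) -> float:
    """Abundance-weighted mean pairwise immunity, in [0, 1].

    ``1 - sum nBi nVj pV(i,j) / (pV sum nBi nVj)``; the naive success
    probability pV cancels in the ratio.  With delta-matching and e = 1 this
    is the matched-count overlap sum_i nBi nVi / (NB NV).
    """
    NB = float(sum(bacteria.values()))
    NV = float(sum(phage.values()))
    if NB <= 0 or NV <= 0:
        raise ValueError("average immunity undefined for an empty population")
    pv = _kernel_fn(params, e, xr)
    acc = 0.0
    for i, nb in bacteria.items():
        for j, nv in phage.items():
            acc += nb * nv * pv(i, j)
    return 1.0 - acc / (NB * NV)


def marginal_immunity(focal_type: object, focal_side: str, other: Counts,
                      params: Optional[Params] = None, e: float = 1.0,
                      xr: Optional[CrossReactivity] = None) -> float:
    """Average immunity with one side collapsed to a single focal clone.

    ``focal_side`` is the population the focal clone belongs to ("bacteria"
    for a spacer clone against the whole phage population, "phage" for a
    protospacer clone against the whole bacterial population).
    """
    if focal_side not in ("bacteria", "phage"):
        raise ValueError("focal_side must be 'bacteria' or 'phage'")
    focal = {focal_type: 1.0}
    if focal_side == "bacteria":
        return average_immunity(focal, other, params, e, xr)
    return average_immunity(other, focal, params, e, xr)


def time_shift_immunity(bacteria: AbundanceSeries, phage: AbundanceSeries,
                        multiplier: float = 1.0,
                        trim_head: int = 0, trim_tail: int = 0,
                        params: Optional[Params] = None, e: float = 1.0,
                        xr: Optional[CrossReactivity] = None) -> ShiftCurve:
    """Average immunity of bacteria at t against phage at t + delay.

    Both series are interpolated onto a shared grid at the minimum sampling
    interval after trimming; for each signed delay on the grid the statistic
    is averaged over all valid t.  The result is multiplied by ``multiplier``
    (the mean number of protospacers per phage when types are data-derived;
    products above 1 are reported as-is).
    """
    b = bacteria.trim(trim_head, trim_tail)
    v = phage.trim(trim_head, trim_tail)
    lo = max(b.times[0], v.times[0])
    hi = min(b.times[-1], v.times[-1])
    if hi <= lo:
        raise ValueError("no overlapping time range after trimming")
    dt = min(b.min_interval(), v.min_interval())
    grid = np.arange(lo, hi + dt / 2, dt)
    bg = b.interpolate(grid)
    vg = v.interpolate(grid)
    T = len(grid)
    ks = range(-(T - 1), T)
    delays, means, sds, ns = [], [], [], []
    for k in ks:
        vals = []
        for i in range(T):
            j = i + k
            if not 0 <= j < T:
                continue
            bd, vd = bg.at(i), vg.at(j)
            if not bd or not vd:
                continue
            vals.append(average_immunity(bd, vd, params, e, xr) * multiplier)
        if not vals:
            continue
        delays.append(k * dt)
        means.append(float(np.mean(vals)))
        sds.append(float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
        ns.append(len(vals))
    return ShiftCurve(np.asarray(delays), np.asarray(means), np.asarray(sds),
                      np.asarray(ns))


def turnover(series: AbundanceSeries, delays: Optional[Sequence[float]] = None
             ) -> ShiftCurve:
    """Fraction of types present at t still present at t + delay.

    Presence means count > 0 on the interpolated grid; time points with no
    types present are excluded from the average.  Equals 1 at zero delay and
    is bounded by 1 everywhere.
    """
    dt = series.min_interval()
    grid = np.arange(series.times[0], series.times[-1] + dt / 2, dt)
    sg = series.interpolate(grid)
    present = sg.counts > 0
    T = len(grid)
    if delays is None:
        ks = range(0, T)
    else:
        ks = sorted({int(round(d / dt)) for d in delays})
    out_d, out_m, out_s, out_n = [], [], [], []
    for k in ks:
        vals = []
        for i in range(T - k):
            base = present[i]
            nbase = base.sum()
            if nbase == 0:
                continue
            vals.append((base & present[i + k]).sum() / nbase)
        if not vals:
            continue
        out_d.append(k * dt)
        out_m.append(float(np.mean(vals)))
        out_s.append(float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
        out_n.append(len(vals))
    return ShiftCurve(np.asarray(out_d), np.asarray(out_m), np.asarray(out_s),
                      np.asarray(out_n))


# ----------------------------------------------------------------------
# establishment
# ----------------------------------------------------------------------

def classify_large_clones(sizes: Sequence[float], pest: float,
                          n_est: float) -> Dict[str, float]:
    """Expected number of long-time survivors among observed clones.

    Each observed clone of size n below the cutoff ``n_est`` is weighted by
    its survival probability 1 - (1 - Pest)^n (per-individual survival
    compounded over the clone); clones at or above the cutoff count fully.
    """
    sizes = np.asarray(sizes, dtype=float)
    if np.any(sizes < 0):
        raise ValueError("sizes must be non-negative")
    w = np.where(sizes >= n_est, 1.0, 1.0 - (1.0 - pest) ** sizes)
    return {"estimated_count": float(w.sum()),
            "fraction_large": float(w.mean()) if len(w) else 0.0}


def empirical_establishment(clones, threshold: float,
                            window: Optional[Tuple[float, float]] = None,
                            gC0: Optional[float] = None) -> Dict[str, float]:
    """Fraction and per-generation rate of phage clones crossing a threshold.

    ``clones`` are CloneRecords; only phage clones born by mutation (with a
    parent) count as mutants.  ``window`` restricts births to a time interval
    in minutes (typically the steady-state window); the rate is per
    bacterial generation when ``gC0`` is given, else per minute.
    """
    phage = [c for c in clones if c.population == "phage" and c.parent is not None]
    if window is not None:
        phage = [c for c in phage if window[0] <= c.birth <= window[1]]
    if not phage:
        raise ValueError("no phage mutant clones in the window")
    n_est = sum(1 for c in phage if c.max_size >= threshold)
    frac = n_est / len(phage)
    rate = float("nan")
    if window is not None:
        span_min = window[1] - window[0]
        span = span_min * gC0 if gC0 else span_min
        rate = n_est / span if span > 0 else float("nan")
    return {"fraction_established": frac, "rate": rate,
            "n_mutant_clones": len(phage), "n_established": n_est}


# ----------------------------------------------------------------------
# sequence-space geometry
# ----------------------------------------------------------------------

def _seq_matrix(types: Sequence[object], L: Optional[int] = None) -> np.ndarray:
    seqs = [as_seq(t, None if not isinstance(t, str) else len(t)) for t in types]
    if L is None:
        L = max(len(t) for t in types) if types and isinstance(types[0], str) else 30
    bits = np.zeros((len(seqs), L))
    for i, s in enumerate(seqs):
        for k in range(L):
            bits[i, k] = (s >> k) & 1
    return bits


def centre_of_mass(types: Sequence[object], abundances: Sequence[float],
                   L: Optional[int] = None) -> np.ndarray:
    """Abundance-weighted per-site mean, a point in [0, 1]^L."""
    w = np.asarray(abundances, dtype=float)
    if w.sum() <= 0:
        raise ValueError("empty population")
    bits = _seq_matrix(list(types), L)
    return bits.T @ (w / w.sum())


def speed_and_spread(snapshots: Sequence[Tuple[float, Dict[object, float]]],
                     ancestor: object, L: Optional[int] = None) -> Dict[str, object]:
    """Centre-of-mass trajectory statistics in sequence space.

    ``snapshots`` is a sequence of (time_in_generations, {type: count}).
    Returns the centre-of-mass L1 distance from the ancestor per time point,
    the abundance-weighted mean L1 distance to the centre of mass (spread),
    the maximum distance reached, and the long-horizon speed: max distance
    divided by the elapsed generations.
    """
    if not snapshots:
        raise ValueError("no snapshots")
    anc_str = str(ancestor)
    Lg = L or (len(anc_str) if set(anc_str) <= {"0", "1"} else None)
    anc_bits = _seq_matrix([ancestor], Lg)[0]
    times, dists, spreads = [], [], []
    for t, table in snapshots:
        types = list(table.keys())
        w = np.asarray([table[k] for k in types], dtype=float)
        if w.sum() <= 0:
            continue
        bits = _seq_matrix(types, Lg)
        com = bits.T @ (w / w.sum())
        dists.append(float(np.abs(com - anc_bits).sum()))
        spreads.append(float((np.abs(bits - com).sum(axis=1) * (w / w.sum())).sum()))
        times.append(t)
    times = np.asarray(times)
    dists = np.asarray(dists)
    elapsed = times[-1] - times[0] if len(times) > 1 else float("nan")
    max_d = float(dists.max())
    return {
        "times": times, "distance": dists, "spread": np.asarray(spreads),
        "max_distance": max_d,
        "speed": max_d / elapsed if elapsed and elapsed > 0 else float("nan"),
    }


def cluster_clans(types: Sequence[object], abundances: Optional[Sequence[float]] = None,
                  cut: float = 2.0, L: Optional[int] = None) -> Dict[str, object]:
    """Single-linkage clans of sequences under the L1 metric.

    Merges happen strictly below ``cut`` (default 2), so clans are the
    connected components of the graph with edges between sequences one
    mutation apart: groups with no members closer than two mutations stay
    separate.  Abundances affect clan sizes only, never the partition.
    """
    types = list(types)
    if not types:
        raise ValueError("no sequences")
    if len(types) == 1:
        labels = np.zeros(1, dtype=int)
    else:
        bits = _seq_matrix(types, L)
        model = AgglomerativeClustering(n_clusters=None, distance_threshold=cut,
                                        metric="manhattan", linkage="single")
        labels = model.fit_predict(bits)
    n_clans = int(labels.max()) + 1
    sizes = np.zeros(n_clans)
    if abundances is None:
        for lab in labels:
            sizes[lab] += 1
    else:
        for lab, w in zip(labels, abundances):
            sizes[lab] += w
    return {"labels": labels, "n_clans": n_clans,
            "mean_clan_size": float(sizes.mean()), "clan_sizes": sizes}


def pca_trajectories(phage: AbundanceSeries, bacteria: AbundanceSeries
                     ) -> Dict[str, np.ndarray]:
    """Two-component PCA of relative clone abundances.

    The axes are fitted on the phage time series only (per-time-point
    normalized abundances over the union of types, zero-filled); both
    populations are then projected into the same coordinates.
    """
    if len(phage.times) < 2:
        raise ValueError("need at least two time points")
    all_types = sorted(set(phage.types) | set(bacteria.types))

    def rel_matrix(series: AbundanceSeries) -> np.ndarray:
        M = np.zeros((len(series.times), len(all_types)))
        idx = {t: k for k, t in enumerate(all_types)}
        for k, t in enumerate(series.types):
            M[:, idx[t]] = series.counts[:, k]
        tot = M.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        return M / tot

    Pv = rel_matrix(phage)
    Pb = rel_matrix(bacteria)
    pca = PCA(n_components=2)
    phage_xy = pca.fit_transform(Pv)
    bact_xy = pca.transform(Pb)
    return {"phage": phage_xy, "bacteria": bact_xy,
            "explained_variance_ratio": pca.explained_variance_ratio_,
            "times_phage": phage.times, "times_bacteria": bacteria.times}


# ----------------------------------------------------------------------
# similarity and tests
# ----------------------------------------------------------------------

def morisita_horn(x: Counts, y: Counts) -> float:
    """Morisita-Horn similarity between two abundance tables, in [0, 1]."""
    X = float(sum(x.values()))
    Y = float(sum(y.values()))
    if X <= 0 or Y <= 0:
        raise ValueError("Morisita-Horn undefined for an all-zero table")
    shared = set(x) & set(y)
    cross = sum(x[k] * y[k] for k in shared)
    sx = sum(v * v for v in x.values()) / X ** 2
    sy = sum(v * v for v in y.values()) / Y ** 2
    return 2.0 * cross / ((sx + sy) * X * Y)


def shift_asymmetry_test(zero_delay: Sequence[float], shifted: Sequence[float]
                         ) -> Dict[str, float]:
    """One-sided paired signed-rank test: shifted immunity < zero-delay immunity.

    Zero differences are dropped (the standard treatment; note the paper-scale
    use has small n, so ties matter).  Identical pairs throughout make the
    test degenerate: no asymmetry, reported as p = 1 with ``degenerate`` set.
    """
    z = np.asarray(zero_delay, dtype=float)
    s = np.asarray(shifted, dtype=float)
    if len(z) != len(s) or len(z) < 6:
        raise ValueError("need >= 6 paired observations")
    if np.all(z == s):
        return {"statistic": 0.0, "p_value": 1.0, "degenerate": True}
    res = wilcoxon(z, s, alternative="greater", zero_method="wilcox")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "degenerate": False}
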