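"""Toy models linking CRISPR array length, repertoire structure and immunity.

These closed-form and sampling models ask how the population-level average
immunity behaves when bacteria carry arrays of ``n`` spacers and phages carry
``x`` protospacers, under the organism-level rule that any shared element
makes the bacterium immune (e = 1).

Two headline results:

* array-length law: if a single spacer gives baseline immunity ``a1``, an
  array of ``n`` independently drawn spacers gives ``a_n = 1 - (1 - a1)^n``
  — diminishing returns, never reaching 1;
* with phage and bacterial diversity coupled, average immunity *decreases*
  as the shared sequence pool grows, for random assignment and
  successive-sweep phage structure alike; only when variation is confined to
  a single mutating protospacer position (all others conserved) can
  multi-spacer bacteria hold immunity near 1 across diversity levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

__all__ = [
    "ArrayScenario",
    "array_immunity",
    "assort_and_score",
    "strain_mixture_immunity",
    "set_overlap_immunity",
]


@dataclass(frozen=True)
class ArrayScenario:
    """Sampling scenario for assembling spacer arrays and protospacer sets.

    ``assignment`` controls phage repertoire structure: ``random`` draws each
    phage's ``x`` protospacers uniquely at random; ``successive-sweeps``
    changes the first k positions in phage k (sequential escape mutations in
    the previous mutant's background); ``last-position-only`` varies only the
    final protospacer (an initially clonal population mutating rapidly).
    ``length_law`` draws spacers-per-bacterium as constant, gaussian (sd 2)
    or exponential with mean ``n``; ``abundance_law`` samples spacers from the
    pool uniformly or with geometrically decaying weights over ranked types
    (the discrete stand-in for exponentially distributed abundances;
    ``abundance_mean`` sets the mean rank).
    """

    pool_size: int
    n_phage: int = 100
    x: int = 1                       # protospacers per phage
    n: int = 1                       # mean spacers per bacterium
    n_spacers_total: int = 1000
    length_law: str = "constant"     # constant | gaussian | exponential
    abundance_law: str = "uniform"   # uniform | exponential
    abundance_mean: float = 6.0
    assignment: str = "random"       # random | successive-sweeps | last-position-only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.x < 1 or self.n < 1:
            raise ValueError("x and n must be >= 1")
        if self.pool_size < self.x:
            raise ValueError("pool must hold at least x protospacers")
        if self.length_law not in ("constant", "gaussian", "exponential"):
            raise ValueError("unknown length law")
        if self.abundance_law not in ("uniform", "exponential"):
            raise ValueError("unknown abundance law")
        if self.assignment not in ("random", "successive-sweeps", "last-position-only"):
            raise ValueError("unknown assignment mode")


def array_immunity(a1: float, n: int) -> float:
    """Average immunity of an n-spacer array: a_n = 1 - (1 - a1)^n.

    Each additional spacer removes the same *fraction* of the remaining
    susceptibility, so immunity saturates: a_0 = 0, a_1 = a1, and a_n is
    increasing in n but bounded by 1.
    """
    if not 0 <= a1 <= 1:
        raise ValueError("a1 must lie in [0, 1]")
    if n < 0 or int(n) != n:
        raise ValueError("n must be a non-negative integer")
    return 1.0 - (1.0 - a1) ** n


def set_overlap_immunity(bacteria: Dict[frozenset, float],
                         phage: Dict[frozenset, float]) -> float:
    """Organism-level average immunity with e = 1 set-overlap matching.

    ``sum_IJ nBI nVJ [I cap J != empty] / (NB NV)`` over abundance tables
    keyed by frozen sets of spacer/protospacer identities.
    """
    NB = sum(bacteria.values())
    NV = sum(phage.values())
    if NB <= 0 or NV <= 0:
        raise ValueError("empty population")
    acc = 0.0
    for I, nb in bacteria.items():
        for J, nv in phage.items():
            if I & J:
                acc += nb * nv
    return acc / (NB * NV)


def _pool_weights(sc: ArrayScenario) -> np.ndarray:
    """Abundance law over ranked pool sequences (geometric stand-in for
    exponentially distributed abundances; mean rank ``abundance_mean``)."""
    if sc.abundance_law == "uniform":
        return np.ones(sc.pool_size) / sc.pool_size
    q = 1.0 / sc.abundance_mean
    w = (1.0 - q) ** np.arange(sc.pool_size)
    return w / w.sum()


def _phage_sets(sc: ArrayScenario, rng: np.random.Generator) -> List[frozenset]:
    pool = np.arange(sc.pool_size)
    w = _pool_weights(sc)
    sets: List[frozenset] = []
    if sc.assignment == "random":
        for _ in range(sc.n_phage):
            sets.append(frozenset(
                rng.choice(pool, size=sc.x, replace=False, p=w).tolist()))
    elif sc.assignment == "successive-sweeps":
        # phage k differs from the ancestor in its first k positions
        anc = rng.choice(pool, size=sc.x, replace=False, p=w).tolist()
        for k in range(sc.n_phage):
            arr = list(anc)
            kk = min(k, sc.x)
            for pos in range(kk):
                arr[pos] = int(rng.choice(pool, p=w))
            sets.append(frozenset(arr))
    else:  # last-position-only
        anc = rng.choice(pool, size=sc.x, replace=False, p=w).tolist()
        for _ in range(sc.n_phage):
            arr = list(anc)
            arr[-1] = int(rng.choice(pool, p=w))
            sets.append(frozenset(arr))
    return sets


def assort_and_score(scenario: ArrayScenario, replicates: int = 20
                     ) -> Dict[str, float]:
    """Sampled population average immunity for one scenario.

    Builds the phage protospacer sets under the assignment mode (protospacer
    picks weighted by the abundance law), draws ``n_spacers_total`` spacers
    uniformly from the multiset of protospacers carried by the phage
    population (how acquisition samples sequence space: abundant
    protospacers beget abundant spacers), partitions them into arrays under
    the length law, and scores the set-overlap average immunity.  Returns
    the replicate mean and standard deviation plus the realized diversity
    (unique types drawn).
    """
    vals = []
    divs = []
    rng0 = np.random.default_rng(scenario.seed)
    for rep in range(replicates):
        rng = np.random.default_rng(rng0.integers(2 ** 31 - 1))
        phage_sets = _phage_sets(scenario, rng)
        proto_multiset = np.array([s for ps in phage_sets for s in sorted(ps)])
        spacers = rng.choice(proto_multiset, size=scenario.n_spacers_total,
                             replace=True)
        # partition the sampled spacers into arrays (without replacement
        # within the sampled multiset)
        rng.shuffle(spacers)
        arrays: Dict[frozenset, float] = {}
        i = 0
        while i < len(spacers):
            if scenario.length_law == "constant":
                k = scenario.n
            elif scenario.length_law == "gaussian":
                k = max(1, int(round(rng.normal(scenario.n, 2.0))))
            else:
                k = max(1, int(round(rng.exponential(scenario.n))))
            arr = frozenset(spacers[i:i + k].tolist())
            if len(spacers) - i < k:
                break  # drop the final incomplete array
            arrays[arr] = arrays.get(arr, 0.0) + 1.0
            i += k
        if not arrays:
            raise ValueError("spacer budget exhausted before any complete array")
        phage_tab: Dict[frozenset, float] = {}
        for s in phage_sets:
            phage_tab[s] = phage_tab.get(s, 0.0) + 1.0
        vals.append(set_overlap_immunity(arrays, phage_tab))
        uniq: Set[int] = set()
        for a in arrays:
            uniq |= set(a)
        divs.append(len(uniq))
    return {"mean_immunity": float(np.mean(vals)),
            "sd_immunity": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "mean_diversity": float(np.mean(divs))}


def strain_mixture_immunity(m: int, include_surface: bool = False) -> float:
    """Initial average immunity of an m-strain CRISPR mixture vs one escape phage.

    Equal-proportion CRISPR strains, one escape phage able to infect exactly
    one of them, e = 1: immunity (m - 1)/m.  Including one surface-mutant
    strain (always immune) in equal proportion gives m/(m + 1).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if include_surface:
        return m / (m + 1.0)
    return (m - 1.0) / m
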