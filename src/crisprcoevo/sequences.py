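"""Binary spacer/protospacer sequences, mutation draws and the infection kernel.

Spacers and protospacers are binary words of length ``L`` (default 30).
Internally a sequence is an unsigned integer whose bit ``i`` is site ``i``
(position 0 = lowest bit); serialization is always a left-to-right 0/1 string
of length ``L`` with site 0 first, so the on-disk form is unambiguous.

The mutational distance between two sequences is the L1 (Hamming) distance:
the number of sites at which they differ, i.e. the number of point mutations
separating them.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Union

import numpy as np

from .params import CrossReactivity, CrossReactivityMode

SequenceLike = Union[int, str]


def seq_to_string(seq: int, L: int) -> str:
    """Serialize an integer sequence to a fixed-width 0/1 string (site 0 first)."""
    if seq < 0 or seq >> L:
        raise ValueError(f"sequence {seq} does not fit in {L} bits")
    return "".join("1" if (seq >> i) & 1 else "0" for i in range(L))


def string_to_seq(s: str, L: Optional[int] = None) -> int:
    """Parse a 0/1 string (site 0 first) back to an integer sequence."""
    if L is not None and len(s) != L:
        raise ValueError(f"expected a string of length {L}, got {len(s)}")
    if set(s) - {"0", "1"}:
        raise ValueError("sequence strings may only contain 0 and 1")
    return sum(1 << i for i, c in enumerate(s) if c == "1")


def as_seq(seq: SequenceLike, L: Optional[int] = None) -> int:
    """Coerce an int or 0/1 string to the integer representation."""
    if isinstance(seq, str):
        return string_to_seq(seq, L)
    return int(seq)


def hamming_distance(s1: SequenceLike, s2: SequenceLike, L: Optional[int] = None) -> int:
    """Number of point mutations separating two equal-length sequences.

    Symmetric, satisfies the triangle inequality, and bounded by ``L``.
    String inputs must have equal lengths; integer inputs are assumed to share
    the system's ``L``.
    """
    if isinstance(s1, str) and isinstance(s2, str) and len(s1) != len(s2):
        raise ValueError("sequences have different lengths")
    a, b = as_seq(s1, L), as_seq(s2, L)
    return int(bin(a ^ b).count("1"))


def draw_burst_offspring(
    parent: SequenceLike,
    B: int,
    mu: float,
    rng: np.random.Generator,
    L: int = 30,
) -> List[int]:
    """Draw the ``B`` offspring of one burst, flipping each bit with probability mu.

    Every one of the ``B * L`` bits mutates independently with probability
    ``mu``; offspring with no flips keep the parent type.  Mutation back to an
    existing type and multiple flips in one offspring are both permitted (the
    latter occurs roughly ``mu * L`` times as often as single flips).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 <= mu <= 1:
        raise ValueError("mu must lie in [0, 1]")
    p = as_seq(parent, L)
    if mu == 0.0:
        return [p] * B
    flips = rng.random((B, L)) < mu
    masks = (flips.astype(np.uint64) << np.arange(L, dtype=np.uint64)).sum(axis=1)
    return [int(p ^ int(m)) for m in masks]


def infection_success(
    spacer: Optional[SequenceLike],
    protospacer: SequenceLike,
    pV: float,
    e: float,
    xr: Optional[CrossReactivity] = None,
    L: Optional[int] = None,
) -> float:
    """Probability that a phage kills the bacterium it adsorbed to.

    ``spacer is None`` denotes a naive bacterium (probability ``pV``).  With a
    spacer at mutational distance ``d`` from the protospacer, the success
    probability is

    * all-or-nothing: ``pV (1 - e)`` iff ``d == 0``, else ``pV``;
    * exponential:    ``pV (1 - e * exp(-d / theta))``;
    * step:           ``pV (1 - e)`` iff ``d <= theta``, else ``pV``.

    ``theta == 0`` with mode ``exponential`` is defined as the all-or-nothing
    kernel (the limit of vanishing cross-reactivity radius).  The return value
    always lies in ``[pV (1 - e), pV]``.
    """
    if not 0 <= pV <= 1 or not 0 <= e <= 1:
        raise ValueError("pV and e must lie in [0, 1]")
    if spacer is None:
        return pV
    d = hamming_distance(spacer, protospacer, L)
    return kernel_success(d, pV, e, xr)


def kernel_success(d: int, pV: float, e: float, xr: Optional[CrossReactivity]) -> float:
    """Infection-success probability as a function of mutational distance ``d``."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    mode = CrossReactivityMode.NONE if xr is None else xr.mode
    theta = 0.0 if xr is None else xr.theta
    if mode is CrossReactivityMode.EXPONENTIAL and theta > 0:
        return pV * (1.0 - e * float(np.exp(-d / theta)))
    if mode is CrossReactivityMode.STEP:
        return pV * (1.0 - e) if d <= theta else pV
    # all-or-nothing (also the theta -> 0 limit of the exponential kernel)
    return pV * (1.0 - e) if d == 0 else pV


def pairwise_success_matrix(
    spacers: Iterable[SequenceLike],
    protospacers: Iterable[SequenceLike],
    pV: float,
    e: float,
    xr: Optional[CrossReactivity] = None,
    L: Optional[int] = None,
) -> np.ndarray:
    """Matrix of ``pV(i, j)`` for spacer rows against protospacer columns."""
    ss = [as_seq(s, L) for s in spacers]
    ps = [as_seq(p, L) for p in protospacers]
    out = np.empty((len(ss), len(ps)))
    for i, a in enumerate(ss):
        for j, b in enumerate(ps):
            out[i, j] = kernel_success(int(bin(a ^ b).count("1")), pV, e, xr)
    return out
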