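"""Model parameters for the chemostat bacteria-phage-CRISPR system.

All rates are stored per minute.  The natural per-capita scales are set by
the maximal bacterial growth rate ``gC0`` (default 2.4e-2 min^-1, i.e. a
41.7 min doubling-time equivalent for *S. thermophilus* in lab conditions);
"bacterial generations" used in reporting are ``t_minutes * gC0``.

The adsorption rate ``alpha`` scales inversely with the nutrient inflow
concentration ``C0`` (``alpha = 2e-2 / C0`` by default): exploring different
total population sizes at fixed ``alpha * C0`` corresponds to shrinking the
culture volume as ``C0`` decreases, and keeps the deterministic phase diagram
fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional


class CrossReactivityMode(str, Enum):
    NONE = "none"
    EXPONENTIAL = "exponential"
    STEP = "step"


@dataclass(frozen=True)
class CrossReactivity:
    """Shape of partial immunity as a function of spacer-protospacer distance.

    ``theta`` scales the mutational radius of cross-reactivity.  With mode
    ``none`` (or ``theta == 0``) immunity is all-or-nothing: only an exact
    spacer-protospacer match confers protection.
    """

    mode: CrossReactivityMode = CrossReactivityMode.NONE
    theta: float = 0.0

    def __post_init__(self) -> None:
        mode = CrossReactivityMode(self.mode)
        object.__setattr__(self, "mode", mode)
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        if mode is CrossReactivityMode.NONE and self.theta != 0:
            raise ValueError("mode 'none' requires theta == 0")


@dataclass(frozen=True)
class Params:
    """All model constants, single source of truth for rate conversions.

    Parameters
    ----------
    C0 : float
        Inflow nutrient concentration, in units of bacterial cell density.
    gC0 : float
        Maximal bacterial growth rate (min^-1); ``g = gC0 / C0``.
    f : float
        Normalized chemostat outflow in (0, 1); ``F = f * gC0`` (min^-1).
    alpha : float, optional
        Phage adsorption rate (min^-1 per pair).  Defaults to ``2e-2 / C0``.
    B : int
        Phage burst size.
    pV : float
        Probability of phage success against bacteria without a matching
        spacer.
    e : float
        Spacer effectiveness in [0, 1]: a matching spacer reduces phage
        success to ``pV * (1 - e)``.
    R : float
        Per-generation spacer-loss probability; ``r = R * gC0`` (min^-1).
    eta : float
        Probability that a surviving naive bacterium acquires a spacer.
    mu : float
        Phage mutation probability per base per replication.
    L : int
        Protospacer length (binary sites).
    xr : CrossReactivity
        Cross-reactivity kernel.
    """

    C0: float = 1e4
    gC0: float = 2.4e-2
    f: float = 0.3
    alpha: Optional[float] = None
    B: int = 170
    pV: float = 0.02
    e: float = 0.95
    R: float = 0.04
    eta: float = 1e-3
    mu: float = 1e-5
    L: int = 30
    xr: CrossReactivity = field(default_factory=CrossReactivity)

    def __post_init__(self) -> None:
        if self.alpha is None:
            object.__setattr__(self, "alpha", 2e-2 / self.C0)
        if self.C0 <= 0:
            raise ValueError("C0 must be positive")
        if self.gC0 <= 0 or self.alpha < 0 or self.R < 0:
            raise ValueError("rates must be non-negative (gC0 positive)")
        if not 0 < self.f < 1:
            raise ValueError("f must lie strictly between 0 and 1")
        if self.B < 2:
            raise ValueError("burst size B must be at least 2")
        for name in ("pV", "e", "eta", "mu"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.L < 1 or self.L > 62:
            raise ValueError("L must lie in [1, 62] (sequences are 64-bit words)")

    # -- derived rates (per minute) --------------------------------------
    @property
    def g(self) -> float:
        """Per-nutrient growth rate g = gC0 / C0 (min^-1)."""
        return self.gC0 / self.C0

    @property
    def F(self) -> float:
        """Chemostat flow rate F = f * gC0 (min^-1)."""
        return self.f * self.gC0

    @property
    def r(self) -> float:
        """Spacer loss rate r = R * gC0 (min^-1)."""
        return self.R * self.gC0

    @property
    def generation_minutes(self) -> float:
        """Duration of one bacterial generation, 1 / gC0 (minutes)."""
        return 1.0 / self.gC0

    def with_(self, **kwargs) -> "Params":
        """Return a copy with the given fields replaced.

        ``alpha`` is re-derived from ``C0`` unless given explicitly.
        """
        if "C0" in kwargs and "alpha" not in kwargs:
            kwargs["alpha"] = None
        return replace(self, **kwargs)
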