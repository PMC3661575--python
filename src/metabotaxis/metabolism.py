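"""Intrinsic metabolic dynamics: a bistable autocatalytic reaction system.

The model tracks two lumped concentrations: ``A``, the autocatalytic
metabolite pool, and ``F``, the environmental resource it feeds on.  The
kinetic scheme is the minimal mass-action autocatalysis

    2A + F  <-->  3A        (forward k_forward, backward k_backward)
    A       -->   (decay)   (first order, k_decay)

which yields

    dA/dt = k_forward * F * A**2  -  k_backward * A**3  -  k_decay * A.

For a fixed resource level the cubic factors as ``A * q(A)`` with
``q(A) = -k_backward*A**2 + k_forward*F*A - k_decay``: the origin is always
a stable "dead" equilibrium, and above a saddle-node bifurcation in ``F``
a stable viable branch and an unstable separatrix branch appear.

Two death boundaries make the system mortal: starvation when ``A`` falls
to ``A_death_low``, and an "osmotic crisis" (the modelled cell bursts)
when ``A`` reaches ``A_death_high``.  States between the boundaries are
*viable* if, at fixed ``F``, the intrinsic dynamics carry them to the
stable branch without touching either boundary, and *precarious*
otherwise — precarious states can only be rescued by behavior that
changes ``F``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "MetabolismParams",
    "SystemState",
    "EquilibriumSet",
    "RegionLabel",
    "metabolic_rate",
    "equilibria",
    "bifurcation_point",
    "classify_state",
    "calibrate_default_params",
    "bifurcation_scan",
]


@dataclass(frozen=True)
class MetabolismParams:
    """Rate constants and death boundaries of the autocatalytic system.

    Parameters
    ----------
    k_forward
        Rate constant of the autocatalytic forward reaction
        (concentration^-2 * time^-1).
    k_backward
        Rate constant of the backward reaction (concentration^-2 * time^-1).
    k_decay
        First-order degradation rate of the metabolite (time^-1).
    A_death_low
        Starvation boundary: the system is dead once ``A <= A_death_low``.
    A_death_high
        Osmotic-crisis boundary: the system is dead once
        ``A >= A_death_high``.
    """

    k_forward: float = 0.8
    k_backward: float = 0.2
    k_decay: float = 0.8
    A_death_low: float = 0.5
    A_death_high: float = 8.0

    def __post_init__(self) -> None:
        for name in ("k_forward", "k_backward", "k_decay"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not (0 <= self.A_death_low < self.A_death_high):
            raise ValueError(
                "death boundaries must satisfy 0 <= A_death_low < A_death_high"
            )

    @property
    def A_mid(self) -> float:
        """Midpoint between the two death boundaries."""
        return 0.5 * (self.A_death_low + self.A_death_high)


@dataclass(frozen=True)
class SystemState:
    """Instantaneous state: metabolite concentration ``A``, resource ``F``."""

    A: float
    F: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.A) and math.isfinite(self.F)):
            raise ValueError("state components must be finite")
        if self.A < 0 or self.F < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class EquilibriumSet:
    """Equilibria of the metabolism at one fixed resource level.

    ``dead_root`` (the origin) is always present.  Above the saddle-node
    bifurcation, ``unstable_root <= stable_root`` are the two positive
    roots of ``k_backward*A**2 - k_forward*F*A + k_decay = 0``; below it
    both are ``None``.  At the bifurcation they coincide.
    """

    dead_root: float = 0.0
    unstable_root: Optional[float] = None
    stable_root: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.unstable_root is None) != (self.stable_root is None):
            raise ValueError("optional roots must be both present or both absent")
        if self.unstable_root is not None:
            if not 0 < self.unstable_root <= self.stable_root:
                raise ValueError("roots must satisfy 0 < unstable <= stable")

    @property
    def roots(self) -> list[float]:
        """All equilibria, in increasing order."""
        out = [self.dead_root]
        if self.unstable_root is not None:
            out += [self.unstable_root, self.stable_root]
        return out


class RegionLabel(enum.Enum):
    """Viability classification of a single state (exactly one label)."""

    VIABLE = "viable"
    PRECARIOUS = "precarious"
    DEAD_LOW = "dead_low"
    DEAD_HIGH = "dead_high"


def _rate(A, F, p: MetabolismParams):
    """Raw kinetic law; accepts scalars or arrays, no validation."""
    return A * (F * p.k_forward * A - p.k_backward * A * A - p.k_decay)


def metabolic_rate(state: SystemState, p: MetabolismParams) -> float:
    """Instantaneous dA/dt of the intrinsic metabolism at ``state``.

    Zero exactly at the equilibria returned by :func:`equilibria`;
    positive between the unstable and stable branches (the metabolism
    grows), negative outside them.
    """
    return float(_rate(state.A, state.F, p))


def equilibria(F: float, p: MetabolismParams) -> EquilibriumSet:
    """All equilibria of ``dA/dt`` at fixed resource concentration ``F``.

    The origin is always returned.  The optional branch roots solve the
    quadratic factor ``k_backward*A**2 - k_forward*F*A + k_decay = 0``;
    their absence (``F`` below the bifurcation) is a valid result.
    """
    if not (math.isfinite(F) and F >= 0):
        raise ValueError(f"F must be finite and >= 0, got {F!r}")
    disc = (p.k_forward * F) ** 2 - 4.0 * p.k_backward * p.k_decay
    scale = (p.k_forward * F) ** 2 + 4.0 * p.k_backward * p.k_decay
    if -1e-12 * scale < disc < 0:
        disc = 0.0  # tangency at the saddle-node, up to roundoff
    if disc < 0:
        return EquilibriumSet()
    s = math.sqrt(disc)
    lo = (p.k_forward * F - s) / (2.0 * p.k_backward)
    hi = (p.k_forward * F + s) / (2.0 * p.k_backward)
    return EquilibriumSet(unstable_root=lo, stable_root=hi)


def bifurcation_point(p: MetabolismParams) -> float:
    """Resource level of the saddle-node bifurcation.

    Below ``F_bif = 2*sqrt(k_backward*k_decay)/k_forward`` only the dead
    equilibrium exists; above it the viable and unstable branches appear.
    """
    return 2.0 * math.sqrt(p.k_backward * p.k_decay) / p.k_forward


def classify_state(state: SystemState, p: MetabolismParams) -> RegionLabel:
    """Viable / precarious / dead classification at fixed ``F``.

    A living state is *viable* when the frozen-``F`` trajectory of ``A``
    converges to the stable branch without touching a death boundary.
    Because the 1-D dynamics are monotone between equilibria, this holds
    exactly when the stable branch exists, lies strictly between the
    boundaries, and ``A`` sits above the unstable separatrix.  Everything
    else that is still alive is *precarious*: it dies unless behavior
    changes ``F``.
    """
    if state.A <= p.A_death_low:
        return RegionLabel.DEAD_LOW
    if state.A >= p.A_death_high:
        return RegionLabel.DEAD_HIGH
    eq = equilibria(state.F, p)
    if eq.stable_root is None:
        return RegionLabel.PRECARIOUS  # everything decays toward A = 0
    if not (p.A_death_low < eq.stable_root < p.A_death_high):
        return RegionLabel.PRECARIOUS
    if state.A <= eq.unstable_root:
        return RegionLabel.PRECARIOUS  # below (or on) the separatrix
    return RegionLabel.VIABLE


def calibrate_default_params() -> MetabolismParams:
    """The repository's frozen default metabolism preset.

    A single calibration, chosen so that (i) the bifurcation diagram has
    the canonical shape — dead lines at low and high ``A`` with the
    stable/unstable branch pair between them, (ii) the shipped behavior
    parameter ranges straddle the bifurcation and span the viable branch,
    and (iii) the survivability ranking of the four behavior presets is
    reproduced by the simulation suite.  Pure constants: bit-stable
    across runs.
    """
    return MetabolismParams(
        k_forward=0.8,
        k_backward=0.2,
        k_decay=0.8,
        A_death_low=0.5,
        A_death_high=8.0,
    )


def bifurcation_scan(
    p: MetabolismParams,
    F_min: float = 0.0,
    F_max: float = 4.0,
    n: int = 401,
) -> pd.DataFrame:
    """Tabulate the equilibrium branches over a range of resource levels.

    Returns a frame with columns ``(F, dead_root, unstable_root,
    stable_root)``; absent branches are NaN.  Suitable for direct CSV
    export of the bifurcation diagram.
    """
    F_values = np.linspace(F_min, F_max, n)
    rows = []
    for F in F_values:
        eq = equilibria(float(F), p)
        rows.append(
            (
                float(F),
                eq.dead_root,
                np.nan if eq.unstable_root is None else eq.unstable_root,
                np.nan if eq.stable_root is None else eq.stable_root,
            )
        )
    return pd.DataFrame(
        rows, columns=["F", "dead_root", "unstable_root", "stable_root"]
    )
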