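"""1-D spatial population of chemotaxing agents on a resource gradient.

Instead of acting on the resource level directly, each agent is
embedded at a position ``x`` in a one-dimensional arena with a fixed,
monotone non-decreasing resource profile ``F(x)`` and walls at both
ends.  The behavioral controller's output ``B`` (its would-be dF/dt) is
re-expressed as motion: a non-negative ``B + epsilon`` moves the agent
up-gradient at speed ``v``, a negative one down-gradient, where
``epsilon`` is a fixed per-agent error bias drawn once at birth.
Agents that push past a wall are relocated onto it.  Each agent's
metabolite level evolves under the local resource level; crossing a
death boundary freezes the agent permanently.

Agents are independent (no interaction, no resource depletion), so the
whole population is stepped as flat NumPy arrays; per-agent random
substreams keyed by (master seed, agent index) make runs reproducible
and prefix-stable when the population is enlarged.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .behaviors import BehaviorSpec, behavior_rate_arrays
from .metabolism import MetabolismParams, _rate

__all__ = [
    "Environment1D",
    "Agent",
    "AgentStatus",
    "PopulationConfig",
    "PopulationSnapshot",
    "PopulationResult",
    "resource_at",
    "init_population",
    "step_population",
    "run_population",
]


class AgentStatus(enum.IntEnum):
    ALIVE = 0
    DEAD_LOW = 1
    DEAD_HIGH = 2


@dataclass(frozen=True)
class Environment1D:
    """A walled 1-D arena with a fixed monotone resource profile.

    ``kind`` selects the profile: ``linear`` interpolates from ``F_lo``
    at the left wall to ``F_hi`` at the right wall; ``sigmoid`` is a
    logistic ramp between the same asymptotes with midpoint
    ``sigmoid_center`` and steepness ``sigmoid_steepness``.
    """

    x_min: float = 0.0
    x_max: float = 1.0
    F_lo: float = 0.0
    F_hi: float = 4.0
    kind: str = "linear"  # "linear" | "sigmoid"
    sigmoid_center: float = 0.5
    sigmoid_steepness: float = 10.0

    def __post_init__(self) -> None:
        if not self.x_max > self.x_min:
            raise ValueError("x_max must exceed x_min")
        if self.F_hi < self.F_lo or self.F_lo < 0:
            raise ValueError("resource profile must be non-negative, non-decreasing")
        if self.kind not in ("linear", "sigmoid"):
            raise ValueError("kind must be 'linear' or 'sigmoid'")


def resource_at(x, env: Environment1D):
    """Resource concentration at position(s) ``x`` inside the walls."""
    x = np.asarray(x, dtype=float)
    if np.any(x < env.x_min) or np.any(x > env.x_max):
        raise ValueError("position outside walls; clamp before lookup")
    frac = (x - env.x_min) / (env.x_max - env.x_min)
    if env.kind == "linear":
        out = env.F_lo + (env.F_hi - env.F_lo) * frac
    else:
        c = (env.sigmoid_center - env.x_min) / (env.x_max - env.x_min)
        raw = 1.0 / (1.0 + np.exp(-env.sigmoid_steepness * (frac - c)))
        lo = 1.0 / (1.0 + np.exp(env.sigmoid_steepness * c))
        hi = 1.0 / (1.0 + np.exp(-env.sigmoid_steepness * (1.0 - c)))
        out = env.F_lo + (env.F_hi - env.F_lo) * (raw - lo) / (hi - lo)
    return out if out.shape else float(out)


@dataclass(frozen=True)
class Agent:
    """One agent's state: position, metabolite level, fixed bias, status."""

    x: float
    A: float
    epsilon: float
    status: AgentStatus


@dataclass(frozen=True)
class PopulationConfig:
    """Spatial-simulation settings.

    Initial positions are flat between the walls; initial metabolite
    levels flat over ``(A_init_lo, A_init_hi)`` (defaulting to the open
    interval between the death boundaries).  ``epsilon_sd = 0`` gives
    every agent a zero bias; otherwise biases are normal with mean 0.
    """

    n_agents: int = 1000
    v: float = 0.25
    dt: float = 1e-3
    t_end: float = 100.0
    epsilon_sd: float = 0.0
    A_init_lo: Optional[float] = None  # default: A_death_low
    A_init_hi: Optional[float] = None  # default: A_death_high
    snapshot_interval: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if not (self.v > 0 and self.dt > 0 and self.t_end > 0):
            raise ValueError("v, dt and t_end must be > 0")
        if self.epsilon_sd < 0:
            raise ValueError("epsilon_sd must be >= 0")


@dataclass(frozen=True)
class PopulationSnapshot:
    """Per-agent view of the population at one instant."""

    time: float
    x: np.ndarray
    A_initial: np.ndarray
    A: np.ndarray
    status: np.ndarray  # AgentStatus integer codes

    def agents(self, epsilon: Optional[np.ndarray] = None):
        eps = epsilon if epsilon is not None else np.zeros_like(self.x)
        for i in range(self.x.size):
            yield Agent(
                x=float(self.x[i]),
                A=float(self.A[i]),
                epsilon=float(eps[i]),
                status=AgentStatus(int(self.status[i])),
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.time,
                "agent_id": np.arange(self.x.size),
                "x": self.x,
                "A_init": self.A_initial,
                "A": self.A,
                "status": [AgentStatus(int(s)).name.lower() for s in self.status],
            }
        )


@dataclass
class PopulationResult:
    """Snapshots plus end-of-run summaries of a spatial simulation."""

    snapshots: list[PopulationSnapshot]
    x: np.ndarray
    A: np.ndarray
    A_initial: np.ndarray
    epsilon: np.ndarray
    status: np.ndarray
    reversals: np.ndarray  # number of movement-direction changes per agent

    @property
    def survival_fraction(self) -> float:
        return float(np.mean(self.status == AgentStatus.ALIVE))

    def fractions_by_cause(self) -> dict[str, float]:
        n = self.status.size
        return {
            s.name.lower(): float(np.count_nonzero(self.status == s) / n)
            for s in AgentStatus
        }


def init_population(cfg: PopulationConfig, env: Environment1D, p: MetabolismParams):
    """Draw initial positions, metabolite levels and biases per agent.

    Each agent uses its own random substream seeded by
    ``(cfg.seed, agent index)``, so enlarging the population leaves the
    first agents' draws unchanged.
    """
    a_lo = p.A_death_low if cfg.A_init_lo is None else cfg.A_init_lo
    a_hi = p.A_death_high if cfg.A_init_hi is None else cfg.A_init_hi
    x = np.empty(cfg.n_agents)
    A = np.empty(cfg.n_agents)
    eps = np.zeros(cfg.n_agents)
    for i in range(cfg.n_agents):
        rng = np.random.default_rng([cfg.seed, i])
        x[i] = rng.uniform(env.x_min, env.x_max)
        A[i] = rng.uniform(a_lo, a_hi)
        if cfg.epsilon_sd > 0:
            eps[i] = rng.normal(0.0, cfg.epsilon_sd)
    return x, A, eps


def step_population(
    x: np.ndarray,
    A: np.ndarray,
    epsilon: np.ndarray,
    status: np.ndarray,
    behavior: BehaviorSpec,
    env: Environment1D,
    p: MetabolismParams,
    cfg: PopulationConfig,
    direction_out: Optional[np.ndarray] = None,
):
    """Advance every living agent by one time step ``cfg.dt`` (in place).

    For each living agent: look up the local resource level, evaluate
    the controller output ``B`` and the metabolic rate, move up-gradient
    if ``B + epsilon >= 0`` else down-gradient, relocate onto a wall if
    pushed past it, then advance the metabolite level one RK4 step at
    the (pre-move) local resource level.  Boundary crossings mark the
    agent dead; dead agents are frozen.  ``direction_out``, if given,
    receives each agent's movement sign (0 for dead agents).
    """
    alive = status == AgentStatus.ALIVE
    F = resource_at(np.clip(x, env.x_min, env.x_max), env)
    dA = _rate(A, F, p)
    B = behavior_rate_arrays(behavior, A, F, dA)
    up = (B + epsilon) >= 0.0
    direction = np.where(up, 1.0, -1.0)
    x_new = np.clip(x + direction * cfg.v * cfg.dt, env.x_min, env.x_max)
    x[alive] = x_new[alive]
    if direction_out is not None:
        direction_out[:] = np.where(alive, direction, 0.0)

    # metabolism update at the local (pre-move) resource level
    dt = cfg.dt
    k1 = dA
    k2 = _rate(np.maximum(A + 0.5 * dt * k1, 0.0), F, p)
    k3 = _rate(np.maximum(A + 0.5 * dt * k2, 0.0), F, p)
    k4 = _rate(np.maximum(A + dt * k3, 0.0), F, p)
    A_new = np.maximum(A + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4), 0.0)
    A[alive] = A_new[alive]

    died_low = alive & (A <= p.A_death_low)
    died_high = alive & (A >= p.A_death_high)
    status[died_low] = AgentStatus.DEAD_LOW
    status[died_high] = AgentStatus.DEAD_HIGH
    return x, A, status


def run_population(
    behavior: BehaviorSpec,
    env: Environment1D,
    p: MetabolismParams,
    cfg: PopulationConfig,
) -> PopulationResult:
    """Simulate the whole population and collect periodic snapshots.

    Returns snapshots at ``cfg.snapshot_interval`` (always including
    t = 0 and t_end), final per-agent state, and the number of
    movement-direction reversals each agent performed while alive
    (a simple signature of overshoot-style oscillation).
    """
    x, A, eps = init_population(cfg, env, p)
    A_initial = A.copy()
    status = np.full(cfg.n_agents, AgentStatus.ALIVE, dtype=np.int8)
    status[A <= p.A_death_low] = AgentStatus.DEAD_LOW
    status[A >= p.A_death_high] = AgentStatus.DEAD_HIGH

    n_steps = int(round(cfg.t_end / cfg.dt))
    snap_every = max(1, int(round(cfg.snapshot_interval / cfg.dt)))
    snapshots = [
        PopulationSnapshot(0.0, x.copy(), A_initial.copy(), A.copy(), status.copy())
    ]
    prev_dir = np.zeros(cfg.n_agents)
    direction = np.zeros(cfg.n_agents)
    reversals = np.zeros(cfg.n_agents, dtype=np.int64)

    for step in range(1, n_steps + 1):
        step_population(
            x, A, eps, status, behavior, env, p, cfg, direction_out=direction
        )
        flipped = (direction * prev_dir) < 0.0
        reversals[flipped] += 1
        moved = direction != 0.0
        prev_dir[moved] = direction[moved]
        if step % snap_every == 0 or step == n_steps:
            snapshots.append(
                PopulationSnapshot(
                    step * cfg.dt, x.copy(), A_initial.copy(), A.copy(), status.copy()
                )
            )

    return PopulationResult(
        snapshots=snapshots,
        x=x,
        A=A,
        A_initial=A_initial,
        epsilon=eps,
        status=status,
        reversals=reversals,
    )
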