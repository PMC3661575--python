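"""Integration of the coupled metabolism + behavior system.

Two integration routes are provided:

* :func:`simulate_trajectory` — adaptive Runge--Kutta (``scipy``'s
  ``solve_ivp``) with terminal event detection at both death
  boundaries; the route of choice for individual trajectories where
  the time of death matters.
* :func:`integrate_batch` — a vectorised fixed-step classical RK4
  stepper that advances thousands of independent initial conditions in
  lockstep, freezing each the moment it crosses a boundary.  This is
  what the survivability maps and the fitness evaluations use; death
  times are only resolved to one step.

Both routes treat the death set as closed (touching a boundary counts
as death) and absorbing (dead states are frozen), and clamp
concentrations at zero.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .behaviors import BehaviorSpec, behavior_rate_arrays
from .metabolism import MetabolismParams, SystemState, _rate

__all__ = [
    "IntegratorConfig",
    "TrajectoryResult",
    "InitialGrid",
    "SurvivabilityGrid",
    "Outcome",
    "IntegrationError",
    "simulate_trajectory",
    "survivability_map",
    "survival_proportion",
    "integrate_batch",
]


class Outcome(enum.Enum):
    """Fate of a trajectory."""

    SURVIVED = "survived"
    DEAD_LOW = "dead_low"
    DEAD_HIGH = "dead_high"


#: integer codes used in the vectorised stepper / grid storage
OUTCOME_CODES = {Outcome.SURVIVED: 0, Outcome.DEAD_LOW: 1, Outcome.DEAD_HIGH: 2}
CODE_OUTCOMES = {v: k for k, v in OUTCOME_CODES.items()}


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid state."""

    def __init__(self, message: str, t: float, state: SystemState):
        super().__init__(f"{message} (t={t:.6g}, A={state.A:.6g}, F={state.F:.6g})")
        self.t = t
        self.last_state = state


@dataclass(frozen=True)
class IntegratorConfig:
    """Integration settings for trajectory and map runs.

    ``method`` selects the adaptive event-detecting solver or the
    fixed-step RK4 stepper (step ``dt``).  ``steady_tol`` is the
    threshold on |dA/dt| and |dF/dt| below which the final state is
    flagged as (near-)steady.
    """

    method: str = "adaptive"  # "adaptive" | "fixed"
    t_end: float = 100.0
    dt: float = 1e-3
    rtol: float = 1e-8
    atol: float = 1e-10
    steady_tol: float = 1e-6
    n_samples: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("adaptive", "fixed"):
            raise ValueError("method must be 'adaptive' or 'fixed'")
        if not (self.t_end > 0 and self.dt > 0):
            raise ValueError("t_end and dt must be > 0")
        if not (self.rtol > 0 and self.atol > 0 and self.steady_tol > 0):
            raise ValueError("tolerances must be > 0")


@dataclass(frozen=True)
class TrajectoryResult:
    """A simulated trajectory and its fate."""

    t: np.ndarray
    A: np.ndarray
    F: np.ndarray
    outcome: Outcome
    time_of_death: Optional[float]
    final_A: float
    final_F: float
    reached_steady: bool

    @property
    def survived(self) -> bool:
        return self.outcome is Outcome.SURVIVED

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "A": self.A, "F": self.F})


@dataclass(frozen=True)
class InitialGrid:
    """Uniform rectangular lattice of initial conditions in (F, A)."""

    F_min: float = 0.0
    F_max: float = 4.0
    A_min: float = 0.0
    A_max: float = 8.0
    resolution: int = 51

    def __post_init__(self) -> None:
        if not (self.F_max > self.F_min and self.A_max > self.A_min):
            raise ValueError("ranges must have positive length")
        if self.resolution < 2:
            raise ValueError("resolution must be >= 2")

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (F, A) coordinates of all lattice cells (row-major in F)."""
        F = np.linspace(self.F_min, self.F_max, self.resolution)
        A = np.linspace(self.A_min, self.A_max, self.resolution)
        FF, AA = np.meshgrid(F, A, indexing="ij")
        return FF.ravel(), AA.ravel()


@dataclass(frozen=True)
class SurvivabilityGrid:
    """Per-cell outcomes and final metabolite levels over an initial grid."""

    grid: InitialGrid
    F_init: np.ndarray
    A_init: np.ndarray
    outcome_code: np.ndarray  # int codes, see OUTCOME_CODES
    final_A: np.ndarray

    def __post_init__(self) -> None:
        n = self.grid.resolution**2
        if not (len(self.F_init) == len(self.outcome_code) == n):
            raise ValueError("cell count must equal resolution**2")

    def proportions(self) -> dict[str, float]:
        """Fractions of survived / dead_low / dead_high cells (sum to 1)."""
        n = self.outcome_code.size
        return {
            out.value: float(np.count_nonzero(self.outcome_code == code) / n)
            for out, code in OUTCOME_CODES.items()
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "F_init": self.F_init,
                "A_init": self.A_init,
                "outcome": [CODE_OUTCOMES[c].value for c in self.outcome_code],
                "final_A": self.final_A,
            }
        )


def _initial_outcome(A0: float, p: MetabolismParams) -> Optional[Outcome]:
    if A0 <= p.A_death_low:
        return Outcome.DEAD_LOW
    if A0 >= p.A_death_high:
        return Outcome.DEAD_HIGH
    return None


def simulate_trajectory(
    init: SystemState,
    behavior: BehaviorSpec,
    p: MetabolismParams,
    cfg: IntegratorConfig = IntegratorConfig(),
) -> TrajectoryResult:
    """Integrate one trajectory of the coupled system until death or t_end.

    The coupled ODE is ``dA/dt = metabolic_rate(A, F)`` and ``dF/dt``
    given by the behavior; ``F`` is clamped at zero (the actuator cannot
    push the resource level negative).  Death-boundary crossings are
    localised by the solver's event machinery (adaptive method) or to
    one step (fixed method); a start on or beyond a boundary dies at
    ``t = 0``.
    """
    at_start = _initial_outcome(init.A, p)
    if at_start is not None:
        t = np.array([0.0])
        return TrajectoryResult(
            t=t,
            A=np.array([init.A]),
            F=np.array([init.F]),
            outcome=at_start,
            time_of_death=0.0,
            final_A=init.A,
            final_F=init.F,
            reached_steady=False,
        )

    if cfg.method == "fixed":
        return _simulate_fixed(init, behavior, p, cfg)

    def rhs(t, y):
        A = max(y[0], 0.0)
        F = max(y[1], 0.0)
        dA = _rate(A, F, p)
        dF = float(behavior_rate_arrays(behavior, A, F, dA))
        if y[1] <= 0.0 and dF < 0.0:
            dF = 0.0
        return (dA, dF)

    def ev_low(t, y):
        return y[0] - p.A_death_low

    def ev_high(t, y):
        return y[0] - p.A_death_high

    ev_low.terminal = True
    ev_low.direction = -1
    ev_high.terminal = True
    ev_high.direction = 1

    t_eval = np.linspace(0.0, cfg.t_end, cfg.n_samples)
    sol = solve_ivp(
        rhs,
        (0.0, cfg.t_end),
        (init.A, init.F),
        method="RK45",
        t_eval=t_eval,
        events=(ev_low, ev_high),
        rtol=cfg.rtol,
        atol=cfg.atol,
    )
    if sol.status == -1:
        last = SystemState(max(sol.y[0, -1], 0.0), max(sol.y[1, -1], 0.0))
        raise IntegrationError(sol.message, float(sol.t[-1]), last)

    if sol.status == 1:  # a terminal event fired
        if sol.t_events[0].size:
            outcome = Outcome.DEAD_LOW
            t_death = float(sol.t_events[0][0])
            y_death = sol.y_events[0][0]
        else:
            outcome = Outcome.DEAD_HIGH
            t_death = float(sol.t_events[1][0])
            y_death = sol.y_events[1][0]
        t = np.append(sol.t, t_death)
        A = np.append(sol.y[0], y_death[0])
        F = np.append(sol.y[1], max(y_death[1], 0.0))
        return TrajectoryResult(
            t=t,
            A=A,
            F=F,
            outcome=outcome,
            time_of_death=t_death,
            final_A=float(y_death[0]),
            final_F=float(max(y_death[1], 0.0)),
            reached_steady=False,
        )

    A_end, F_end = float(sol.y[0, -1]), float(max(sol.y[1, -1], 0.0))
    dA_end, dF_end = rhs(cfg.t_end, (A_end, F_end))
    steady = abs(dA_end) <= cfg.steady_tol and abs(dF_end) <= cfg.steady_tol
    return TrajectoryResult(
        t=sol.t,
        A=sol.y[0],
        F=np.maximum(sol.y[1], 0.0),
        outcome=Outcome.SURVIVED,
        time_of_death=None,
        final_A=A_end,
        final_F=F_end,
        reached_steady=steady,
    )


def _simulate_fixed(init, behavior, p, cfg) -> TrajectoryResult:
    """Single-trajectory wrapper around the vectorised fixed-step core."""
    res = integrate_batch(
        np.array([init.A]),
        np.array([init.F]),
        behavior,
        p,
        dt=cfg.dt,
        t_end=cfg.t_end,
        record_every=max(1, int(round(cfg.t_end / cfg.dt / (cfg.n_samples - 1)))),
    )
    t = res["t_samples"]
    A = res["A_samples"][:, 0]
    F = res["F_samples"][:, 0]
    code = int(res["outcome"][0])
    outcome = CODE_OUTCOMES[code]
    t_death = None if outcome is Outcome.SURVIVED else float(res["t_death"][0])
    A_end, F_end = float(res["A"][0]), float(res["F"][0])
    dA = _rate(A_end, F_end, p)
    dF = float(behavior_rate_arrays(behavior, A_end, F_end, dA))
    steady = outcome is Outcome.SURVIVED and (
        abs(dA) <= cfg.steady_tol and abs(dF) <= cfg.steady_tol
    )
    return TrajectoryResult(
        t=t,
        A=A,
        F=F,
        outcome=outcome,
        time_of_death=t_death,
        final_A=A_end,
        final_F=F_end,
        reached_steady=steady,
    )


def integrate_batch(
    A0: np.ndarray,
    F0: np.ndarray,
    behavior,
    p: MetabolismParams,
    dt: float = 1e-3,
    t_end: float = 100.0,
    record_every: int = 0,
    rate_fn=None,
) -> dict:
    """Advance many independent (A, F) systems with fixed-step RK4.

    ``behavior`` is either a :class:`BehaviorSpec` (broadcast over all
    systems) or ``None`` together with ``rate_fn(A, F, dA_dt) -> dF_dt``
    for per-system controller parameters (used by the lattice search).
    Dead systems are frozen at the state in which they first touched a
    boundary; their death time is resolved to one step.

    Returns a dict with final ``A``, ``F``, integer ``outcome`` codes,
    ``t_death`` (NaN for survivors) and, if ``record_every > 0``,
    sampled time series ``t_samples`` / ``A_samples`` / ``F_samples``.
    """
    if rate_fn is None:
        def rate_fn(A, F, dA):  # noqa: F811 - deliberate default binding
            return behavior_rate_arrays(behavior, A, F, dA)

    A = np.array(A0, dtype=float).copy()
    F = np.array(F0, dtype=float).copy()
    n = A.size
    outcome = np.zeros(n, dtype=np.int8)
    t_death = np.full(n, np.nan)

    outcome[A <= p.A_death_low] = OUTCOME_CODES[Outcome.DEAD_LOW]
    outcome[A >= p.A_death_high] = OUTCOME_CODES[Outcome.DEAD_HIGH]
    alive = outcome == 0
    t_death[~alive] = 0.0

    n_steps = int(round(t_end / dt))
    samples_t, samples_A, samples_F = [], [], []
    if record_every > 0:
        samples_t.append(0.0)
        samples_A.append(A.copy())
        samples_F.append(F.copy())

    def deriv(a, f):
        dA = _rate(a, f, p)
        dF = rate_fn(a, f, dA)
        dF = np.where((f <= 0.0) & (dF < 0.0), 0.0, dF)
        return dA, dF

    any_alive = bool(alive.any())
    for step in range(1, n_steps + 1):
        if not any_alive:
            if record_every > 0 and step % record_every == 0:
                samples_t.append(step * dt)
                samples_A.append(A.copy())
                samples_F.append(F.copy())
            continue
        k1a, k1f = deriv(A, F)
        k2a, k2f = deriv(A + 0.5 * dt * k1a, np.maximum(F + 0.5 * dt * k1f, 0.0))
        k3a, k3f = deriv(A + 0.5 * dt * k2a, np.maximum(F + 0.5 * dt * k2f, 0.0))
        k4a, k4f = deriv(A + dt * k3a, np.maximum(F + dt * k3f, 0.0))
        A_new = A + (dt / 6.0) * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
        F_new = np.maximum(F + (dt / 6.0) * (k1f + 2.0 * k2f + 2.0 * k3f + k4f), 0.0)
        A_new = np.maximum(A_new, 0.0)
        A = np.where(alive, A_new, A)
        F = np.where(alive, F_new, F)

        died_low = alive & (A <= p.A_death_low)
        died_high = alive & (A >= p.A_death_high)
        if died_low.any() or died_high.any():
            outcome[died_low] = OUTCOME_CODES[Outcome.DEAD_LOW]
            outcome[died_high] = OUTCOME_CODES[Outcome.DEAD_HIGH]
            t_death[died_low | died_high] = step * dt
            alive = alive & ~(died_low | died_high)
            any_alive = bool(alive.any())

        if record_every > 0 and step % record_every == 0:
            samples_t.append(step * dt)
            samples_A.append(A.copy())
            samples_F.append(F.copy())

    result = {"A": A, "F": F, "outcome": outcome, "t_death": t_death}
    if record_every > 0:
        result["t_samples"] = np.array(samples_t)
        result["A_samples"] = np.array(samples_A)
        result["F_samples"] = np.array(samples_F)
    return result


def survivability_map(
    grid: InitialGrid,
    behavior: BehaviorSpec,
    p: MetabolismParams,
    cfg: IntegratorConfig = IntegratorConfig(),
) -> SurvivabilityGrid:
    """Outcome of every lattice initial condition under one behavior.

    All cells are advanced together by the fixed-step batch integrator
    (step ``cfg.dt``); the result is independent of cell order.
    """
    F0, A0 = grid.mesh()
    res = integrate_batch(A0, F0, behavior, p, dt=cfg.dt, t_end=cfg.t_end)
    return SurvivabilityGrid(
        grid=grid,
        F_init=F0,
        A_init=A0,
        outcome_code=res["outcome"],
        final_A=res["A"],
    )


def survival_proportion(g: SurvivabilityGrid) -> float:
    """Fraction of lattice cells whose trajectories avoided both boundaries."""
    return g.proportions()[Outcome.SURVIVED.value]
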