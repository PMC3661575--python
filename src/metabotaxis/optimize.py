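"""Fitness scoring and parameter optimisation for the behaviors.

A behavior's fitness is evaluated by simulating a uniform lattice of
initial conditions and combining

* ``S`` — the proportion of lattice trajectories that survive, and
* ``V`` — the mean normalised closeness of the final metabolite level
  to the midpoint between the two death boundaries (dead trajectories
  score 0), i.e. ``mean(max(0, 1 - |A_end - A_mid| / (A_high - A_mid)))``

into ``total = S + V`` (bounded in [0, 2]).  ``V`` rewards behaviors
that park the system deep inside the viable region rather than hugging
a boundary.

The two-parameter behaviors are optimised by exhaustive lattice
sampling of their parameter plane; the six-parameter hybrid by a
microbial genetic algorithm: repeated pairwise tournaments in which the
loser's genes are pulled toward the winner's and then mutated with
Gaussian noise whose spread is one percent of each gene's allowed
range, wrapping out-of-range values back in modular fashion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .behaviors import (
    PARAM_RANGES,
    Behavior1Params,
    Behavior2Params,
    Behavior3Params,
    Behavior4Params,
    BehaviorSpec,
    MotorLimit,
)
from .metabolism import MetabolismParams
from .simulate import InitialGrid, IntegratorConfig, Outcome, OUTCOME_CODES, integrate_batch

__all__ = [
    "FitnessScore",
    "Genotype",
    "GAConfig",
    "LatticeSearchConfig",
    "fitness",
    "lattice_search",
    "microbial_ga",
    "spec_from_genes",
]

_PARAM_CLASSES = {
    "B1": Behavior1Params,
    "B2": Behavior2Params,
    "B3": Behavior3Params,
    "B4": Behavior4Params,
}


@dataclass(frozen=True)
class FitnessScore:
    """Survival proportion ``S``, closeness score ``V``, and their sum."""

    S: float
    V: float

    @property
    def total(self) -> float:
        return self.S + self.V


@dataclass(frozen=True)
class Genotype:
    """An ordered parameter vector with per-gene allowed ranges."""

    values: np.ndarray
    ranges: np.ndarray  # shape (n_genes, 2)
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        lo, hi = self.ranges[:, 0], self.ranges[:, 1]
        if np.any(self.values < lo) or np.any(self.values > hi):
            raise ValueError("genotype values must lie inside their ranges")


@dataclass(frozen=True)
class GAConfig:
    """Microbial-GA settings.

    ``mutation_sd_frac`` is the Gaussian mutation spread expressed as a
    fraction of each gene's allowed range (default one percent);
    ``recombination`` is how far the tournament loser is pulled toward
    the winner.
    """

    population: int = 40
    tournaments: int = 2000
    recombination: float = 0.5
    mutation_sd_frac: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0 < self.recombination <= 1:
            raise ValueError("recombination must be in (0, 1]")
        if self.mutation_sd_frac < 0:
            raise ValueError("mutation_sd_frac must be >= 0")


@dataclass(frozen=True)
class LatticeSearchConfig:
    """Exhaustive sampling of a 2-parameter behavior's parameter plane."""

    resolution: int = 101
    ranges: Optional[dict[str, tuple[float, float]]] = None  # default: PARAM_RANGES

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise ValueError("resolution must be >= 2")


def _v_scores(final_A: np.ndarray, outcome: np.ndarray, p: MetabolismParams) -> np.ndarray:
    """Per-cell closeness of the final metabolite level to the midpoint."""
    half_width = p.A_death_high - p.A_mid
    v = np.maximum(0.0, 1.0 - np.abs(final_A - p.A_mid) / half_width)
    return np.where(outcome == OUTCOME_CODES[Outcome.SURVIVED], v, 0.0)


def fitness(
    behavior: BehaviorSpec,
    p: MetabolismParams,
    grid: InitialGrid = InitialGrid(resolution=21),
    cfg: IntegratorConfig = IntegratorConfig(),
) -> FitnessScore:
    """Score one behavior over a lattice of initial conditions."""
    F0, A0 = grid.mesh()
    res = integrate_batch(A0, F0, behavior, p, dt=cfg.dt, t_end=cfg.t_end)
    survived = res["outcome"] == OUTCOME_CODES[Outcome.SURVIVED]
    S = float(np.mean(survived))
    V = float(np.mean(_v_scores(res["A"], res["outcome"], p)))
    return FitnessScore(S=S, V=V)


def spec_from_genes(
    kind: str, values: Sequence[float], r_max: float = 1.0
) -> BehaviorSpec:
    """Build a BehaviorSpec from an ordered gene vector for ``kind``."""
    names = list(PARAM_RANGES[kind])
    params = _PARAM_CLASSES[kind](**dict(zip(names, map(float, values))))
    return BehaviorSpec(kind=kind, params=params, motor=MotorLimit(r_max=r_max))


def lattice_search(
    behavior_kind: str,
    cfg: LatticeSearchConfig,
    p: MetabolismParams,
    grid: InitialGrid = InitialGrid(resolution=21),
    integrator: IntegratorConfig = IntegratorConfig(),
    r_max: float = 1.0,
) -> tuple[dict[str, float], FitnessScore, pd.DataFrame]:
    """Exhaustively score a 2-parameter behavior over its parameter plane.

    Every (target, gain) node of the parameter lattice is evaluated with
    the full fitness lattice of initial conditions; all node x cell
    systems are integrated jointly in one vectorised batch.  Returns the
    argmax node (first encountered in row-major order on ties), its
    score, and the full surface as a DataFrame.
    """
    if behavior_kind not in ("B1", "B2", "B3"):
        raise ValueError("lattice search applies to the 2-parameter behaviors")
    ranges = cfg.ranges or PARAM_RANGES[behavior_kind]
    (name_t, (t_lo, t_hi)), (name_k, (k_lo, k_hi)) = list(ranges.items())
    thetas = np.linspace(t_lo, t_hi, cfg.resolution)
    gains = np.linspace(k_lo, k_hi, cfg.resolution)
    TT, KK = np.meshgrid(thetas, gains, indexing="ij")
    theta_nodes, gain_nodes = TT.ravel(), KK.ravel()
    n_nodes = theta_nodes.size

    F0_cells, A0_cells = grid.mesh()
    n_cells = F0_cells.size
    A0 = np.tile(A0_cells, n_nodes)
    F0 = np.tile(F0_cells, n_nodes)
    theta = np.repeat(theta_nodes, n_cells)
    gain = np.repeat(gain_nodes, n_cells)

    def rate_fn(A, F, dA):
        if behavior_kind == "B1":
            x = theta - F
        elif behavior_kind == "B2":
            x = theta - A
        else:
            x = theta - dA
        return r_max * np.tanh(gain * x)

    res = integrate_batch(
        A0, F0, None, p, dt=integrator.dt, t_end=integrator.t_end, rate_fn=rate_fn
    )
    survived = (res["outcome"] == OUTCOME_CODES[Outcome.SURVIVED]).reshape(
        n_nodes, n_cells
    )
    v = _v_scores(res["A"], res["outcome"], p).reshape(n_nodes, n_cells)
    S = survived.mean(axis=1)
    V = v.mean(axis=1)
    total = S + V

    best = int(np.argmax(total))  # first-encountered tie-break, row-major
    best_params = {name_t: float(theta_nodes[best]), name_k: float(gain_nodes[best])}
    best_score = FitnessScore(S=float(S[best]), V=float(V[best]))
    surface = pd.DataFrame(
        {name_t: theta_nodes, name_k: gain_nodes, "S": S, "V": V, "total": total}
    )
    return best_params, best_score, surface


def _wrap(values: np.ndarray, ranges: np.ndarray) -> np.ndarray:
    """Wrap out-of-range genes back into range via modular arithmetic."""
    lo, hi = ranges[:, 0], ranges[:, 1]
    width = hi - lo
    return lo + np.mod(values - lo, width)


def microbial_ga(
    cfg: GAConfig,
    fitness_fn: Callable[[np.ndarray], float],
    ranges: np.ndarray,
    names: Sequence[str] = (),
    initial_population: Optional[np.ndarray] = None,
) -> tuple[Genotype, float, np.ndarray]:
    """Microbial genetic algorithm over a box-constrained gene space.

    A random population is improved by repeated pairwise tournaments:
    the loser's genes are pulled a fraction ``cfg.recombination`` toward
    the winner's, mutated with Gaussian noise of spread
    ``cfg.mutation_sd_frac`` times each gene's range, wrapped back into
    range modularly, and re-scored.  The winner is never modified, so
    the best-so-far fitness trace is non-decreasing.  Fully reproducible
    from ``cfg.seed``.

    Returns the fittest final genotype, its fitness, and the per-
    tournament best-so-far trace.
    """
    ranges = np.asarray(ranges, dtype=float)
    n_genes = ranges.shape[0]
    names = tuple(names) if names else tuple(f"g{i}" for i in range(n_genes))
    rng = np.random.default_rng(cfg.seed)

    if initial_population is not None:
        pop = np.array(initial_population, dtype=float).copy()
        if pop.shape != (cfg.population, n_genes):
            raise ValueError("initial_population shape must be (population, n_genes)")
    else:
        pop = rng.uniform(ranges[:, 0], ranges[:, 1], size=(cfg.population, n_genes))
    fit = np.empty(cfg.population)
    for i in range(cfg.population):
        fit[i] = fitness_fn(pop[i])
        if not np.isfinite(fit[i]):
            raise RuntimeError(f"non-finite fitness for genotype {pop[i]!r}")

    trace = np.empty(cfg.tournaments)
    best_so_far = float(fit.max())
    for t in range(cfg.tournaments):
        i, j = rng.choice(cfg.population, size=2, replace=False)
        if fit[i] >= fit[j]:
            win, lose = i, j
        else:
            win, lose = j, i
        child = pop[lose] + cfg.recombination * (pop[win] - pop[lose])
        child = child + rng.normal(
            0.0, cfg.mutation_sd_frac * (ranges[:, 1] - ranges[:, 0]), size=n_genes
        )
        child = _wrap(child, ranges)
        pop[lose] = child
        fit[lose] = fitness_fn(child)
        if not np.isfinite(fit[lose]):
            raise RuntimeError(f"non-finite fitness for genotype {child!r}")
        best_so_far = max(best_so_far, float(fit[lose]))
        trace[t] = best_so_far

    best = int(np.argmax(fit))
    return Genotype(values=pop[best].copy(), ranges=ranges, names=names), float(
        fit[best]
    ), trace
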