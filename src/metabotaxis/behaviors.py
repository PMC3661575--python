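"""The four behavioral controllers that steer the resource level.

Each behavior is an ODE for ``dF/dt`` with a bounded actuator: the cell
can raise or lower its local resource concentration at most at
``r_max``.  The response is a saturating tanh of the deviation from a
target, with the gain setting the sensitivity inside the bound:

* Behavior 1 (metabolism-independent): homeostat on the resource level
  ``F`` itself; blind to the metabolic state.
* Behavior 2 (metabolism-based): homeostat on the metabolite level
  ``A``; blind to the environment.
* Behavior 3 (metabolism-based, rate-of-change): regulates the *rate of
  change* of ``A``, which is indirectly sensitive to both ``A`` and
  ``F``.
* Behavior 4 (hybrid): a smooth sigmoidal switch in ``A`` blends an
  F-homeostat branch (dominant when the metabolism is doing well, high
  ``A``) with a rate-of-change branch (dominant when ``A`` is low).

Default parameter values are the optimised presets shipped with the
package (lattice sampling for the two-parameter behaviors, a microbial
genetic algorithm for the six-parameter hybrid); see
:func:`metabotaxis.config.load_behavior_presets`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .metabolism import SystemState, _rate, MetabolismParams

__all__ = [
    "MotorLimit",
    "Behavior1Params",
    "Behavior2Params",
    "Behavior3Params",
    "Behavior4Params",
    "BehaviorSpec",
    "PARAM_RANGES",
    "behavior1_rate",
    "behavior2_rate",
    "behavior3_rate",
    "switch_sigma",
    "behavior4_rate",
    "behavior_rate_arrays",
    "default_spec",
]


#: Allowed parameter ranges used by the optimisers (lattice sampling /
#: genetic algorithm) and by the modular mutation wrap.
PARAM_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "B1": {"theta_F": (0.0, 4.0), "k_F": (0.0, 10.0)},
    "B2": {"theta_A": (0.0, 8.0), "k_A": (0.0, 10.0)},
    "B3": {"theta_D": (-2.0, 2.0), "k_D": (0.0, 10.0)},
    "B4": {
        "theta_SF": (0.0, 4.0),
        "k_SF": (0.0, 5.0),
        "theta_SD": (-1.0, 1.0),
        "k_SD": (0.0, 5.0),
        "k_sigma": (0.0, 4.0),
        "k_r": (0.0, 10.0),
    },
}


@dataclass(frozen=True)
class MotorLimit:
    """Maximum achievable magnitude of ``dF/dt`` (concentration/time).

    ``r_max = 0`` is permitted and yields the null behavior (no
    actuation), useful as a fixed-resource control.
    """

    r_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.r_max >= 0:
            raise ValueError("r_max must be >= 0")


@dataclass(frozen=True)
class Behavior1Params:
    """Resource homeostat: target level ``theta_F``, sensitivity ``k_F``."""

    theta_F: float = 1.12
    k_F: float = 9.4


@dataclass(frozen=True)
class Behavior2Params:
    """Metabolite homeostat: target level ``theta_A``, sensitivity ``k_A``."""

    theta_A: float = 4.0
    k_A: float = 10.0


@dataclass(frozen=True)
class Behavior3Params:
    """Rate-of-change controller: target ``theta_D`` on dA/dt, gain ``k_D``."""

    theta_D: float = 0.0
    k_D: float = 10.0


@dataclass(frozen=True)
class Behavior4Params:
    """Sigmoidal-switch hybrid.

    ``(theta_SF, k_SF)`` parameterise the resource-homeostat branch,
    ``(theta_SD, k_SD)`` the rate-of-change branch.  ``k_sigma`` is the
    metabolite level at which the two branches are equally influential
    and ``k_r`` the steepness of the switch.
    """

    theta_SF: float = 1.1033
    k_SF: float = 2.7381
    theta_SD: float = 0.2894
    k_SD: float = 2.9981
    k_sigma: float = 2.6494
    k_r: float = 6.0630


BehaviorParams = Union[
    Behavior1Params, Behavior2Params, Behavior3Params, Behavior4Params
]

_KIND_FOR_PARAMS = {
    Behavior1Params: "B1",
    Behavior2Params: "B2",
    Behavior3Params: "B3",
    Behavior4Params: "B4",
}


@dataclass(frozen=True)
class BehaviorSpec:
    """A controller variant together with its parameters and motor limit."""

    kind: str
    params: BehaviorParams
    motor: MotorLimit = field(default_factory=MotorLimit)

    def __post_init__(self) -> None:
        expected = _KIND_FOR_PARAMS.get(type(self.params))
        if expected != self.kind:
            raise ValueError(
                f"kind {self.kind!r} does not match params of type "
                f"{type(self.params).__name__}"
            )


def default_spec(kind: str, r_max: float = 1.0) -> BehaviorSpec:
    """The shipped optimised preset for behavior ``kind`` in {B1..B4}."""
    cls = {
        "B1": Behavior1Params,
        "B2": Behavior2Params,
        "B3": Behavior3Params,
        "B4": Behavior4Params,
    }[kind]
    return BehaviorSpec(kind=kind, params=cls(), motor=MotorLimit(r_max=r_max))


def behavior1_rate(F, p: Behavior1Params, m: MotorLimit):
    """Metabolism-independent resource homeostat: dF/dt from ``F`` alone."""
    return m.r_max * np.tanh(p.k_F * (p.theta_F - F))


def behavior2_rate(A, p: Behavior2Params, m: MotorLimit):
    """Metabolite homeostat: raise F when A is below target, lower above."""
    return m.r_max * np.tanh(p.k_A * (p.theta_A - A))


def behavior3_rate(dA_dt, p: Behavior3Params, m: MotorLimit):
    """Rate-of-change controller: counteract deviation of dA/dt from target."""
    return m.r_max * np.tanh(p.k_D * (p.theta_D - dA_dt))


def switch_sigma(A, p: Behavior4Params):
    """Sigmoidal switch state in (0, 1), strictly increasing in ``A``.

    Equals 0.5 at ``A = k_sigma`` (the equal-influence point); tends to 1
    at high ``A`` where the resource-homeostat branch dominates.
    """
    return 1.0 / (1.0 + np.exp(-p.k_r * (np.asarray(A, dtype=float) - p.k_sigma)))


def behavior4_rate(state: SystemState, dA_dt, p: Behavior4Params, m: MotorLimit):
    """Hybrid controller: sigma-weighted blend of the two branches."""
    return _b4_rate(state.A, state.F, dA_dt, p, m)


def _b4_rate(A, F, dA_dt, p: Behavior4Params, m: MotorLimit):
    sigma = switch_sigma(A, p)
    b_f = m.r_max * np.tanh(p.k_SF * (p.theta_SF - F))
    b_d = m.r_max * np.tanh(p.k_SD * (p.theta_SD - dA_dt))
    return sigma * b_f + (1.0 - sigma) * b_d


def behavior_rate_arrays(spec: BehaviorSpec, A, F, dA_dt):
    """Vectorised dF/dt for any behavior kind; elementwise over arrays.

    ``dA_dt`` is the analytic metabolic rate at (A, F); it is only used
    by the derivative-sensitive kinds.
    """
    p, m = spec.params, spec.motor
    if spec.kind == "B1":
        return behavior1_rate(F, p, m)
    if spec.kind == "B2":
        return behavior2_rate(A, p, m)
    if spec.kind == "B3":
        return behavior3_rate(dA_dt, p, m)
    if spec.kind == "B4":
        return _b4_rate(A, F, dA_dt, p, m)
    raise ValueError(f"unknown behavior kind {spec.kind!r}")


def coupled_rates(A: float, F: float, spec: BehaviorSpec, p: MetabolismParams):
    """(dA/dt, dF/dt) of the coupled metabolism + behavior system."""
    dA = _rate(A, F, p)
    dF = behavior_rate_arrays(spec, A, F, dA)
    return dA, dF
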