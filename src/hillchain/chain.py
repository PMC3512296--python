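"""Assembly and equations of motion of the point-mass/CE chain.

The continuous mass distribution of a muscle is approximated by
``n_ce + 1`` point masses (PMs) in an alternating sequence with ``n_ce``
identical contractile elements.  Each PM carries the same share
``M / (n_ce + 1)`` of the total muscle mass; each CE has optimal length
``l_m_opt / n_ce``.  The PM at the coordinate origin is fixed to the
world; the PM at the other extreme is free, so releasing the chain from
rest at optimal length imposes the largest force step possible on the
free end.  There is no gravity and no parallel or serial elasticity.

Coordinates: x increases from the fixed end (x = 0) toward the free end;
a shortening CE therefore has negative length rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ce import CEParameters, ce_force
from .presets import MusclePreset

__all__ = [
    "ChainModel",
    "ChainState",
    "CEKinematics",
    "build_chain",
    "initial_state",
    "accelerations",
    "ce_kinematics",
]


@dataclass(frozen=True)
class ChainModel:
    """The assembled chain: mass allocation, CE constants, boundary condition."""

    n_ce: int
    total_mass: float  # kg
    ce: CEParameters

    def __post_init__(self) -> None:
        if self.n_ce < 1:
            raise ValueError(f"n_ce must be >= 1, got {self.n_ce}")
        if self.total_mass <= 0:
            raise ValueError("total_mass must be positive")

    @property
    def pm_mass(self) -> float:
        """Mass of each point mass, M/(n_ce + 1) (kg)."""
        return self.total_mass / (self.n_ce + 1)

    @property
    def pm_masses(self) -> np.ndarray:
        """All n_ce + 1 point masses (kg); index 0 is the fixed end."""
        return np.full(self.n_ce + 1, self.pm_mass)

    @property
    def l_m_opt(self) -> float:
        """Optimal muscle length, n_ce * l_opt (m)."""
        return self.n_ce * self.ce.l_opt

    @property
    def v_m_max0(self) -> float:
        """Theoretical maximum whole-muscle shortening speed (m/s)."""
        return self.ce.b_rel / self.ce.a_rel * self.l_m_opt


@dataclass
class ChainState:
    """Positions and velocities of the free point masses at one instant.

    ``x[j]`` is the coordinate of free PM j+1 (m, measured from the fixed
    end, strictly increasing); ``v[j]`` its velocity (m/s).  The fixed PM
    at x = 0 is not stored.
    """

    t: float
    x: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.x.shape != self.v.shape:
            raise ValueError("x and v must have the same shape")


@dataclass
class CEKinematics:
    """Per-CE lengths, length rates and forces, plus the fixed-end force."""

    lengths: np.ndarray  # m
    velocities: np.ndarray  # m/s, negative = shortening
    forces: np.ndarray  # N, positive = tension
    f_fixed: float  # force at the fixed end, = forces[0] (N)
    l_m: float  # muscle length = free-end position (m)


def build_chain(preset: MusclePreset, n_ce: int) -> ChainModel:
    """Assemble the chain for a muscle preset with ``n_ce`` CEs."""
    return ChainModel(n_ce=n_ce, total_mass=preset.mass, ce=preset.ce_parameters(n_ce))


def initial_state(chain: ChainModel) -> ChainState:
    """Quick-release initial condition: every CE at optimal length, at rest.

    All CEs then pull with F_max, so only the free-end PM is accelerated
    at t = 0.
    """
    j = np.arange(1, chain.n_ce + 1, dtype=float)
    return ChainState(t=0.0, x=j * chain.ce.l_opt, v=np.zeros(chain.n_ce))


def _kinematics_arrays(chain: ChainModel, x: np.ndarray, v: np.ndarray):
    """CE lengths, rates and forces from free-PM coordinates.

    Works on 1-D state arrays or on (n_ce, n_samples) stacks.
    """
    pad = np.zeros((1,) + x.shape[1:])
    l = np.diff(np.concatenate([pad, x], axis=0), axis=0)
    ldot = np.diff(np.concatenate([pad, v], axis=0), axis=0)
    if np.any(l <= 0):
        raise FloatingPointError("non-positive CE length encountered")
    f = ce_force(l, ldot, chain.ce)
    return l, ldot, np.atleast_1d(f)


def _accelerations_arrays(chain: ChainModel, f: np.ndarray) -> np.ndarray:
    """Newton's second law per free PM given CE tensions.

    Free PM j (1-based) feels tension f[j-1] pulling toward the fixed end
    and, if an outer CE exists, f[j] pulling toward the free end; the
    outermost PM feels only -f[-1].
    """
    pad = np.zeros((1,) + f.shape[1:])
    return (np.concatenate([f[1:], pad], axis=0) - f) / chain.pm_mass


def ce_kinematics(chain: ChainModel, state: ChainState) -> CEKinematics:
    """Lengths, rates and forces of all CEs plus the fixed-end force."""
    l, ldot, f = _kinematics_arrays(chain, state.x, state.v)
    return CEKinematics(
        lengths=l,
        velocities=ldot,
        forces=f,
        f_fixed=float(f[0]),
        l_m=float(state.x[-1]),
    )


def accelerations(chain: ChainModel, state: ChainState) -> np.ndarray:
    """Accelerations of the free PMs (m/s^2); the fixed PM has exactly zero."""
    _, _, f = _kinematics_arrays(chain, state.x, state.v)
    return _accelerations_arrays(chain, f)
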