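r"""Time integration of the quick-release contraction.

The chain's equations of motion are integrated with an adaptive
high-order Runge-Kutta method (DOP853) at tight tolerances (default
1e-12 absolute and relative) with dense output.  Three bookkeeping
quantities are integrated alongside the mechanical state so that the
work-energy and momentum theorems can be checked to solver tolerance
rather than to sampling-grid quadrature accuracy:

* cumulative CE work  W(t) = -sum_i \int F_i * l_dot_i dt,
* fixed-end impulse   J(t) = \int F|_{x=0} dt,
* compressive dissipation D(t): energy absorbed by CEs shortening
  beyond their local unloaded speed (F < 0 while l_dot < 0).

Events (zero of the outermost CE force, fixed-end force and free-end
speed thresholds, peak free-end speed) are located by the solver's root
refinement on the dense solution, independent of the output grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .chain import ChainModel, _accelerations_arrays, _kinematics_arrays

logger = logging.getLogger(__name__)

__all__ = ["Trajectory", "simulate", "detect_events"]

DEFAULT_FORCE_FRAC = 0.02  # "force has dropped to almost zero" threshold
DEFAULT_VEL_FRAC = 0.98  # "has reached v_max" threshold


@dataclass
class Trajectory:
    """Sampled solution of one quick-release run.

    Arrays are sampled on a uniform grid of ``t`` (s); per-PM arrays have
    shape (n_ce, n_samples) with PM/CE index leading.  ``events`` maps
    event names to refined times in seconds (None = did not occur):

    * ``outer_force_zero`` — first zero crossing of the outermost CE
      force, i.e. of the free-end acceleration (the effective-mass pole);
    * ``force_settle`` — fixed-end force first below ``force_frac * F_max``;
    * ``velocity_settle`` — free-end speed first above
      ``vel_frac * v_m_max0``;
    * ``peak_velocity`` — time of maximum free-end speed
      (``peak_censored`` is True when the maximum sits at t_end).
    """

    chain: ChainModel
    t: np.ndarray
    x: np.ndarray
    v: np.ndarray
    a: np.ndarray
    ce_length: np.ndarray
    ce_velocity: np.ndarray
    ce_force: np.ndarray
    f_fixed: np.ndarray
    work: np.ndarray
    impulse: np.ndarray
    dissipation: np.ndarray
    events: dict[str, Optional[float]]
    peak_censored: bool
    v_peak: float
    meta: dict = field(default_factory=dict)

    @property
    def free_end_speed(self) -> np.ndarray:
        """Shortening speed of the free end (m/s, positive)."""
        return -self.v[-1]

    @property
    def l_m(self) -> np.ndarray:
        """Muscle length = free-end position (m)."""
        return self.x[-1]


def _rhs(t, y, chain: ChainModel):
    n = chain.n_ce
    x, v = y[:n], y[n : 2 * n]
    l, ldot, f = _kinematics_arrays(chain, x, v)
    a = _accelerations_arrays(chain, f)
    power = f * ldot  # < 0 while shortening under tension
    w_dot = -np.sum(power)
    j_dot = f[0]
    d_dot = np.sum(np.where((f < 0) & (ldot < 0), power, 0.0))
    return np.concatenate([v, a, [w_dot, j_dot, d_dot]])


def simulate(
    chain: ChainModel,
    t_end: float,
    abs_tol: float = 1e-12,
    rel_tol: float = 1e-12,
    n_samples: int = 2000,
    force_frac: float = DEFAULT_FORCE_FRAC,
    vel_frac: float = DEFAULT_VEL_FRAC,
) -> Trajectory:
    """Integrate the quick release from the optimal-length rest state.

    Parameters
    ----------
    chain : ChainModel
    t_end : float
        Simulation horizon (s).
    abs_tol, rel_tol : float
        Solver error tolerances, each in (0, 1e-3].
    n_samples : int
        Number of uniform output samples (dense output is resampled; event
        times do not depend on this grid).
    force_frac, vel_frac : float
        Thresholds, as fractions of F_max and of the theoretical maximum
        muscle speed, for the force-settle and velocity-settle events.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    for tol in (abs_tol, rel_tol):
        if not 0 < tol <= 1e-3:
            raise ValueError("tolerances must lie in (0, 1e-3]")
    if not (0 < force_frac < 1 and 0 < vel_frac < 1):
        raise ValueError("event thresholds must lie in (0, 1)")

    n = chain.n_ce
    j = np.arange(1, n + 1, dtype=float)
    y0 = np.concatenate([j * chain.ce.l_opt, np.zeros(n), np.zeros(3)])

    f_max0 = chain.ce.f_max * chain.ce.q
    v_ref = chain.v_m_max0

    def ev_outer_force(t, y, *_):
        _, _, f = _kinematics_arrays(chain, y[:n], y[n : 2 * n])
        return f[-1]

    ev_outer_force.direction = -1.0

    def ev_force_settle(t, y, *_):
        _, _, f = _kinematics_arrays(chain, y[:n], y[n : 2 * n])
        return f[0] - force_frac * f_max0

    ev_force_settle.direction = -1.0

    def ev_vel_settle(t, y, *_):
        return -y[2 * n - 1] - vel_frac * v_ref

    ev_vel_settle.direction = 1.0

    def ev_length_collapse(t, y, *_):
        x = y[:n]
        l = np.diff(np.concatenate([[0.0], x]))
        return float(np.min(l)) - 1e-9 * chain.ce.l_opt

    ev_length_collapse.direction = -1.0
    ev_length_collapse.terminal = True

    sol = solve_ivp(
        _rhs,
        (0.0, t_end),
        y0,
        method="DOP853",
        args=(chain,),
        rtol=rel_tol,
        atol=abs_tol,
        dense_output=True,
        events=[ev_outer_force, ev_force_settle, ev_vel_settle, ev_length_collapse],
    )
    if sol.status == -1:
        raise RuntimeError(f"integration failed: {sol.message}")
    if sol.status == 1:
        logger.error(
            "CE length collapsed at t = %.6g s; returning partial trajectory",
            sol.t[-1],
        )

    t_stop = sol.t[-1]
    t = np.linspace(0.0, t_stop, n_samples)
    y = sol.sol(t)
    x, v = y[:n], y[n : 2 * n]
    l, ldot, f = _kinematics_arrays(chain, x, v)
    a = _accelerations_arrays(chain, f)

    def first(event_times) -> Optional[float]:
        return float(event_times[0]) if len(event_times) else None

    events: dict[str, Optional[float]] = {
        "outer_force_zero": first(sol.t_events[0]),
        "force_settle": first(sol.t_events[1]),
        "velocity_settle": first(sol.t_events[2]),
    }

    t_peak, v_peak, censored = _refine_peak(
        sol.sol, n, t, -v[-1], events["outer_force_zero"], t_stop
    )
    events["peak_velocity"] = t_peak
    events = dict(events)

    return Trajectory(
        chain=chain,
        t=t,
        x=x,
        v=v,
        a=a,
        ce_length=l,
        ce_velocity=ldot,
        ce_force=f,
        f_fixed=f[0],
        work=y[2 * n],
        impulse=y[2 * n + 1],
        dissipation=y[2 * n + 2],
        events=events,
        peak_censored=censored,
        v_peak=v_peak,
        meta={
            "abs_tol": abs_tol,
            "rel_tol": rel_tol,
            "n_samples": n_samples,
            "force_frac": force_frac,
            "vel_frac": vel_frac,
            "t_end": t_end,
            "n_rhs_evals": int(sol.nfev),
            "terminated_early": bool(sol.status == 1),
        },
    )


def _refine_peak(dense, n, t_grid, speed_grid, t_pole, t_stop):
    """Locate the maximum free-end speed on the dense solution.

    The free-end acceleration vanishes exactly when the outermost CE force
    crosses zero, so when that event occurred its time is the peak.
    Otherwise the grid argmax is refined by bounded scalar minimization;
    a maximum at the final time is flagged as censored.
    """

    def speed(tq):
        return -float(dense(tq)[2 * n - 1])

    if t_pole is not None:
        return t_pole, speed(t_pole), False
    k = int(np.argmax(speed_grid))
    if k == len(t_grid) - 1:
        return float(t_stop), speed(t_stop), True
    lo = t_grid[max(k - 1, 0)]
    hi = t_grid[min(k + 1, len(t_grid) - 1)]
    res = minimize_scalar(lambda tq: -speed(tq), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x), speed(float(res.x)), False


def detect_events(
    traj: Trajectory,
    force_frac: float = DEFAULT_FORCE_FRAC,
    vel_frac: float = DEFAULT_VEL_FRAC,
) -> dict[str, Optional[float]]:
    """Grid-based event detection for trajectories without solver events.

    Used when a trajectory has been re-read from CSV and the dense solution
    is no longer available: crossing times are located by linear
    interpolation between samples.  ``simulate`` populates ``events`` with
    solver-refined times, which take precedence.
    """
    if traj.events:
        return traj.events

    def crossing(t, g):
        s = np.sign(g)
        idx = np.nonzero(np.diff(s) != 0)[0]
        if len(idx) == 0:
            return None
        k = idx[0]
        # linear interpolation across the sign change
        return float(t[k] - g[k] * (t[k + 1] - t[k]) / (g[k + 1] - g[k]))

    f_max0 = traj.chain.ce.f_max * traj.chain.ce.q
    speed = traj.free_end_speed
    k_peak = int(np.argmax(speed))
    return {
        "outer_force_zero": crossing(traj.t, traj.ce_force[-1]),
        "force_settle": crossing(traj.t, traj.f_fixed - force_frac * f_max0),
        "velocity_settle": crossing(traj.t, speed - vel_frac * traj.chain.v_m_max0),
        "peak_velocity": float(traj.t[k_peak]),
    }
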