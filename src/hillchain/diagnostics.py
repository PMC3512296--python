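"""Derived quantities of a quick-release trajectory.

The central diagnostic is the *effective mass*

    mu_eff(t) = F|_{x=0}(t) / x_dd|_{x=l_M}(t),

the ratio of the force at the fixed end to the acceleration of the free
end.  If accelerations increased exactly linearly from the fixed to the
free end, mu_eff would equal half the muscle mass; for a single CE
driving a single free point mass the ratio is M/2 identically.  When the
free-end acceleration crosses zero (the outermost CE reaches its local
unloaded speed), mu_eff has a pole — the signature of the big muscle's
biased kinematics.

Also computed: level-off times of force and velocity, the fraction of
the theoretical maximum speed actually attained, the contraction
fraction, and an energy ledger (kinetic energy vs cumulative CE work,
plus the energy dissipated by CEs pushed beyond their local unloaded
speed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .integrate import Trajectory, detect_events

__all__ = [
    "DiagnosticsReport",
    "effective_mass",
    "mu_eff_stationary",
    "level_off_times",
    "peak_velocity_fraction",
    "contraction_fraction",
    "energy_ledger",
    "report",
]

ACC_FLOOR_FRAC = 1e-6  # mask mu_eff where |a_free| < this fraction of |a_free(0)|

# Continuum limit of the pre-pole stationary effective mass, as a fraction of
# the total muscle mass.  Linearizing the late-time dynamics about the
# uniform-shortening state turns the chain into a diffusion equation for the
# velocity field on [0, L] with v(0) = 0 and zero force (zero velocity
# gradient deviation) at the free end; force and acceleration then decay
# along the slowest mode sin(pi*x/2L), whose fixed-end force over free-end
# acceleration ratio is exactly 2*M/pi.  Finite chains approach this from
# below (M/2 exactly at n_ce = 1).
MU_EFF_CONTINUUM_FRACTION = 2.0 / np.pi


def effective_mass(traj: Trajectory, floor_frac: float = ACC_FLOOR_FRAC) -> np.ndarray:
    """Signed effective-mass series (kg); NaN where the free end is unaccelerated.

    Signed as fixed-end force over free-end *deceleration of length*, so the
    value is positive while the contraction still accelerates and the pole
    (sign change) remains visible.  Samples with free-end acceleration below
    ``floor_frac`` of its initial magnitude are masked rather than divided.
    """
    a_free = traj.a[-1]
    floor = floor_frac * abs(a_free[0])
    out = np.full_like(a_free, np.nan)
    ok = np.abs(a_free) >= floor
    # a_free < 0 while the muscle still speeds up its shortening
    out[ok] = -traj.f_fixed[ok] / a_free[ok]
    return out


def mu_eff_stationary(traj: Trajectory) -> tuple[float, str]:
    """Stationary effective mass (kg) and a description of the window used.

    When the effective-mass pole occurs inside the run the value at the
    last unmasked sample before the pole is reported; otherwise the median
    over the final 20 % of unmasked samples.
    """
    mu = effective_mass(traj)
    t_pole = traj.events.get("outer_force_zero")
    if t_pole is not None:
        pre = np.nonzero((traj.t < t_pole) & np.isfinite(mu))[0]
        if len(pre) == 0:
            return float("nan"), "no unmasked pre-pole samples"
        k = pre[-1]
        return float(mu[k]), f"last pre-pole sample (t = {traj.t[k]:.6g} s)"
    ok = np.nonzero(np.isfinite(mu))[0]
    if len(ok) == 0:
        return float("nan"), "no unmasked samples"
    window = ok[int(0.8 * len(ok)) :]
    return (
        float(np.median(mu[window])),
        "median over final 20% of unmasked samples "
        f"(t in [{traj.t[window[0]]:.6g}, {traj.t[window[-1]]:.6g}] s)",
    )


def level_off_times(
    traj: Trajectory,
    force_frac: float | None = None,
    vel_frac: float | None = None,
) -> tuple[Optional[float], Optional[float]]:
    """(t_force_settle, t_velocity_settle) in seconds; None = not occurred.

    Taken from the solver-refined event table when the thresholds match the
    ones used during integration, otherwise recomputed on the sample grid.
    """
    meta = traj.meta
    same = (force_frac is None or force_frac == meta.get("force_frac")) and (
        vel_frac is None or vel_frac == meta.get("vel_frac")
    )
    if same and traj.events:
        return traj.events.get("force_settle"), traj.events.get("velocity_settle")
    ev = detect_events(
        Trajectory(**{**traj.__dict__, "events": {}}),
        force_frac=force_frac if force_frac is not None else meta.get("force_frac", 0.02),
        vel_frac=vel_frac if vel_frac is not None else meta.get("vel_frac", 0.98),
    )
    return ev["force_settle"], ev["velocity_settle"]


def peak_velocity_fraction(traj: Trajectory) -> tuple[float, bool]:
    """Peak free-end speed over the theoretical maximum v_M,max,0.

    Returns ``(fraction, censored)``; censored is True when the maximum sat
    at the end of the run (the true peak may lie beyond the horizon).
    """
    return traj.v_peak / traj.chain.v_m_max0, traj.peak_censored


def contraction_fraction(traj: Trajectory, t) -> np.ndarray | float:
    """Shortening (l_M,opt - l_M(t)) / l_M,opt at time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > traj.t[-1]):
        raise ValueError("t outside the simulated horizon")
    l_m = np.interp(t, traj.t, traj.l_m)
    out = (traj.chain.l_m_opt - l_m) / traj.chain.l_m_opt
    return float(out) if out.ndim == 0 else out


def energy_ledger(traj: Trajectory) -> dict:
    """Kinetic energy, cumulative CE work, their residual, and dissipation (J).

    Kinetic energy is evaluated from the sampled velocities; CE work and the
    compressive-dissipation total were integrated alongside the dynamics, so
    the residual reflects solver accuracy only.
    """
    ke = 0.5 * traj.chain.pm_mass * np.sum(traj.v**2, axis=0)
    return {
        "kinetic": ke,
        "work": traj.work,
        "residual": ke - traj.work,
        "dissipation_total": float(traj.dissipation[-1]),
    }


@dataclass
class DiagnosticsReport:
    """Scalar summary of one run plus the effective-mass series."""

    mu_eff: np.ndarray
    mu_eff_stationary: float
    stationary_window: str
    pole_time: Optional[float]
    t_force_settle: Optional[float]
    t_velocity_settle: Optional[float]
    v_peak: float
    v_peak_fraction: float
    peak_censored: bool
    contraction_fraction_final: float
    energy: dict = field(repr=False)
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-ready scalar view (series are summarized, not dumped)."""
        e = self.energy
        return {
            "mu_eff_stationary_kg": self.mu_eff_stationary,
            "stationary_window": self.stationary_window,
            "pole_time_s": self.pole_time,
            "t_force_settle_s": self.t_force_settle,
            "t_velocity_settle_s": self.t_velocity_settle,
            "v_peak_m_per_s": self.v_peak,
            "v_peak_fraction": self.v_peak_fraction,
            "peak_censored": self.peak_censored,
            "contraction_fraction_final": self.contraction_fraction_final,
            "kinetic_energy_final_J": float(e["kinetic"][-1]),
            "ce_work_final_J": float(e["work"][-1]),
            "energy_residual_max_J": float(np.max(np.abs(e["residual"]))),
            "dissipation_total_J": e["dissipation_total"],
            "thresholds": self.thresholds,
        }


def report(traj: Trajectory) -> DiagnosticsReport:
    """Assemble the full diagnostics report for one trajectory."""
    mu = effective_mass(traj)
    mu_stat, window = mu_eff_stationary(traj)
    t_force, t_vel = level_off_times(traj)
    frac, censored = peak_velocity_fraction(traj)
    return DiagnosticsReport(
        mu_eff=mu,
        mu_eff_stationary=mu_stat,
        stationary_window=window,
        pole_time=traj.events.get("outer_force_zero"),
        t_force_settle=t_force,
        t_velocity_settle=t_vel,
        v_peak=traj.v_peak,
        v_peak_fraction=frac,
        peak_censored=censored,
        contraction_fraction_final=float(contraction_fraction(traj, traj.t[-1])),
        energy=energy_ledger(traj),
        thresholds={
            "force_frac": traj.meta.get("force_frac"),
            "vel_frac": traj.meta.get("vel_frac"),
            "acc_floor_frac": ACC_FLOOR_FRAC,
        },
    )
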