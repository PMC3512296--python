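"""Force law of a single Hill-type contractile element (CE).

A CE produces force as the product of an isometric force--length factor
(a bell curve peaking at the optimal length ``l_opt``) and a hyperbolic
force--velocity relation (the Hill relation).  With the normalized
shortening rate ``u = -l_dot / l_opt`` the concentric branch is

    F(u) = (F_isom + A) * B / (B + u) - A,

where ``F_isom = F_max * q * f_isom(l)`` is the current isometric force,
``A = A_rel * F_max * q`` and ``B = B_rel`` are the hyperbola's asymptotes.
This construction has F(0) = F_isom, crosses zero exactly at
``u = (B_rel / A_rel) * f_isom(l)`` — so the local unloaded shortening
speed scales with the force--length factor — and is continued smoothly
past the zero crossing, yielding bounded compressive (negative) forces
with asymptote ``-A`` as u -> infinity.

All quantities are SI (m, s, kg, N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_warned: set[str] = set()


def _warn_once(key: str, msg: str, *args) -> None:
    """First occurrence at WARNING, repeats at DEBUG (solver trial stages
    can hit the eccentric guard thousands of times per run)."""
    if key in _warned:
        logger.debug(msg, *args)
    else:
        _warned.add(key)
        logger.warning(msg, *args)

__all__ = [
    "CEParameters",
    "isometric_factor",
    "ce_force",
    "local_vmax",
    "force_velocity_slope",
]


@dataclass(frozen=True)
class CEParameters:
    """Static and dynamic constants of one contractile element.

    Parameters
    ----------
    f_max : float
        Maximum isometric force (N).
    l_opt : float
        Optimal CE length (m), where the force--length factor peaks.
    a_rel, b_rel : float
        Normalized Hill asymptotes (dimensionless and 1/s).  Together they
        fix the unloaded shortening speed ``v_max = (b_rel/a_rel)*l_opt``
        and the curvature of the force--velocity hyperbola.
    q : float
        Activity level in [0, 1] (1 = fully active).
    dw_asc, nu_asc : float
        Width and exponent of the ascending (short-length) branch of the
        force--length bell.
    dw_des, nu_des : float
        Width and exponent of the descending (long-length) branch.
    """

    f_max: float
    l_opt: float
    a_rel: float = 0.1
    b_rel: float = 1.0
    q: float = 1.0
    dw_asc: float = 0.505
    nu_asc: float = 4.0
    dw_des: float = 0.30
    nu_des: float = 2.0

    def __post_init__(self) -> None:
        if self.f_max <= 0:
            raise ValueError(f"f_max must be positive, got {self.f_max}")
        if self.l_opt <= 0:
            raise ValueError(f"l_opt must be positive, got {self.l_opt}")
        if self.a_rel <= 0 or self.b_rel <= 0:
            raise ValueError("Hill parameters a_rel, b_rel must be positive")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"activity q must lie in [0, 1], got {self.q}")
        if self.dw_asc <= 0 or self.dw_des <= 0:
            raise ValueError("bell widths dw_asc, dw_des must be positive")
        if self.nu_asc < 1 or self.nu_des < 1:
            raise ValueError("bell exponents nu_asc, nu_des must be >= 1")

    @property
    def vmax_opt(self) -> float:
        """Unloaded shortening speed at optimal length, (b_rel/a_rel)*l_opt (m/s)."""
        return self.b_rel / self.a_rel * self.l_opt


def _check_length(l) -> np.ndarray:
    l = np.asarray(l, dtype=float)
    if np.any(l <= 0):
        raise ValueError("CE length must be positive")
    return l


def isometric_factor(l, p: CEParameters):
    """Force--length factor f_isom(l) in [0, 1].

    Two exponential bell branches, ``exp(-|(l/l_opt - 1)/dw|**nu)``, joined
    at ``l_opt`` where both have value 1 and (for nu > 1) zero slope: the
    ascending branch applies for l <= l_opt, the descending for l > l_opt.
    """
    l = _check_length(l)
    rel = l / p.l_opt - 1.0
    asc = np.exp(-np.abs(rel / p.dw_asc) ** p.nu_asc)
    des = np.exp(-np.abs(rel / p.dw_des) ** p.nu_des)
    out = np.where(rel <= 0.0, asc, des)
    return float(out) if out.ndim == 0 else out


def local_vmax(l, p: CEParameters):
    """Length-dependent unloaded shortening speed (m/s).

    ``v_max(l) = (b_rel/a_rel) * l_opt * f_isom(l)`` — the shortening speed
    at which :func:`ce_force` crosses zero.
    """
    return p.b_rel / p.a_rel * p.l_opt * isometric_factor(l, p)


# Lengthening is outside the concentric scenario this model targets: the same
# hyperbola is continued for mild lengthening rates and the force is clamped
# at 1.5x the current isometric force before the hyperbola's pole at
# u = -b_rel can be reached.
_ECC_U_FLOOR_FRAC = 0.5  # clamp activates for u <= -0.5 * b_rel
_ECC_FORCE_CAP = 1.5  # in units of the current isometric force


def ce_force(l, ldot, p: CEParameters):
    """CE force (N) at length ``l`` and length rate ``ldot`` (negative = shortening).

    Concentric branch: the Hill hyperbola described in the module docstring,
    extrapolated smoothly beyond its zero crossing to bounded compressive
    forces.  Mild lengthening (u < 0) continues the same hyperbola; the force
    is clamped at ``1.5 * F_isom`` (with a logged warning) before the
    hyperbola's pole, so no unbounded value is ever returned.
    """
    l = _check_length(l)
    ldot = np.asarray(ldot, dtype=float)
    u = -ldot / p.l_opt
    f_isom = p.f_max * p.q * isometric_factor(l, p)
    a = p.a_rel * p.f_max * p.q
    b = p.b_rel

    u_floor = -_ECC_U_FLOOR_FRAC * b
    at_floor = u <= u_floor
    if np.any(at_floor):
        _warn_once(
            "pole_guard",
            "lengthening rate at or beyond the hyperbola pole guard "
            "(u <= %.3g 1/s); force clamped at %.1fx isometric",
            u_floor,
            _ECC_FORCE_CAP,
        )
    u_safe = np.where(at_floor, u_floor, u)
    f = (f_isom + a) * b / (b + u_safe) - a

    cap = _ECC_FORCE_CAP * f_isom
    over = f > cap
    if np.any(over & ~at_floor):
        _warn_once("ecc_cap", "eccentric force clamped at %.1fx isometric",
                   _ECC_FORCE_CAP)
    f = np.where(over, cap, f)
    return float(f) if f.ndim == 0 else f


def force_velocity_slope(u, p: CEParameters, l=None):
    """Magnitude of the force--velocity slope |dF/dv| (N*s/m) at rate ``u``.

    On the concentric branch (u >= 0),

        |dF/dv| = (F_isom + A) * B / ((B + u)^2 * l_opt),

    with F_isom evaluated at ``l`` (optimal length if omitted).  This is the
    damping coefficient the hyperbola presents to an inertial load at the
    operating point, and the quantity whose reciprocal (times the accelerated
    mass) sets the linearized step-response time constant.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("slope is defined on the concentric branch (u >= 0)")
    f_isom = p.f_max * p.q * (1.0 if l is None else isometric_factor(l, p))
    a = p.a_rel * p.f_max * p.q
    s = (f_isom + a) * p.b_rel / ((p.b_rel + u) ** 2 * p.l_opt)
    return float(s) if s.ndim == 0 else s
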