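r"""Closed-form companions to the chain simulation.

Linearizing the hyperbolic force--velocity relation at any operating
point turns the single-mass force-step problem into a first-order linear
ODE: the velocity relaxes aperiodically (no overshoot) toward a limit
velocity with time constant

    tau = m / |dF/dv|,

the accelerated mass over the local slope of the hyperbola.  tau grows
as (B_rel + u0)^2 along the concentric branch, so a muscle responds to
force steps two orders of magnitude faster near the isometric state than
near its unloaded maximum speed: the ratio between the two extremes is
exactly (1 + 1/A_rel)^2 = 121 for A_rel = 0.1.

Because muscle density rho and maximum stress sigma_max are roughly
invariant across muscle designs, substituting M = rho*S*l and
F_max = sigma_max*S shows tau scales with the *square* of fibre length —
the reason big muscles never reach their theoretical maximum contraction
velocity while small ones do.

The module also provides the full-hyperbola single-mass quadrature,
t(u) = m*l_opt * \int_0^u du'/F(u'), used as an independent oracle for
the chain integrator at n_ce = 1, and the excitation-propagation time
l/c for comparison with tau.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .ce import CEParameters, ce_force, force_velocity_slope, isometric_factor
from .presets import MusclePreset

__all__ = [
    "LinearizedResponse",
    "ScalingContext",
    "tau_linearized",
    "step_response_linearized",
    "single_mass_quadrature",
    "single_mass_rate_at_time",
    "geometric_scale",
    "tau_fiber_length",
    "propagation_time",
]


def tau_linearized(m: float, p: CEParameters, u0: float, l: float | None = None) -> float:
    """Time constant (s) of the linearized force-step response at rate ``u0``.

    ``tau = m / |dF/dv|`` evaluated at the operating point: explicitly,
    ``m * l_opt * (b_rel + u0)^2 / (F_max * q * f_isom * (1 + a_rel) * b_rel)``
    for a CE at optimal length.
    """
    if m <= 0:
        raise ValueError("accelerated mass must be positive")
    return m / force_velocity_slope(u0, p, l=l)


@dataclass(frozen=True)
class LinearizedResponse:
    """Analytic solution of one mass driven by the linearized hyperbola.

    ``velocity(t)`` returns the shortening speed (m/s, positive), decaying
    exponentially from ``v0`` toward ``v_limit`` with time constant ``tau``
    and no overshoot.
    """

    m: float
    u0: float
    tau: float
    v0: float
    v_limit: float

    def velocity(self, t):
        t = np.asarray(t, dtype=float)
        v = self.v_limit + (self.v0 - self.v_limit) * np.exp(-t / self.tau)
        return float(v) if v.ndim == 0 else v


def step_response_linearized(
    m: float, p: CEParameters, u0: float, f_external: float = 0.0
) -> LinearizedResponse:
    """Linearized response to a step of the external force to ``f_external``.

    The hyperbola is linearized at ``u0``; the mass then obeys
    ``m*l_opt*du/dt = -k*(u - u_limit)`` with ``k = -dF/du`` and the limit
    rate solving the linearized force balance F_lin(u) = f_external.
    """
    slope_v = force_velocity_slope(u0, p)  # N s/m
    f0 = ce_force(p.l_opt, -u0 * p.l_opt, p)
    tau = tau_linearized(m, p, u0)
    u_limit = u0 + (f0 - f_external) / (slope_v * p.l_opt)
    return LinearizedResponse(
        m=m, u0=u0, tau=tau, v0=u0 * p.l_opt, v_limit=u_limit * p.l_opt
    )


def single_mass_quadrature(m: float, p: CEParameters, u_target: float) -> float:
    """Time (s) for one mass driven by one CE to reach shortening rate ``u_target``.

    Solves ``m * l_opt * du/dt = F(u)`` by adaptive quadrature of
    ``t(u) = m * l_opt * \\int_0^u du'/F(u')`` with the force--length factor
    held at its initial value 1 (the chain shortens by well under 1 % of
    l_opt on the horizons where this oracle is used).
    """
    if m <= 0:
        raise ValueError("mass must be positive")
    u_zero = p.b_rel / p.a_rel  # zero-force rate at f_isom = 1
    if not 0 <= u_target < u_zero:
        raise ValueError(
            f"u_target must lie in [0, {u_zero}) — the integral is improper "
            "at the zero-force rate"
        )
    if u_target == 0:
        return 0.0
    # Substituting u = u_zero*(1 - exp(-s)) regularizes the integrable
    # logarithmic endpoint singularity at the zero-force rate: the integrand
    # u_zero*exp(-s)/F tends to the reciprocal hyperbola slope as s grows.
    s_target = -np.log1p(-u_target / u_zero)

    def integrand(s):
        e = np.exp(-s)
        u = u_zero * (1.0 - e)
        return u_zero * e / ce_force(p.l_opt, -u * p.l_opt, p)

    val, _ = quad(integrand, 0.0, s_target, epsabs=0.0, epsrel=1e-11, limit=300)
    return m * p.l_opt * val


def single_mass_rate_at_time(
    m: float, p: CEParameters, t, n_nodes: int = 400
) -> np.ndarray | float:
    """Inverse of :func:`single_mass_quadrature`: normalized rate u at time(s) t.

    The strictly increasing map u -> t(u) is evaluated by quadrature on a
    cosine-clustered node grid up to the largest rate reached within
    ``max(t)`` (located by bracketing root finding) and inverted with a
    monotone cubic interpolant; node density keeps the interpolation error
    orders of magnitude below the quadrature tolerance.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    t_max = float(np.max(t)) if t.size else 0.0
    if t_max == 0.0:
        out = np.zeros_like(t)
        return float(out) if out.ndim == 0 else out

    u_zero = p.b_rel / p.a_rel
    u_cap = u_zero * (1.0 - 1e-12)
    # bracketing probe only; full quadrature precision is not needed here
    # and quad complains about the scale span next to the zero-force rate
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if single_mass_quadrature(m, p, u_cap) <= t_max:
            u_hi = u_cap
        else:
            u_hi = brentq(
                lambda u: single_mass_quadrature(m, p, u) - t_max,
                0.0,
                u_cap,
                xtol=1e-15,
                rtol=8.9e-16,
            )

    theta = np.linspace(0.0, np.pi, n_nodes + 1)
    u_nodes = u_hi * 0.5 * (1.0 - np.cos(theta))
    t_nodes = np.array([single_mass_quadrature(m, p, u) for u in u_nodes])
    from scipy.interpolate import PchipInterpolator

    u_of_t = PchipInterpolator(t_nodes, u_nodes, extrapolate=False)
    out = np.where(t >= t_nodes[-1], u_hi, u_of_t(np.minimum(t, t_nodes[-1])))
    return float(out) if out.ndim == 0 else out


def geometric_scale(preset: MusclePreset, k_l: float, k_s: float) -> MusclePreset:
    """Scale a muscle design by ``k_l`` in length and ``k_s`` in cross-section.

    Mass scales with volume (k_l*k_s), maximum force with area (k_s),
    optimal length — and hence maximum speed — with k_l; the normalized Hill
    parameters are design invariants.
    """
    if k_l <= 0 or k_s <= 0:
        raise ValueError("scale factors must be positive")
    name = preset.name if (k_l == 1 and k_s == 1) else f"{preset.name}*{k_l:g}x{k_s:g}"
    return replace(
        preset,
        name=name,
        mass=preset.mass * k_l * k_s,
        f_max=preset.f_max * k_s,
        l_m_opt=preset.l_m_opt * k_l,
    )


@dataclass(frozen=True)
class ScalingContext:
    """Tissue invariants for geometric scaling: density and maximum stress."""

    density: float  # kg/m^3
    sigma_max: float  # Pa

    def __post_init__(self) -> None:
        if self.density <= 0 or self.sigma_max <= 0:
            raise ValueError("density and sigma_max must be positive")

    @classmethod
    def from_preset(cls, preset: MusclePreset, density: float = 1060.0) -> "ScalingContext":
        """Derive the (rho, sigma_max) pair implied by a preset.

        Only the ratio rho/sigma_max = M/(F_max * l_M,opt) enters the time
        constant; the density default is typical striated-muscle tissue.
        """
        sigma = density * preset.f_max * preset.l_m_opt / preset.mass
        return cls(density=density, sigma_max=sigma)


def tau_fiber_length(
    l: float, ctx: ScalingContext, p: CEParameters, u0: float
) -> float:
    """Linearized time constant (s) as a function of fibre length alone.

    Substituting M = rho*S*l and F_max = sigma_max*S into ``tau_linearized``
    cancels the cross-section:

        tau = rho * l^2 * (b_rel + u0)^2 / (sigma_max * (1 + a_rel) * b_rel)

    — quadratic in fibre length at fixed tissue properties.
    """
    if l <= 0:
        raise ValueError("fibre length must be positive")
    if u0 < 0:
        raise ValueError("u0 must be on the concentric branch")
    return (
        ctx.density
        * l**2
        * (p.b_rel + u0) ** 2
        / (ctx.sigma_max * (1.0 + p.a_rel) * p.b_rel * p.q)
    )


def propagation_time(l: float, c: float = 4.0) -> float:
    """Time (s) for the excitation wave to travel fibre length ``l`` at speed ``c``.

    Surface propagation of excitation in vertebrate cross-striated muscle is
    about 4 m/s; comparing l/c with tau separates excitation-limited from
    inertia-limited response times.
    """
    if l < 0:
        raise ValueError("length must be non-negative")
    if c <= 0:
        raise ValueError("propagation speed must be positive")
    return l / c
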