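# Methods

## The model

A muscle is represented as a one-dimensional chain: `n_ce + 1` point
masses (PMs) in alternating sequence with `n_ce` contractile elements
(CEs), lying along the x-axis with the first PM clamped at x = 0. Mass
is distributed homogeneously — every PM carries ℳ/(n_ce + 1) — and all
CEs are identical, with optimal length l_M,opt/n_ce. This is the
discrete form of dF = ẍ·(ℳ/l_M)·dx for a continuous rod whose only
constitutive law is the CE force relation; letting n_ce grow approaches
the continuum (in practice the n_ce = 16 and 32 solutions are
indistinguishable at the 1%-of-v_max level).

Each CE force is the product structure standard for Hill-type models:

* a force–length factor `f_isom(l) = exp(−|(l/l_opt − 1)/dw|^nu)` with
  separate (dw, nu) per branch, joined with value 1 and zero slope at
  l_opt;
* a force–velocity hyperbola in the normalized shortening rate
  u = −l̇/l_opt:

      F(u) = (F_isom + A)·B/(B + u) − A,
      F_isom = F_max·q·f_isom(l),  A = A_rel·F_max·q,  B = B_rel.

The anchoring of the asymptote A to *maximum* isometric force (rather
than to the current F_isom) is a deliberate construction: it leaves
F(0) = F_isom and places the zero crossing exactly at
u = (B_rel/A_rel)·f_isom(l), so the local unloaded speed
v_max(l) = (B_rel/A_rel)·l_opt·f_isom(l) scales with the force–length
factor, and it reduces to the current-force normalization at l = l_opt,
where all the analytic time constants are evaluated. The same hyperbola
is continued past the zero crossing, giving bounded compressive forces
(asymptote −A as u → ∞) for CEs driven beyond their local v_max by the
momentum of their neighbours. Whether such compressive forces are
physiological is an open question; here they are a modelling choice that
keeps the force law smooth where the free end overruns v_max.

Excluded on purpose: serial and parallel elasticity (hence no
oscillations), activation dynamics (q ≡ 1), gravity, eccentric
force–velocity modelling. Mild lengthening rates continue the concentric
hyperbola; at u ≤ −B_rel/2 the force is clamped at 1.5·F_isom with a
logged warning. The clamp exists to keep rejected solver trial stages
finite — accepted states in the quick-release scenario never lengthen.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| ℳ, F_max, l_M,opt | design parameters | presets below | set static scale |
| A_rel | normalized Hill asymptote (–) | 0.1 | typical mammalian curvature; fixes v_max = 10·l_M,opt/s with B_rel |
| B_rel | normalized Hill asymptote (1/s) | 1.0 | idem |
| q | activity | 1 | fully active throughout |
| dw_asc, nu_asc | ascending bell branch | 0.505, 4 | broad ascending branch: f_isom(0.76·l_opt) = 0.95 |
| dw_des, nu_des | descending bell branch | 0.30, 2 | generic; never visited in these scenarios |
| abs_tol, rel_tol | solver tolerances | 1e-12 | far below all reported effects |
| force_frac | "force ≈ 0" threshold | 0.02·F_max | operationalizes the qualitative level-off |
| vel_frac | "v_max reached" threshold | 0.98·v_M,max,0 | idem |

Presets: `small` — ℳ = 6.5 g, F_max = 30 N, l_M,opt = 15 mm (piglet
plantar-flexor assembly); `big` — the small preset scaled ×10 in length
and ×10 in cross-section (650 g, 300 N, 150 mm). The bell-branch values
are a calibration, not a measurement: the underlying experimental
parameter set is not available, and the single anchor used is that a CE
shortened by 24% retains about 95% of its isometric force. The
big-muscle results (pole time, contraction fraction, peak-velocity
fraction) inherit an O(5%) sensitivity to this branch; the small-muscle
results do not (sub-2% shortening).

Units are SI internally; the TOML config surface takes grams,
millimeters and newtons for bench readability.

## Numerics

The equations of motion (Newton's law per free PM, with CE tensions from
the force law) are integrated with `scipy.integrate.solve_ivp`'s DOP853
at abs_tol = rel_tol = 1e-12 with dense output. Three bookkeeping states
are integrated alongside: cumulative CE work, fixed-end impulse, and the
energy absorbed by CEs in compression while shortening ("dissipation").
This makes the work–energy and momentum checks solver-accurate instead
of sampling-grid-accurate: on all shipped scenarios
|KE − W| < 1e-11·max KE and |Σmv + ∫F dt| < 1e-11·max impulse.

Events — the first zero of the outermost CE force (equivalently of the
free-end acceleration: the effective-mass pole), the force and velocity
threshold crossings, and the peak free-end speed — are located by the
solver's root refinement on the dense solution and are therefore
independent of the output grid (2000 uniform samples by default). A
maximum sitting at the end of the horizon is flagged censored. A
terminal guard aborts with a partial trajectory if any CE length
approaches zero (never triggered in the study scenarios).

Effective-mass samples with free-end acceleration below 1e-6 of its
initial magnitude are masked, not divided. The "stationary" effective
mass is reported as the value at the last unmasked pre-pole sample when
a pole occurs, else the median over the final 20% of unmasked samples,
always together with the window used.

Horizons are 2 ms (small) and 60 ms (big): the small muscle completes
its transient within 0.5 ms, the big one crosses its effective-mass pole
near 30 ms; the extra margin shows the post-pole deceleration.
The single-mass quadrature oracle integrates 1/F(u) with the
substitution u = u_zero·(1 − e^(−s)), which regularizes the integrable
endpoint singularity at the zero-force rate.

## Analytic companions

Linearizing the hyperbola at operating point u₀ turns the single-mass
force-step problem into m·l_opt·du/dt = −k·(u − u_lim) with
k = (F_isom + A)·B/(B + u₀)², i.e. an aperiodic exponential decay with

    τ = m / |dF/dv| = m·l_opt·(B_rel + u₀)² / (F_max·q·f_isom·(1 + A_rel)·B_rel).

τ spans (1 + 1/A_rel)² = 121 between the isometric and unloaded points.
With the whole muscle mass accelerated by one CE this gives 3.0 µs
(small, u₀ = 0), 0.36 ms (small, u₀ = 10) and 36 ms (big, u₀ = 10).
Substituting ℳ = ρSl and F_max = σ_max·S cancels the cross-section and
gives τ = ρ·l²·(B_rel + u₀)²/(σ_max·(1 + A_rel)·B_rel): response times
scale with the square of fibre length. Compared with the ~4 m/s surface
propagation speed of excitation, inertia overtakes propagation as the
limiting process somewhere between 1.5 and 15 cm of fibre length.

A full-hyperbola quadrature, t(u) = m·l_opt·∫₀ᵘ du′/F(u′) with f_isom
held at 1, serves as an independent oracle for the chain integrator at
n_ce = 1. Its validity window is the sub-1% shortening regime: beyond
that the simulation visibly (at the few-1e-6 relative level) lags the
drifting force–length target, a real effect the frozen-f_isom oracle
excludes by construction.

## Stationary effective mass: the 2ℳ/π limit

For n_ce = 1 the effective mass is ℳ/2 at every instant — with one CE
the acceleration "distribution" is trivially linear. For fine chains the
small-muscle μ_eff saturates slightly *above* ℳ/2 (3.25 → 3.51 → 3.75 →
3.92 → 4.02 → 4.08 g for n_ce = 1…32). The limit is derivable: once all
CEs operate near their unloaded rate, linearizing the force law turns
the chain into a diffusion equation for the velocity deviation field on
[0, L] with v = 0 at the fixed end and zero gradient (zero force) at the
free end. Force and acceleration then decay along the slowest mode
sin(πx/2L), whose fixed-end-force to free-end-acceleration ratio is
exactly 2ℳ/π ≈ 0.637·ℳ (4.14 g for the small muscle). The discrete
chain approaches this from below. In the big muscle no such plateau
forms: the free-end acceleration crosses zero (μ_eff pole) before the
acceleration distribution linearizes.

## What the simulations show — and what they cannot

The simulated quick release reproduces, from the force law and the mass
distribution alone: force level-off at ~0.16 ms and velocity level-off
at ~0.40 ms in the small muscle (against the qualitative "about 0.2 /
about 0.5 ms" with 2% / 98% thresholds); the hundredfold time scale of
the big muscle; its effective-mass pole at ~36 ms (n_ce = 1) / ~29 ms
(n_ce = 32); ~24% shortening by 30 ms; and a peak speed of ~93% of
v_M,max,0 for a 15 cm fibre.

These are model statements, not measurements: a real muscle has serial
and parallel elasticity (which superpose oscillations on the aperiodic
decay and may partly compensate the force–length droop), distributed
activation, non-homogeneous mass, and transverse constraints that the
compressive extrapolation only caricatures. The model's value is the
time-scale and scaling structure — in particular that inertial response
times grow with fibre length squared — not curve-level prediction of any
particular preparation.
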