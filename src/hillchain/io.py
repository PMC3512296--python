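"""Configuration loading and trajectory/diagnostics serialization.

Configuration files are TOML with two tables.  The ``[muscle]`` table
uses bench-friendly units (grams, millimeters, newtons), converted to SI
on load; the ``[run]`` table holds integration settings::

    [muscle]
    preset = "small"     # optional base preset
    mass_g = 6.5
    f_max_n = 30.0
    l_opt_mm = 15.0
    a_rel = 0.1
    b_rel = 1.0
    q = 1.0

    [run]
    n_ce = 32
    t_end_ms = 2.0
    abs_tol = 1e-12
    rel_tol = 1e-12
    n_samples = 2000
    force_frac = 0.02
    vel_frac = 0.98

Unknown keys are rejected with the offending key path.  Trajectories are
written as flat CSV (one row per sample) with a JSON sidecar carrying the
fully resolved configuration and the event table, so every run can be
reproduced from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chain import ChainModel
from .integrate import Trajectory
from .presets import MusclePreset, get_preset

logger = logging.getLogger(__name__)

__all__ = ["RunSettings", "load_config", "write_trajectory", "read_trajectory",
           "write_diagnostics"]


@dataclass(frozen=True)
class RunSettings:
    """Integration settings for one quick-release run."""

    n_ce: int = 32
    t_end: float = 2e-3  # s
    abs_tol: float = 1e-12
    rel_tol: float = 1e-12
    n_samples: int = 2000
    force_frac: float = 0.02
    vel_frac: float = 0.98

    def __post_init__(self) -> None:
        if self.n_ce < 1:
            raise ValueError(f"run.n_ce must be >= 1, got {self.n_ce}")
        if self.t_end <= 0:
            raise ValueError("run.t_end must be positive")
        if self.n_samples < 2:
            raise ValueError("run.n_samples must be >= 2")


_MUSCLE_KEYS = {
    "preset", "mass_g", "f_max_n", "l_opt_mm", "a_rel", "b_rel", "q",
    "dw_asc", "nu_asc", "dw_des", "nu_des",
}
_RUN_KEYS = {"n_ce", "t_end_ms", "abs_tol", "rel_tol", "n_samples",
             "force_frac", "vel_frac"}

# config-surface key -> (MusclePreset field, conversion to SI)
_MUSCLE_MAP = {
    "mass_g": ("mass", 1e-3),
    "f_max_n": ("f_max", 1.0),
    "l_opt_mm": ("l_m_opt", 1e-3),
    "a_rel": ("a_rel", 1.0),
    "b_rel": ("b_rel", 1.0),
    "q": ("q", 1.0),
    "dw_asc": ("dw_asc", 1.0),
    "nu_asc": ("nu_asc", 1.0),
    "dw_des": ("dw_des", 1.0),
    "nu_des": ("nu_des", 1.0),
}


def load_config(
    path: str | Path | None = None,
    preset: str | None = None,
    muscle_overrides: dict | None = None,
    run_overrides: dict | None = None,
) -> tuple[MusclePreset, RunSettings]:
    """Resolve a muscle preset and run settings from a file and/or overrides.

    Precedence: named preset < config file < explicit overrides (overrides
    use SI field names, e.g. ``f_max=60.0``).  The resolved parameters are
    echoed to the log.
    """
    muscle_cfg: dict = {}
    run_cfg: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
        unknown_tables = set(cfg) - {"muscle", "run"}
        if unknown_tables:
            raise ValueError(f"unknown config table(s): {sorted(unknown_tables)}")
        muscle_cfg = dict(cfg.get("muscle", {}))
        run_cfg = dict(cfg.get("run", {}))
        for key in muscle_cfg:
            if key not in _MUSCLE_KEYS:
                raise ValueError(f"unknown config key muscle.{key}")
        for key in run_cfg:
            if key not in _RUN_KEYS:
                raise ValueError(f"unknown config key run.{key}")

    preset_name = preset or muscle_cfg.pop("preset", None)
    if preset_name is not None:
        base = get_preset(preset_name)
    else:
        required = {"mass_g", "f_max_n", "l_opt_mm"}
        missing = required - set(muscle_cfg)
        if missing:
            raise ValueError(
                f"no preset named and muscle.{sorted(missing)} missing from config"
            )
        base = MusclePreset(name="custom", mass=1.0, f_max=1.0, l_m_opt=1.0)

    fields = {}
    for key, value in muscle_cfg.items():
        field, factor = _MUSCLE_MAP[key]
        fields[field] = value * factor
    if muscle_overrides:
        valid = {f.name for f in dataclasses.fields(MusclePreset)}
        bad = set(muscle_overrides) - valid
        if bad:
            raise ValueError(f"unknown muscle override(s): {sorted(bad)}")
        fields.update(muscle_overrides)
    muscle = base.with_overrides(**fields) if fields else base

    run_fields = {}
    if "t_end_ms" in run_cfg:
        run_fields["t_end"] = run_cfg.pop("t_end_ms") * 1e-3
    run_fields.update(run_cfg)
    if run_overrides:
        valid = {f.name for f in dataclasses.fields(RunSettings)}
        bad = set(run_overrides) - valid
        if bad:
            raise ValueError(f"unknown run override(s): {sorted(bad)}")
        run_fields.update(run_overrides)
    settings = RunSettings(**run_fields)

    logger.info(
        "resolved muscle %s: mass=%.6g kg, F_max=%.6g N, l_M,opt=%.6g m, "
        "A_rel=%.3g, B_rel=%.3g 1/s, q=%.3g",
        muscle.name, muscle.mass, muscle.f_max, muscle.l_m_opt,
        muscle.a_rel, muscle.b_rel, muscle.q,
    )
    logger.info("run settings: %s", settings)
    return muscle, settings


def _trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    n = traj.chain.n_ce
    cols: dict[str, np.ndarray] = {"t": traj.t}
    for j in range(n):
        cols[f"x_{j+1}"] = traj.x[j]
    for j in range(n):
        cols[f"v_{j+1}"] = traj.v[j]
    for j in range(n):
        cols[f"a_{j+1}"] = traj.a[j]
    for i in range(n):
        cols[f"l_{i+1}"] = traj.ce_length[i]
    for i in range(n):
        cols[f"ldot_{i+1}"] = traj.ce_velocity[i]
    for i in range(n):
        cols[f"F_{i+1}"] = traj.ce_force[i]
    cols["F_fixed"] = traj.f_fixed
    from .diagnostics import effective_mass

    cols["mu_eff"] = effective_mass(traj)
    return pd.DataFrame(cols)


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".meta.json")


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory CSV plus a ``.meta.json`` sidecar.

    The sidecar holds the resolved muscle/chain configuration, solver
    settings, and the event table — everything needed to rerun or re-read
    the trajectory.
    """
    path = Path(path)
    _trajectory_frame(traj).to_csv(path, index=False, float_format="%.17g")
    ce = traj.chain.ce
    meta = {
        "chain": {
            "n_ce": traj.chain.n_ce,
            "total_mass_kg": traj.chain.total_mass,
            "ce": dataclasses.asdict(ce),
        },
        "run": traj.meta,
        "events": traj.events,
        "peak": {"t": traj.events.get("peak_velocity"), "v": traj.v_peak,
                 "censored": traj.peak_censored},
        "work_impulse_dissipation_final": [
            float(traj.work[-1]), float(traj.impulse[-1]), float(traj.dissipation[-1])
        ],
    }
    with open(sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2)
    logger.info("wrote trajectory %s (+%s)", path, sidecar_path(path).name)
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    """Reconstruct a Trajectory from a CSV and its sidecar.

    The integrated work/impulse/dissipation series are not stored in the
    CSV; they are rebuilt by trapezoidal quadrature on the sample grid (the
    final integrated values from the sidecar are kept in ``meta``).
    """
    from scipy.integrate import cumulative_trapezoid

    from .ce import CEParameters

    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    with open(sidecar_path(path)) as fh:
        meta = json.load(fh)
    n = meta["chain"]["n_ce"]
    chain = ChainModel(
        n_ce=n,
        total_mass=meta["chain"]["total_mass_kg"],
        ce=CEParameters(**meta["chain"]["ce"]),
    )

    def block(prefix):
        return np.vstack([df[f"{prefix}_{k+1}"].to_numpy() for k in range(n)])

    t = df["t"].to_numpy()
    f = block("F")
    ldot = block("ldot")
    power = np.sum(f * ldot, axis=0)
    work = cumulative_trapezoid(-power, t, initial=0.0)
    impulse = cumulative_trapezoid(f[0], t, initial=0.0)
    diss_rate = np.sum(np.where((f < 0) & (ldot < 0), f * ldot, 0.0), axis=0)
    dissipation = cumulative_trapezoid(diss_rate, t, initial=0.0)

    peak = meta.get("peak", {})
    return Trajectory(
        chain=chain,
        t=t,
        x=block("x"),
        v=block("v"),
        a=block("a"),
        ce_length=block("l"),
        ce_velocity=ldot,
        ce_force=f,
        f_fixed=df["F_fixed"].to_numpy(),
        work=work,
        impulse=impulse,
        dissipation=dissipation,
        events=meta.get("events", {}),
        peak_censored=bool(peak.get("censored", False)),
        v_peak=float(peak.get("v", np.max(-block("v")[-1]))),
        meta=dict(meta.get("run", {})),
    )


def write_diagnostics(report, path: str | Path) -> Path:
    """Serialize a DiagnosticsReport's scalar summary to JSON."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    logger.info("wrote diagnostics %s", path)
    return path
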