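"""Muscle parameter presets.

Two designs ship with the package:

* ``small`` — an averaged assembly of a piglet's four plantar flexors:
  mass 6.5 g, F_max = 30 N, optimal length 15 mm, v_max = 0.15 m/s.
* ``big`` — the same muscle scaled geometrically by a factor of ten in
  length and ten in cross-sectional area (hundredfold mass): 650 g,
  300 N, 150 mm, v_max = 1.5 m/s.  Comparable to a human pectineus or
  the medial head of a horse triceps.

Both share the Hill parameters A_rel = 0.1, B_rel = 1.0 1/s and full
activity q = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .ce import CEParameters

__all__ = ["MusclePreset", "SMALL", "BIG", "PRESETS", "get_preset"]


@dataclass(frozen=True)
class MusclePreset:
    """Whole-muscle parameter set (SI units internally)."""

    name: str
    mass: float  # total muscle mass (kg)
    f_max: float  # maximum isometric force (N)
    l_m_opt: float  # optimal muscle length (m)
    a_rel: float = 0.1
    b_rel: float = 1.0  # 1/s
    q: float = 1.0
    dw_asc: float = 0.505
    nu_asc: float = 4.0
    dw_des: float = 0.30
    nu_des: float = 2.0

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.f_max <= 0 or self.l_m_opt <= 0:
            raise ValueError("mass, f_max and l_m_opt must be positive")

    @property
    def v_m_max0(self) -> float:
        """Theoretical maximum whole-muscle shortening speed (m/s)."""
        return self.b_rel / self.a_rel * self.l_m_opt

    def ce_parameters(self, n_ce: int) -> CEParameters:
        """CE constants for a chain of ``n_ce`` identical elements.

        Each CE receives optimal length ``l_m_opt / n_ce``; force and Hill
        parameters are shared by all elements in series.
        """
        if n_ce < 1:
            raise ValueError(f"n_ce must be >= 1, got {n_ce}")
        return CEParameters(
            f_max=self.f_max,
            l_opt=self.l_m_opt / n_ce,
            a_rel=self.a_rel,
            b_rel=self.b_rel,
            q=self.q,
            dw_asc=self.dw_asc,
            nu_asc=self.nu_asc,
            dw_des=self.dw_des,
            nu_des=self.nu_des,
        )

    def with_overrides(self, **kwargs) -> "MusclePreset":
        return replace(self, **kwargs)


SMALL = MusclePreset(name="small", mass=6.5e-3, f_max=30.0, l_m_opt=0.015)
BIG = MusclePreset(name="big", mass=0.650, f_max=300.0, l_m_opt=0.15)

PRESETS = {"small": SMALL, "big": BIG}


def get_preset(name: str) -> MusclePreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
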