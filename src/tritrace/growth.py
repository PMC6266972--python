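"""Logistic growth of wheat compartments and sap-flow schedules.

Wheat is resolved into four compartments — root, stem, leaf, grain — each
growing along a closed-form logistic trajectory

    M_i(t) = M_max / (1 + ((M_max - M_0)/M_0) * exp(-G * (t - t_e)))

where ``M_0`` is the mass at emergence, ``M_max`` the asymptotic mass, ``G``
the growth coefficient (1/d) and ``t_e`` the emergence day.  The grain
compartment does not exist at sowing; it emerges ~50 d in and its logistic
clock starts there.  Volumetric sap fluxes (xylem up, phloem down) are modelled
as proportional to compartment mass, with the phloem flux a fixed fraction of
the xylem flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WheatPart",
    "GrowthParams",
    "MassSeries",
    "logistic_mass",
    "mass_series",
    "flux_series",
    "TABLE_GROWTH_DEFAULTS",
]


class WheatPart(str, Enum):
    """The four wheat compartments, in fixed canonical order."""

    ROOT = "root"
    STEM = "stem"
    LEAF = "leaf"
    GRAIN = "grain"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical ordering used for every serialization.
PART_ORDER: tuple[WheatPart, ...] = (
    WheatPart.ROOT,
    WheatPart.STEM,
    WheatPart.LEAF,
    WheatPart.GRAIN,
)

#: Default day on which the grain compartment appears (d after sowing).
GRAIN_EMERGENCE_DAY = 50.0


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth parameters for one compartment.

    Parameters
    ----------
    part
        Compartment the parameters describe.
    m0
        Initial (emergence) mass, kg.  Must satisfy ``0 < m0 < mmax``.
    mmax
        Asymptotic mass, kg.
    g
        Growth coefficient, 1/d.
    emergence_day
        Day the compartment starts existing; mass is 0 before it.
    """

    part: WheatPart
    m0: float
    mmax: float
    g: float
    emergence_day: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.m0 < self.mmax):
            raise ValueError(
                f"{self.part}: need 0 < m0 < mmax, got m0={self.m0}, mmax={self.mmax}"
            )
        if self.g <= 0.0:
            raise ValueError(f"{self.part}: growth coefficient must be > 0, got {self.g}")
        if self.emergence_day < 0.0:
            raise ValueError(f"{self.part}: emergence_day must be >= 0")

    @property
    def inflection_day(self) -> float:
        """Day (after sowing) at which the mass reaches mmax/2."""
        return self.emergence_day + math.log((self.mmax - self.m0) / self.m0) / self.g


#: Field-typical logistic parameters per compartment (kg, kg, 1/d).
#: Grain emerges ~50 d after sowing; vegetative parts at sowing.
TABLE_GROWTH_DEFAULTS: dict[WheatPart, GrowthParams] = {
    WheatPart.ROOT: GrowthParams(WheatPart.ROOT, 0.0025, 0.25, 0.0075),
    WheatPart.STEM: GrowthParams(WheatPart.STEM, 0.00125, 0.45, 0.08),
    WheatPart.LEAF: GrowthParams(WheatPart.LEAF, 0.00125, 0.05, 0.08),
    WheatPart.GRAIN: GrowthParams(
        WheatPart.GRAIN, 0.0000056, 0.56, 0.14, emergence_day=GRAIN_EMERGENCE_DAY
    ),
}


def logistic_mass(params: GrowthParams, t: float | np.ndarray) -> float | np.ndarray:
    """Closed-form logistic mass of one compartment at time ``t`` (d).

    Returns 0 before ``params.emergence_day`` and
    ``mmax / (1 + ((mmax-m0)/m0) exp(-g (t - t_e)))`` after it.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("time must be finite")
    shape = (params.mmax - params.m0) / params.m0
    tau = t_arr - params.emergence_day
    with np.errstate(over="ignore"):
        m = params.mmax / (1.0 + shape * np.exp(-params.g * tau))
    m = np.where(tau < 0.0, 0.0, m)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(m)
    return m


@dataclass
class MassSeries:
    """Per-compartment mass and sap-flux trajectories on a shared time grid.

    Attributes
    ----------
    t
        Strictly increasing time grid, d.
    mass
        Mapping part -> mass array (kg), aligned with ``t``.
    q_up, q_down
        Mapping part -> xylem / phloem volumetric flux (L/d); zero until
        :func:`flux_series` fills them.
    params
        The growth parameters the series was built from.
    """

    t: np.ndarray
    mass: dict[WheatPart, np.ndarray]
    q_up: dict[WheatPart, np.ndarray] = field(default_factory=dict)
    q_down: dict[WheatPart, np.ndarray] = field(default_factory=dict)
    params: dict[WheatPart, GrowthParams] = field(default_factory=dict)

    @property
    def parts(self) -> tuple[WheatPart, ...]:
        return tuple(p for p in PART_ORDER if p in self.mass)

    def mass_at(self, part: WheatPart, t: float) -> float:
        """Exact (closed-form) mass of ``part`` at arbitrary time ``t``."""
        return float(logistic_mass(self.params[part], t))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: t, part, mass_kg, q_up, q_down."""
        rows = []
        for part in self.parts:
            qu = self.q_up.get(part, np.zeros_like(self.t))
            qd = self.q_down.get(part, np.zeros_like(self.t))
            rows.append(
                pd.DataFrame(
                    {
                        "t": self.t,
                        "part": part.value,
                        "mass_kg": self.mass[part],
                        "q_up": qu,
                        "q_down": qd,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def default_time_grid(t_end: float = 160.0, dt: float = 0.5) -> np.ndarray:
    """Default simulation grid: sowing to ripeness at half-day resolution."""
    n = int(round(t_end / dt))
    return np.linspace(0.0, n * dt, n + 1)


def mass_series(
    all_params: Sequence[GrowthParams] | Mapping[WheatPart, GrowthParams],
    t_grid: np.ndarray | None = None,
) -> MassSeries:
    """Evaluate logistic trajectories for several compartments on a grid."""
    if isinstance(all_params, Mapping):
        params_list = list(all_params.values())
    else:
        params_list = list(all_params)
    if not params_list:
        raise ValueError("at least one compartment is required")
    seen: set[WheatPart] = set()
    for p in params_list:
        if p.part in seen:
            raise ValueError(f"duplicate compartment {p.part}")
        seen.add(p.part)
    if t_grid is None:
        t_grid = default_time_grid()
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("empty time grid")
    if t_grid[0] != 0.0:
        raise ValueError("time grid must start at 0 (sowing)")
    if t_grid.size > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("time grid must be strictly increasing")

    mass = {p.part: np.asarray(logistic_mass(p, t_grid)) for p in params_list}
    return MassSeries(
        t=t_grid,
        mass=mass,
        q_up={p.part: np.zeros_like(t_grid) for p in params_list},
        q_down={p.part: np.zeros_like(t_grid) for p in params_list},
        params={p.part: p for p in params_list},
    )


def flux_series(
    series: MassSeries,
    q_up_coeff: Mapping[WheatPart, float] | float,
    phloem_fraction: Mapping[WheatPart, float] | float,
) -> MassSeries:
    """Fill xylem/phloem fluxes: Q_up = q*M(t), Q_down = phi*Q_up.

    ``q_up_coeff`` is a per-mass flux coefficient in L/(kg d); ``phloem_fraction``
    (phi, dimensionless) must lie in [0, 1) so phloem flux never exceeds xylem
    flux, matching the observed flux ordering.
    """

    def _get(val, part):
        return float(val[part]) if isinstance(val, Mapping) else float(val)

    for part in series.parts:
        q = _get(q_up_coeff, part)
        phi = _get(phloem_fraction, part)
        if q < 0:
            raise ValueError(f"{part}: q_up coefficient must be >= 0")
        if not (0.0 <= phi < 1.0):
            raise ValueError(f"{part}: phloem fraction must be in [0, 1), got {phi}")
        series.q_up[part] = q * series.mass[part]
        series.q_down[part] = phi * series.q_up[part]
    return series
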