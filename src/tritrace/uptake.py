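"""Elementary and composed trace-metal transfer rates.

A metal reaches a wheat compartment along two pathways:

* from soil, entering the root (transpiration plasmid flow + diffusion) and
  moving up the xylem through stem to leaf and grain;
* from the atmosphere, deposited on leaf and grain surfaces (metabolic
  permeation + particulate deposition) and re-exported downward in the phloem.

Each inter-part hop ``i -> j`` has a first-order rate ``r = Q_j / (K_iw M_j)``
built from the receiving part's sap flux, the source part's water partition
coefficient and the receiving part's mass.  Multi-hop pathways are composed
multiplicatively, the second and later stages nondimensionalised by a
reference time ``tau`` (default 1 d).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .growth import MassSeries, WheatPart

__all__ = [
    "MetalEnvironment",
    "PartGeometry",
    "AtmosphereParams",
    "RootTransportParams",
    "RateSet",
    "PreEmergenceError",
    "transfer_rate",
    "root_uptake_rate",
    "atmos_rate",
    "compose_pathway",
    "build_rate_set",
]

#: Elementary edge labels of the transfer network.
SOIL_EDGES = ("S->R", "R->St", "St->L", "St->G", "L->St", "St->R")
ATMOS_EDGES = ("A->L", "A->G")

#: Pathway chains per compartment: soil route and atmosphere route.
SOIL_CHAINS: dict[WheatPart, tuple[str, ...]] = {
    WheatPart.ROOT: ("S->R",),
    WheatPart.STEM: ("S->R", "R->St"),
    WheatPart.LEAF: ("S->R", "R->St", "St->L"),
    WheatPart.GRAIN: ("S->R", "R->St", "St->G"),
}
ATMOS_CHAINS: dict[WheatPart, tuple[str, ...]] = {
    WheatPart.ROOT: ("A->L", "L->St", "St->R"),
    WheatPart.STEM: ("A->L", "L->St"),
    WheatPart.LEAF: ("A->L",),
    WheatPart.GRAIN: ("A->G",),
}


class PreEmergenceError(ValueError):
    """A rate involving a compartment was requested before it exists."""


@dataclass(frozen=True)
class MetalEnvironment:
    """Soil and atmospheric state for one metal at one site.

    ``c_soluble`` and ``c_exchangeable`` (mg/L) are the bioavailable soil
    pools feeding root uptake; ``c_total_soil`` (mg/kg) is the total soil
    burden used for BCFs and Monte Carlo scaling; ``c_atmosphere`` is the
    airborne concentration (mg/m^3).  ``soil_mass`` (kg) is the soil in the
    rooting volume and ``k_sw`` (L/kg) the soil-water partition coefficient.
    """

    metal: str
    c_total_soil: float
    c_soluble: float
    c_exchangeable: float
    c_atmosphere: float
    soil_mass: float
    k_sw: float

    def __post_init__(self) -> None:
        for name in ("c_total_soil", "c_soluble", "c_exchangeable", "c_atmosphere"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.soil_mass <= 0:
            raise ValueError("soil_mass must be > 0")
        if self.k_sw <= 0:
            raise ValueError("k_sw must be > 0")

    @property
    def bioavailable(self) -> float:
        """Sum of water-soluble and exchangeable pools, mg/L."""
        return self.c_soluble + self.c_exchangeable

    def scaled(self, factor: float) -> "MetalEnvironment":
        """Environment with soluble/exchangeable pools scaled by ``factor``."""
        return MetalEnvironment(
            metal=self.metal,
            c_total_soil=self.c_total_soil * factor,
            c_soluble=self.c_soluble * factor,
            c_exchangeable=self.c_exchangeable * factor,
            c_atmosphere=self.c_atmosphere,
            soil_mass=self.soil_mass,
            k_sw=self.k_sw,
        )


@dataclass(frozen=True)
class PartGeometry:
    """Surface/partition properties of one compartment.

    ``area`` m^2; ``water_content`` L/kg; ``k_iw`` L/kg part-water partition
    coefficient; ``permeability`` m/d, meaningful for leaf and grain only.
    """

    part: WheatPart
    area: float
    water_content: float
    k_iw: float
    permeability: float | None = None

    def __post_init__(self) -> None:
        if self.area < 0 or self.water_content < 0:
            raise ValueError(f"{self.part}: area and water content must be >= 0")
        if self.k_iw <= 0:
            raise ValueError(f"{self.part}: k_iw must be > 0")
        if self.permeability is not None and self.part not in (
            WheatPart.LEAF,
            WheatPart.GRAIN,
        ):
            raise ValueError("permeability is defined for leaf and grain only")


@dataclass(frozen=True)
class AtmosphereParams:
    """Particulate adsorption fraction (f_p, in [0,1]) and deposition velocity (m/d)."""

    f_p: float
    v_dep: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_p <= 1.0):
            raise ValueError(f"f_p must lie in [0, 1], got {self.f_p}")
        if self.v_dep < 0:
            raise ValueError("v_dep must be >= 0")


@dataclass(frozen=True)
class RootTransportParams:
    """Root entry parameters: sap flux Q (L/d), volume conversion f_c (L/m^3),
    root diffusion rate D_R (m/d)."""

    q: float
    f_c: float
    d_r: float

    def __post_init__(self) -> None:
        if min(self.q, self.f_c, self.d_r) < 0:
            raise ValueError("root transport parameters must be >= 0")


def transfer_rate(q_j: float, k_iw: float, m_j: float) -> float:
    """First-order rate (1/d) of the hop i->j: Q_j / (K_iw * M_j).

    ``q_j`` is the sap flux into the receiving part (L/d), ``k_iw`` the source
    part's water partition coefficient (L/kg), ``m_j`` the receiving mass (kg).
    """
    if k_iw <= 0:
        raise ValueError("k_iw must be > 0")
    if q_j < 0:
        raise ValueError("q_j must be >= 0")
    if m_j <= 0:
        raise PreEmergenceError("receiving compartment has zero mass (not emerged)")
    return q_j / (k_iw * m_j)


def root_uptake_rate(
    rt: RootTransportParams, area_root: float, env: MetalEnvironment
) -> float:
    """Soil-to-root absorption rate (1/d): (Q + A_R f_c D_R) / (M_S K_SW).

    Additive in the transpiration-flow term Q and the diffusive term
    A_R * f_c * D_R.
    """
    if area_root < 0:
        raise ValueError("root area must be >= 0")
    return (rt.q + area_root * rt.f_c * rt.d_r) / (env.soil_mass * env.k_sw)


def atmos_rate(area: float, permeability: float, atm: AtmosphereParams) -> float:
    """Atmosphere-to-surface volumetric uptake rate (m^3/d).

    Metabolic permeation takes the gas-phase fraction (1 - f_p); particulate
    deposition at velocity v_dep takes the adsorbed fraction f_p:
    ``A P (1 - f_p) + A v_dep f_p``.
    """
    if area < 0 or permeability < 0:
        raise ValueError("area and permeability must be >= 0")
    return area * permeability * (1.0 - atm.f_p) + area * atm.v_dep * atm.f_p


def compose_pathway(chain: Sequence[float], tau: float = 1.0) -> float:
    """Effective rate of a serial pathway.

    The first stage keeps its native units; each later stage contributes the
    dimensionless transfer efficiency ``r * tau`` with ``tau`` a reference
    time in days.  A one-element chain is the identity.
    """
    if len(chain) == 0:
        raise ValueError("empty pathway chain")
    if any(r < 0 for r in chain):
        raise ValueError("pathway rates must be >= 0")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    eff = float(chain[0])
    for r in chain[1:]:
        eff *= r * tau
    return eff


@dataclass
class RateSet:
    """All transfer rates of the network at one instant.

    ``elementary`` maps edge labels to rates (1/d for soil and inter-part
    edges, m^3/d for the two atmosphere edges, which still need multiplying
    by the air concentration).  ``composed_soil`` / ``composed_atmos`` are the
    per-part pathway rates; ``loss`` holds k_i, the total outgoing rate per
    part (grain has no outgoing edge, so k_grain = 0).
    """

    elementary: dict[str, float]
    composed_soil: dict[WheatPart, float]
    composed_atmos: dict[WheatPart, float]
    loss: dict[WheatPart, float]
    grain_emerged: bool = True

    def __post_init__(self) -> None:
        for label, r in self.elementary.items():
            if r < 0:
                raise ValueError(f"negative rate on edge {label}")

    def edge(self, label: str) -> float:
        """Elementary rate by label; grain edges raise before emergence."""
        if not self.grain_emerged and label in ("St->G", "A->G"):
            raise PreEmergenceError(f"edge {label} queried before grain emergence")
        return self.elementary[label]


def build_rate_set(
    geom: Mapping[WheatPart, PartGeometry],
    env: MetalEnvironment,
    rt: RootTransportParams,
    atm: AtmosphereParams,
    series: MassSeries,
    t: float,
    tau: float = 1.0,
) -> RateSet:
    """Assemble every elementary, composed and loss rate at time ``t``.

    Upward (xylem) edges R->St, St->L, St->G use the receiving part's Q_up;
    downward (phloem) edges L->St, St->R use the receiving part's Q_down.
    Grain edges are 0 before grain emergence (the compartment does not exist).
    Loss rates are the sums of outgoing elementary rates:
    k_R = r(R->St); k_St = r(St->L) + r(St->G) + r(St->R); k_L = r(L->St);
    k_G = 0.
    """
    if not (series.t[0] <= t <= series.t[-1]):
        raise ValueError(f"t={t} outside the mass-series grid")

    def mass(part: WheatPart) -> float:
        return series.mass_at(part, t)

    # flux coefficient recovered from the series (Q = coeff * mass)
    def _coeff(part: WheatPart, which: dict) -> float:
        m = series.mass[part]
        q = which.get(part)
        if q is None:
            return 0.0
        pos = m > 0
        if not pos.any():
            return 0.0
        i = int(np.argmax(pos))
        return float(q[i] / m[i])

    grain_emerged = mass(WheatPart.GRAIN) > 0.0 if WheatPart.GRAIN in series.params else False

    def hop(src: WheatPart, dst: WheatPart, upward: bool) -> float:
        m_dst = mass(dst)
        if m_dst <= 0.0:
            return 0.0  # receiving compartment not emerged: edge inactive
        coeff = _coeff(dst, series.q_up if upward else series.q_down)
        return transfer_rate(coeff * m_dst, geom[src].k_iw, m_dst)

    elementary: dict[str, float] = {
        "S->R": root_uptake_rate(rt, geom[WheatPart.ROOT].area, env),
        "R->St": hop(WheatPart.ROOT, WheatPart.STEM, upward=True),
        "St->L": hop(WheatPart.STEM, WheatPart.LEAF, upward=True),
        "St->G": hop(WheatPart.STEM, WheatPart.GRAIN, upward=True)
        if grain_emerged
        else 0.0,
        "L->St": hop(WheatPart.LEAF, WheatPart.STEM, upward=False),
        "St->R": hop(WheatPart.STEM, WheatPart.ROOT, upward=False),
        "A->L": atmos_rate(
            geom[WheatPart.LEAF].area, geom[WheatPart.LEAF].permeability or 0.0, atm
        ),
        "A->G": atmos_rate(
            geom[WheatPart.GRAIN].area, geom[WheatPart.GRAIN].permeability or 0.0, atm
        )
        if grain_emerged
        else 0.0,
    }

    composed_soil = {
        part: compose_pathway([elementary[e] for e in chain], tau)
        for part, chain in SOIL_CHAINS.items()
    }
    composed_atmos = {
        part: compose_pathway([elementary[e] for e in chain], tau)
        for part, chain in ATMOS_CHAINS.items()
    }
    loss = {
        WheatPart.ROOT: elementary["R->St"],
        WheatPart.STEM: elementary["St->L"] + elementary["St->G"] + elementary["St->R"],
        WheatPart.LEAF: elementary["L->St"],
        WheatPart.GRAIN: 0.0,
    }
    return RateSet(
        elementary=elementary,
        composed_soil=composed_soil,
        composed_atmos=composed_atmos,
        loss=loss,
        grain_emerged=grain_emerged,
    )
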