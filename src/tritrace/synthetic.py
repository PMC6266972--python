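"""Synthetic survey generator: spatially correlated soils + noisy tissue data.

The generator emulates the shape of a field campaign over a contaminated
watershed: ``n_sites`` sampling points scattered uniformly over a rectangular
extent, per-metal soil totals drawn from a lognormal law with spatial
autocorrelation (a Gaussian process with exponential covariance on the logs),
bioavailable soluble/exchangeable pools as fixed fractions of the total, and
— at the subset of sites where wheat reached maturity — tissue concentrations
produced by the accumulation model itself, corrupted with multiplicative
lognormal measurement noise of a chosen CV.

Defaults mirror a 52-site survey with 32 mature wheat sites.  The generator
makes no attempt to mimic any real landscape, land-use pattern or hotspot
structure; it exists so every downstream stage (metrics, Monte Carlo,
kriging) is testable without field data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accumulation import build_schedule, _integrate, _prepare_series
from .config import ModelSetup, default_setup
from .growth import PART_ORDER
from .io import SampleTable, soil_column, tissue_column

__all__ = ["MetalFieldSpec", "SyntheticFieldSpec", "generate_soil_field",
           "model_predictions", "generate_measurements"]


@dataclass(frozen=True)
class MetalFieldSpec:
    """Lognormal field for one metal: log-mean, log-SD, correlation range (m)."""

    log_mean: float
    log_sd: float
    corr_range: float = 1000.0

    def __post_init__(self) -> None:
        if self.log_sd < 0 or self.corr_range < 0:
            raise ValueError("log_sd and corr_range must be >= 0")


def _default_metals() -> dict[str, MetalFieldSpec]:
    # log-means chosen so the field medians sit near the study area's
    # published soil means (Cu 22.1, Cd 0.6, Pb 36.3, Ni 28.9 mg/kg)
    return {
        "Cu": MetalFieldSpec(math.log(22.1), 0.4),
        "Cd": MetalFieldSpec(math.log(0.6), 0.5),
        "Pb": MetalFieldSpec(math.log(36.3), 0.4),
        "Ni": MetalFieldSpec(math.log(28.9), 0.4),
    }


@dataclass(frozen=True)
class SyntheticFieldSpec:
    """Survey design: site count, extent (m), per-metal fields, fractions,
    measurement noise CV, number of mature-wheat sites, and the seed."""

    n_sites: int = 52
    extent: tuple[float, float] = (5000.0, 5000.0)
    metals: dict[str, MetalFieldSpec] = field(default_factory=_default_metals)
    soluble_fraction: float = 0.002
    exchangeable_fraction: float = 0.010
    soil_solution_ratio: float = 1.0
    measurement_noise_cv: float = 0.3
    n_mature: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValueError("n_sites must be >= 3")
        if not (0 <= self.n_mature <= self.n_sites):
            raise ValueError("n_mature must lie in [0, n_sites]")
        if self.soluble_fraction < 0 or self.exchangeable_fraction < 0:
            raise ValueError("fractions must be >= 0")
        if self.soluble_fraction + self.exchangeable_fraction > 1:
            raise ValueError("soluble + exchangeable fractions must be <= 1")
        if self.measurement_noise_cv < 0:
            raise ValueError("measurement_noise_cv must be >= 0")


def generate_soil_field(spec: SyntheticFieldSpec) -> SampleTable:
    """Draw coordinates and spatially correlated lognormal soil pools.

    Log-concentrations follow a Gaussian process with covariance
    ``log_sd^2 exp(-d / corr_range)``; a zero range degenerates to i.i.d.
    lognormal sites.  Soluble/exchangeable pools (mg/L) are the stated
    fractions of the total converted at the soil-solution ratio.
    """
    rng = np.random.default_rng(spec.seed)
    xy = rng.uniform(0.0, 1.0, size=(spec.n_sites, 2)) * np.asarray(spec.extent)
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)

    data: dict[str, np.ndarray | list] = {
        "site_id": [f"S{i + 1:03d}" for i in range(spec.n_sites)],
        "x": xy[:, 0],
        "y": xy[:, 1],
    }
    for metal, mf in spec.metals.items():
        if mf.log_sd == 0.0:
            logs = np.full(spec.n_sites, mf.log_mean)
        elif mf.corr_range <= 0.0:
            logs = rng.normal(mf.log_mean, mf.log_sd, size=spec.n_sites)
        else:
            cov = mf.log_sd**2 * np.exp(-d / mf.corr_range)
            cov[np.diag_indices_from(cov)] += 1e-10 * mf.log_sd**2
            logs = rng.multivariate_normal(
                np.full(spec.n_sites, mf.log_mean), cov, method="cholesky"
            )
        total = np.exp(logs)
        data[soil_column(metal, "total")] = total
        ratio = spec.soil_solution_ratio
        data[soil_column(metal, "soluble")] = total * spec.soluble_fraction * ratio
        data[soil_column(metal, "exchangeable")] = total * spec.exchangeable_fraction * ratio

    mature = np.zeros(spec.n_sites, dtype=bool)
    mature[rng.choice(spec.n_sites, size=spec.n_mature, replace=False)] = True
    data["mature"] = mature
    return SampleTable(pd.DataFrame(data))


def model_predictions(
    table: SampleTable,
    setup: ModelSetup | None = None,
    metals: list[str] | None = None,
) -> pd.DataFrame:
    """Final-day tissue concentrations predicted per site (long format).

    Exploits linearity in the soil pools: per metal the ODE coefficients are
    built once and every site is integrated in one vectorised pass.
    Returns columns (site, metal, part, conc).
    """
    setup = setup or default_setup()
    metals = metals or [m for m in table.metals if m in setup.environments]
    series = _prepare_series(setup.growth, setup.sim, setup.q_up_coeff, setup.phloem_fraction)
    rows = []
    for metal in metals:
        env = setup.environments[metal]
        sched = build_schedule(
            env, setup.geometry, setup.root_transport, setup.atmosphere, series, setup.sim
        )
        s = (
            table.df[soil_column(metal, "soluble")].to_numpy(dtype=float)
            + table.df[soil_column(metal, "exchangeable")].to_numpy(dtype=float)
        )
        traj = _integrate(sched, s, env.c_atmosphere, setup.sim.dt, setup.sim.integrator)
        finals = traj[-1]
        for i, part in enumerate(PART_ORDER):
            for j, site in enumerate(table.df["site_id"]):
                rows.append(
                    {"site": site, "metal": metal, "part": part.value, "conc": finals[j, i]}
                )
    return pd.DataFrame(rows)


def generate_measurements(
    table: SampleTable,
    setup: ModelSetup | None = None,
    noise_cv: float | None = None,
    seed: int = 0,
) -> SampleTable:
    """Fill measured tissue columns at mature sites from the model + noise.

    measured = model output * exp(Normal(-s^2/2, s)) with
    s = sqrt(ln(1 + cv^2)), so the noise is mean-one multiplicative lognormal
    with the requested coefficient of variation; cv = 0 reproduces the model
    output exactly.
    """
    setup = setup or default_setup()
    if noise_cv is None:
        noise_cv = 0.3
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    preds = model_predictions(table, setup)
    df = table.df.copy()
    mature = table.mature_mask()
    sigma = math.sqrt(math.log(1.0 + noise_cv**2))

    wide = preds.pivot_table(index="site", columns=["metal", "part"], values="conc")
    site_order = df["site_id"].tolist()
    for metal, part in wide.columns:
        col = tissue_column(metal, part)
        model_vals = wide[(metal, part)].reindex(site_order).to_numpy()
        if sigma > 0:
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(site_order)))
        else:
            noise = np.ones(len(site_order))
        measured = model_vals * noise
        measured[~mature] = np.nan
        df[col] = measured
    return SampleTable(df)
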