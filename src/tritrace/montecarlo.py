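"""Monte Carlo verification: lognormal soil draws through the simulator.

Soil concentrations across a survey are well described by a lognormal law, so
the log-concentrations are fitted with a normal distribution, the fit is gated
by a Kolmogorov-Smirnov test (p > 0.05), and an ensemble of soil totals is
drawn as exp(x), x ~ Normal(mu, sigma).  Each draw is pushed through the
accumulation model — the site's soluble and exchangeable pools are scaled in
proportion to the drawn total — and the distribution of final tissue
concentrations is compared with measured samples via a density overlay.

Only the soil concentration is randomised; atmosphere and all physiological
parameters are held at their configured values.  Because the model is linear
in the soil pools, the time-varying ODE coefficients are identical for every
replicate; they are computed once and all replicates are integrated together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .accumulation import build_schedule, _integrate, _prepare_series
from .config import ModelSetup
from .growth import PART_ORDER, WheatPart
from .uptake import MetalEnvironment

__all__ = [
    "LognormalFit",
    "EnsembleResult",
    "fit_lognormal",
    "draw_soils",
    "run_ensemble",
    "density_overlay",
    "DensityOverlay",
]


@dataclass(frozen=True)
class LognormalFit:
    """Normal fit of log-concentrations, with its K-S gate.

    ``usable`` is False when the input was degenerate (sigma = 0) or the K-S
    test rejected normality of the logs at p <= 0.05.
    """

    mu: float
    sigma: float
    ks_statistic: float
    ks_p: float
    n: int

    @property
    def usable(self) -> bool:
        return self.sigma > 0.0 and self.ks_p > 0.05


def fit_lognormal(c_soil) -> LognormalFit:
    """Fit ln(concentration) ~ Normal(mu, sigma) and K-S test the logs.

    The test compares the logs against a normal with the fitted moments (no
    small-sample correction of the estimated-parameter bias is applied).
    """
    arr = np.asarray(c_soil, dtype=float).ravel()
    if arr.size < 3:
        raise ValueError("need at least 3 concentrations to fit")
    if np.any(arr <= 0.0) or not np.all(np.isfinite(arr)):
        raise ValueError("concentrations must be positive and finite")
    logs = np.log(arr)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=1))
    if sigma == 0.0:
        return LognormalFit(mu=mu, sigma=0.0, ks_statistic=np.nan, ks_p=0.0, n=arr.size)
    ks = stats.kstest(logs, "norm", args=(mu, sigma))
    return LognormalFit(
        mu=mu, sigma=sigma, ks_statistic=float(ks.statistic), ks_p=float(ks.pvalue), n=arr.size
    )


def draw_soils(fit: LognormalFit, n_rep: int, seed: int) -> np.ndarray:
    """Seeded lognormal draws exp(Normal(mu, sigma)), all positive.

    A degenerate fit (sigma = 0) yields the constant exp(mu); a fit whose
    K-S gate rejected lognormality is refused.
    """
    if fit.sigma > 0.0 and not fit.usable:
        raise ValueError(
            f"fit failed its K-S gate (p = {fit.ks_p:.3g} <= 0.05); refusing to draw"
        )
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    if fit.sigma == 0.0:
        return np.full(n_rep, np.exp(fit.mu))
    return np.exp(rng.normal(fit.mu, fit.sigma, size=n_rep))


@dataclass
class EnsembleResult:
    """Ensemble of soil draws and the tissue concentrations they produce.

    ``outputs[part]`` holds one final concentration per replicate; ``density``
    maps parts to (support, kde values) pairs, absent when n_rep < 2.
    """

    draws: np.ndarray
    outputs: dict[WheatPart, np.ndarray]
    n_rep: int
    seed: int
    metal: str
    density: dict[WheatPart, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def run_ensemble(
    fit: LognormalFit,
    setup: ModelSetup,
    metal: str,
    n_rep: int = 10_000,
    seed: int = 0,
) -> EnsembleResult:
    """Propagate ``n_rep`` lognormal soil draws through the simulator.

    For each drawn total the soluble and exchangeable pools are scaled by
    draw / C_total, preserving the configured fraction ratios, and the model
    is integrated to t_end; final concentrations per part are recorded.
    """
    draws = draw_soils(fit, n_rep, seed)
    env: MetalEnvironment = setup.environments[metal]
    if env.c_total_soil <= 0.0:
        raise ValueError("configured total soil concentration must be > 0")
    factors = draws / env.c_total_soil

    series = _prepare_series(
        setup.growth, setup.sim, setup.q_up_coeff, setup.phloem_fraction
    )
    sched = build_schedule(
        env, setup.geometry, setup.root_transport, setup.atmosphere, series, setup.sim
    )
    traj = _integrate(
        sched,
        env.bioavailable * factors,
        env.c_atmosphere,
        setup.sim.dt,
        setup.sim.integrator,
    )
    if not np.all(np.isfinite(traj)):
        bad = int(np.argwhere(~np.isfinite(traj))[0][1])
        raise RuntimeError(f"simulator diverged on replicate {bad}")
    finals = traj[-1]  # (n_rep, n_parts)
    outputs = {part: finals[:, i].copy() for i, part in enumerate(PART_ORDER)}

    density: dict[WheatPart, tuple[np.ndarray, np.ndarray]] = {}
    if n_rep >= 2:
        for part, vals in outputs.items():
            if np.std(vals) > 0:
                kde = stats.gaussian_kde(vals)  # Silverman bandwidth
                lo, hi = vals.min(), vals.max()
                pad = 0.1 * (hi - lo)
                support = np.linspace(lo - pad, hi + pad, 256)
                density[part] = (support, kde(support))
    return EnsembleResult(
        draws=draws, outputs=outputs, n_rep=n_rep, seed=seed, metal=metal, density=density
    )


@dataclass
class DensityOverlay:
    """Histogram of measured values vs KDE of the ensemble, plus overlap.

    ``overlap`` is the common area of the two probability densities in [0, 1]
    (1 = identical distributions, 0 = disjoint supports).
    """

    support: np.ndarray
    model_density: np.ndarray
    measured_density: np.ndarray
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    overlap: float


def density_overlay(model_values, measured) -> DensityOverlay:
    """Compare an ensemble output distribution with measured samples."""
    mod = np.asarray(model_values, dtype=float).ravel()
    mea = np.asarray(measured, dtype=float).ravel()
    if mod.size < 2 or mea.size < 1:
        raise ValueError("need >= 2 model values and >= 1 measured value")

    # Freedman-Diaconis histogram of the measurements
    hist_counts, hist_edges = np.histogram(mea, bins="fd" if mea.size > 1 else 1)

    lo = min(mod.min(), mea.min())
    hi = max(mod.max(), mea.max())
    pad = 0.1 * (hi - lo) if hi > lo else max(1.0, abs(hi)) * 0.1
    support = np.linspace(lo - pad, hi + pad, 512)

    def _density(vals: np.ndarray) -> np.ndarray:
        if vals.size > 1 and np.std(vals) > 0:
            return stats.gaussian_kde(vals)(support)
        # degenerate sample: narrow gaussian bump at the point mass
        width = pad / 10 or 1e-6
        return np.exp(-0.5 * ((support - vals.mean()) / width) ** 2) / (
            width * np.sqrt(2 * np.pi)
        )

    f = _density(mod)
    g = _density(mea)
    overlap = float(np.trapezoid(np.minimum(f, g), support))
    return DensityOverlay(
        support=support,
        model_density=f,
        measured_density=g,
        hist_edges=hist_edges,
        hist_counts=hist_counts,
        overlap=min(overlap, 1.0),
    )
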