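"""Ordinary kriging of tissue concentrations and prediction-error classes.

The spatial stage interpolates per-site model output over a planar grid:
an empirical semivariogram is binned from the sample pairs, a classical
model (spherical / exponential / gaussian) is fitted by weighted least
squares, and ordinary kriging — the best linear unbiased predictor whose
weights sum to one via a Lagrange multiplier — produces predictions and
kriging variances.  Site-level prediction errors |pred - meas| / meas are
classified into <25%, 25-50% and >50% bands.

Coordinates are planar metric; geographic lat/lon must be projected first
(inputs that look angular trigger a warning upstream).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "VariogramModel",
    "RiskGrid",
    "empirical_variogram",
    "fit_variogram",
    "krige",
    "kriging_weights",
    "leave_one_out",
    "error_classes",
]

ERROR_CLASS_LABELS = ("lt25", "25to50", "gt50")


def _gamma_spherical(h, nugget, psill, rng):
    hr = np.minimum(h / rng, 1.0)
    g = nugget + psill * (1.5 * hr - 0.5 * hr**3)
    return np.where(h == 0, 0.0, g)


def _gamma_exponential(h, nugget, psill, rng):
    g = nugget + psill * (1.0 - np.exp(-3.0 * h / rng))
    return np.where(h == 0, 0.0, g)


def _gamma_gaussian(h, nugget, psill, rng):
    g = nugget + psill * (1.0 - np.exp(-3.0 * (h / rng) ** 2))
    return np.where(h == 0, 0.0, g)


_MODELS = {
    "spherical": _gamma_spherical,
    "exponential": _gamma_exponential,
    "gaussian": _gamma_gaussian,
}


@dataclass(frozen=True)
class VariogramModel:
    """Fitted semivariogram: gamma(h) = nugget + partial sill * shape(h/range).

    ``range`` is the effective range (the exponential and gaussian shapes use
    the practical-range convention, reaching ~95% of the sill there).
    ``fallback`` flags a fit that did not converge and was replaced by a
    moment-based exponential.
    """

    model: Literal["spherical", "exponential", "gaussian"]
    nugget: float
    sill: float
    range_: float
    fallback: bool = False

    def __post_init__(self) -> None:
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")
        if self.sill < self.nugget:
            raise ValueError("sill must be >= nugget")
        if self.range_ <= 0:
            raise ValueError("range must be > 0")

    def gamma(self, h) -> np.ndarray:
        """Semivariance at separation(s) ``h``; gamma(0) = 0 (exact at ties)."""
        h = np.asarray(h, dtype=float)
        return _MODELS[self.model](h, self.nugget, self.sill - self.nugget, self.range_)


def _coords_values(samples, values):
    if isinstance(samples, pd.DataFrame):
        coords = samples[["x", "y"]].to_numpy(dtype=float)
    else:
        coords = np.asarray(samples, dtype=float)
    vals = np.asarray(values, dtype=float).ravel()
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coordinates must be an (n, 2) array or a frame with x, y")
    if coords.shape[0] != vals.size:
        raise ValueError("coordinates and values disagree in length")
    if not (np.all(np.isfinite(coords)) and np.all(np.isfinite(vals))):
        raise ValueError("non-finite coordinates or values")
    return coords, vals


def empirical_variogram(samples, values, n_lags: int = 12) -> pd.DataFrame:
    """Binned semivariances gamma(h) = mean(dz^2)/2 per equal-width lag bin.

    Bins span (0, half the maximum pairwise distance]; empty bins are dropped.
    Returns a frame with columns ``lag`` (bin centre), ``gamma``, ``n_pairs``.
    """
    coords, vals = _coords_values(samples, values)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 sites for an empirical variogram")
    d = pdist(coords)
    if np.all(d == 0):
        raise ValueError("all sites are co-located")
    dz2 = pdist(vals[:, None], metric="sqeuclidean")
    h_max = d.max() / 2.0
    if not np.any(d <= h_max):
        h_max = d.max()  # degenerate layouts (e.g. two sites): keep the pair
    edges = np.linspace(0.0, h_max, n_lags + 1)
    rows = []
    for i in range(n_lags):
        lo, hi = edges[i], edges[i + 1]
        mask = (d > lo) & (d <= hi) if i > 0 else (d >= lo) & (d <= hi)
        if not mask.any():
            continue
        rows.append(
            {
                "lag": 0.5 * (lo + hi),
                "gamma": 0.5 * float(np.mean(dz2[mask])),
                "n_pairs": int(mask.sum()),
            }
        )
    if not rows:
        raise ValueError("no pairs fall inside the lag range")
    return pd.DataFrame(rows)


def fit_variogram(
    emp: pd.DataFrame,
    model: Literal["spherical", "exponential", "gaussian"] = "spherical",
) -> VariogramModel:
    """Weighted least-squares fit of a variogram model to binned semivariances.

    Weights follow the usual two-stage scheme: pair counts first, then
    Cressie's n/gamma^2 weights around the first-stage model.  Range and sill
    are bounded to the data scale (range <= twice the largest lag) to keep the
    flat pure-nugget case identifiable.  On non-convergence the fit falls back
    to an exponential with moment-based parameters and is flagged.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown variogram model {model!r}")
    if len(emp) < 3:
        raise ValueError("need at least 3 non-empty lag bins")
    h = emp["lag"].to_numpy(dtype=float)
    g = emp["gamma"].to_numpy(dtype=float)
    w = emp["n_pairs"].to_numpy(dtype=float)

    gmax = max(g.max(), 1e-12)
    p0 = (min(g[0], gmax) * 0.5, gmax, max(h.max() * 0.5, 1e-9))
    bounds = ([0.0, 0.0, 1e-12], [2 * gmax, 3 * gmax, 2 * h.max()])
    func = _MODELS[model]

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                func, h, g, p0=p0, sigma=1.0 / np.sqrt(w), bounds=bounds, maxfev=20_000
            )
            gamma_hat = np.maximum(func(h, *popt), 1e-12 * gmax)
            popt, _ = curve_fit(
                func, h, g, p0=popt, sigma=gamma_hat / np.sqrt(w),
                bounds=bounds, maxfev=20_000,
            )
        nugget, psill, rng = (float(v) for v in popt)
        return VariogramModel(model=model, nugget=nugget, sill=nugget + psill, range_=rng)
    except RuntimeError:
        # moment fallback: exponential with sill at the mean top-half gamma
        sill = float(np.average(g[h >= np.median(h)], weights=w[h >= np.median(h)]))
        sill = max(sill, 1e-12)
        return VariogramModel(
            model="exponential",
            nugget=0.0,
            sill=sill,
            range_=float(np.median(h)),
            fallback=True,
        )


def _ok_matrix(coords: np.ndarray, vg: VariogramModel) -> np.ndarray:
    n = coords.shape[0]
    gamma = vg.gamma(squareform(pdist(coords)))
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = gamma
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    a[n, n] = 0.0
    return a


def kriging_weights(samples, values, vg: VariogramModel, points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the ordinary-kriging system at ``points``.

    Returns (weights, predictions, variances); ``weights`` has shape
    (n_points, n_sites) and each row sums to 1 by the unbiasedness constraint.
    """
    coords, vals = _coords_values(samples, values)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sites to krige")
    d = squareform(pdist(coords))
    dup = np.argwhere((d == 0) & ~np.eye(n, dtype=bool))
    if dup.size:
        pairs = sorted({tuple(sorted(p)) for p in dup.tolist()})
        raise ValueError(f"duplicate coordinates at site index pairs {pairs}")
    a = _ok_matrix(coords, vg)
    b = np.empty((n + 1, pts.shape[0]))
    b[:n] = vg.gamma(cdist(coords, pts))
    b[n] = 1.0
    sol = np.linalg.solve(a, b)
    lam = sol[:n].T  # (n_points, n)
    mu = sol[n]
    preds = lam @ vals
    variances = np.einsum("pn,np->p", lam, b[:n]) + mu
    return lam, preds, np.maximum(variances, 0.0)


@dataclass
class RiskGrid:
    """Kriged surface plus optional per-site validation classes."""

    x: np.ndarray
    y: np.ndarray
    prediction: np.ndarray
    variance: np.ndarray
    site_classes: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "y": self.y, "prediction": self.prediction, "variance": self.variance}
        )


def krige(samples, values, vg: VariogramModel, grid_shape: tuple[int, int] = (50, 50),
          bounds: tuple[float, float, float, float] | None = None) -> RiskGrid:
    """Ordinary-kriging surface on a regular grid over the sample extent.

    ``bounds`` is (xmin, xmax, ymin, ymax); defaults to the sample bounding
    box.  With a zero nugget the surface is exact at sample locations.
    """
    coords, vals = _coords_values(samples, values)
    if bounds is None:
        bounds = (coords[:, 0].min(), coords[:, 0].max(), coords[:, 1].min(), coords[:, 1].max())
    nx, ny = grid_shape
    gx = np.linspace(bounds[0], bounds[1], nx)
    gy = np.linspace(bounds[2], bounds[3], ny)
    xx, yy = np.meshgrid(gx, gy)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    _, preds, variances = kriging_weights(coords, vals, vg, pts)
    return RiskGrid(x=pts[:, 0], y=pts[:, 1], prediction=preds, variance=variances)


def leave_one_out(samples, values, vg: VariogramModel) -> np.ndarray:
    """Leave-one-out kriging prediction at every site."""
    coords, vals = _coords_values(samples, values)
    n = coords.shape[0]
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        _, p, _ = kriging_weights(coords[keep], vals[keep], vg, coords[i : i + 1])
        preds[i] = p[0]
    return preds


def error_classes(predicted, measured) -> tuple[dict[str, int], list[str]]:
    """Classify relative errors |pred - meas| / meas into three bands.

    Half-open bands: [0, 0.25) -> ``lt25``; [0.25, 0.5) -> ``25to50``;
    [0.5, inf) -> ``gt50``.  Returns (counts, per-site labels).
    """
    pred = np.asarray(predicted, dtype=float).ravel()
    meas = np.asarray(measured, dtype=float).ravel()
    if pred.size != meas.size or pred.size == 0:
        raise ValueError("predicted and measured must be equal-length, non-empty")
    if np.any(meas <= 0.0):
        raise ValueError("measured values must be > 0 for relative error")
    ratio = np.abs(pred - meas) / meas
    labels = np.where(ratio < 0.25, "lt25", np.where(ratio < 0.5, "25to50", "gt50"))
    counts = {lab: int(np.sum(labels == lab)) for lab in ERROR_CLASS_LABELS}
    return counts, labels.tolist()
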