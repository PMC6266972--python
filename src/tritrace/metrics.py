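"""Model-vs-measurement agreement statistics and bioconcentration factors.

Agreement is judged on two axes: magnitude, via the root mean square of the
concentrations and the value difference rate

    V_DR = |RMS_mod - RMS_mea| / RMS_mea,

and spread, via the coefficient of variation and the fluctuation difference
rate

    F_DR = |CV_mod - CV_mea| / CV_mea.

Transfer capacity is summarised by bioconcentration factors: whole-plant
BCF_sw = C_wheat / C_soil with C_wheat the sum of the four part
concentrations, and grain BCF_sg = C_grain / C_soil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import PART_ORDER, WheatPart

__all__ = [
    "rms",
    "value_difference_rate",
    "cv",
    "fluctuation_difference_rate",
    "bcf",
    "BcfReport",
    "MetricsReport",
    "grouped_metrics",
]


def _clean(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in input")
    return arr


def rms(x) -> float:
    """Root mean square, sqrt(mean(x^2))."""
    arr = _clean(x)
    return float(np.sqrt(np.mean(arr**2)))


def value_difference_rate(x_mod, x_mea) -> float:
    """Relative RMS discrepancy |RMS_mod - RMS_mea| / RMS_mea."""
    r_mea = rms(x_mea)
    if r_mea == 0.0:
        raise ValueError("measured RMS is zero; V_DR undefined")
    return abs(rms(x_mod) - r_mea) / r_mea


def cv(x, ddof: int = 1) -> float:
    """Coefficient of variation STD/mean (sample SD by default)."""
    arr = _clean(x)
    mean = float(np.mean(arr))
    if mean == 0.0:
        raise ValueError("zero mean; CV undefined")
    if arr.size == 1:
        return 0.0
    return float(np.std(arr, ddof=ddof) / mean)


def fluctuation_difference_rate(x_mod, x_mea, ddof: int = 1) -> float:
    """Relative CV discrepancy |CV_mod - CV_mea| / CV_mea."""
    cv_mea = cv(x_mea, ddof=ddof)
    if cv_mea == 0.0:
        raise ValueError("measured CV is zero; F_DR undefined")
    return abs(cv(x_mod, ddof=ddof) - cv_mea) / cv_mea


@dataclass(frozen=True)
class BcfReport:
    """Bioconcentration factors for one metal."""

    metal: str
    bcf_sw: float
    bcf_sg: float
    c_soil: float


def bcf(parts: dict[WheatPart, float] | list[float], c_soil: float) -> tuple[float, float]:
    """Whole-plant and grain bioconcentration factors.

    ``parts`` holds tissue concentrations (mg/kg) for root, stem, leaf, grain;
    whole-plant uptake is the sum of the four parts.  ``c_soil`` is the total
    soil concentration (mg/kg).
    """
    if c_soil <= 0.0:
        raise ValueError("c_soil must be > 0")
    if isinstance(parts, dict):
        vals = [float(parts[p]) for p in PART_ORDER]
    else:
        vals = [float(v) for v in parts]
        if len(vals) != 4:
            raise ValueError("expected four part concentrations (root, stem, leaf, grain)")
    if any(v < 0 for v in vals):
        raise ValueError("tissue concentrations must be >= 0")
    bcf_sw = sum(vals) / c_soil
    bcf_sg = vals[3] / c_soil
    return bcf_sw, bcf_sg


@dataclass
class MetricsReport:
    """Agreement statistics grouped by metal and part.

    ``per_group`` carries one row per (metal, part) with RMS/CV of modelled
    and measured values plus V_DR and F_DR; ``per_metal`` averages the rates
    over parts within each metal; ``v_dr`` / ``f_dr`` average those per-metal
    means (equal weight per metal).
    """

    per_group: pd.DataFrame
    per_metal: pd.DataFrame
    v_dr: float
    f_dr: float


def grouped_metrics(
    modeled: pd.DataFrame,
    measured: pd.DataFrame,
    value_col: str = "conc",
    ddof: int = 1,
) -> MetricsReport:
    """Agreement report over site tables keyed by (site, metal, part).

    Both frames need columns ``site``, ``metal``, ``part`` and ``value_col``;
    only (site, metal, part) keys present in both are compared.
    """
    key = ["site", "metal", "part"]
    for name, df in (("modeled", modeled), ("measured", measured)):
        missing = set(key + [value_col]) - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing columns {sorted(missing)}")
    merged = modeled.merge(measured, on=key, suffixes=("_mod", "_mea"))
    if merged.empty:
        raise ValueError("no overlapping (site, metal, part) keys")

    rows = []
    for (metal, part), grp in merged.groupby(["metal", "part"], sort=True):
        xm = grp[f"{value_col}_mod"].to_numpy()
        xa = grp[f"{value_col}_mea"].to_numpy()
        rec = {
            "metal": metal,
            "part": part,
            "n": len(grp),
            "rms_mod": rms(xm),
            "rms_mea": rms(xa),
            "v_dr": value_difference_rate(xm, xa),
        }
        if len(grp) >= 2:
            rec["cv_mod"] = cv(xm, ddof=ddof)
            rec["cv_mea"] = cv(xa, ddof=ddof)
            rec["f_dr"] = fluctuation_difference_rate(xm, xa, ddof=ddof)
        else:
            rec["cv_mod"] = rec["cv_mea"] = rec["f_dr"] = np.nan
        rows.append(rec)
    per_group = pd.DataFrame(rows)
    per_metal = (
        per_group.groupby("metal", sort=True)[["v_dr", "f_dr"]].mean().reset_index()
    )
    return MetricsReport(
        per_group=per_group,
        per_metal=per_metal,
        v_dr=float(per_metal["v_dr"].mean()),
        f_dr=float(per_metal["f_dr"].mean()),
    )
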