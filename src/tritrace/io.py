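"""Site sample tables, CSV interchange, and run manifests.

A :class:`SampleTable` holds one row per sampling site: planar coordinates,
per-metal soil concentrations (total mg/kg plus soluble/exchangeable mg/L)
and, for sites where wheat was mature, measured tissue concentrations per
part.  CSV is the single interchange format; round-trips are lossless at 12
significant digits.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .growth import PART_ORDER

__all__ = ["SampleTable", "read_samples", "write_samples", "write_manifest"]

_REQUIRED = ("site_id", "x", "y")


def soil_column(metal: str, fraction: str) -> str:
    """Column name for a soil pool: fraction in {total, soluble, exchangeable}."""
    return f"{metal}_{fraction}"


def tissue_column(metal: str, part) -> str:
    """Column name for a measured tissue concentration."""
    part = getattr(part, "value", part)
    return f"{metal}_{part}_measured"


@dataclass
class SampleTable:
    """Validated site table; ``df`` is the underlying frame."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = set(_REQUIRED) - set(df.columns)
        if missing:
            raise ValueError(f"sample table missing columns {sorted(missing)}")
        if len(df) < 1:
            raise ValueError("sample table must contain at least one site")
        if df["site_id"].duplicated().any():
            dups = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
            raise ValueError(f"duplicate site_id values: {dups}")
        coords = df[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        if np.all(np.abs(coords[:, 0]) <= 180) and np.all(np.abs(coords[:, 1]) <= 90):
            warnings.warn(
                "coordinates look like unprojected lon/lat degrees; "
                "kriging assumes planar metric coordinates",
                stacklevel=2,
            )
        for col in df.columns:
            if col in _REQUIRED or col == "mature":
                continue
            vals = pd.to_numeric(df[col], errors="coerce")
            is_soil = not col.endswith("_measured")
            neg = vals < 0
            if neg.any():
                row = int(np.argmax(neg.to_numpy()))
                raise ValueError(
                    f"negative concentration in column {col!r}, row {row} "
                    f"(site {df.iloc[row]['site_id']!r})"
                )
            if is_soil and vals.isna().any():
                row = int(np.argmax(vals.isna().to_numpy()))
                raise ValueError(
                    f"missing soil value in column {col!r}, row {row}; "
                    "only tissue measurements may be absent"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def coords(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    @property
    def metals(self) -> list[str]:
        return sorted({c.split("_")[0] for c in self.df.columns if c.endswith("_total")})

    def mature_mask(self) -> np.ndarray:
        if "mature" in self.df.columns:
            return self.df["mature"].astype(bool).to_numpy()
        return np.ones(len(self.df), dtype=bool)

    def tissue_long(self) -> pd.DataFrame:
        """Measured tissue concentrations as long format (site, metal, part, conc)."""
        rows = []
        for metal in self.metals:
            for part in PART_ORDER:
                col = tissue_column(metal, part)
                if col not in self.df.columns:
                    continue
                sub = self.df[["site_id", col]].dropna()
                for _, r in sub.iterrows():
                    rows.append(
                        {
                            "site": r["site_id"],
                            "metal": metal,
                            "part": part.value,
                            "conc": float(r[col]),
                        }
                    )
        return pd.DataFrame(rows)


def read_samples(path: str) -> SampleTable:
    """Read and validate a site CSV."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty sample file") from exc
    return SampleTable(df)


def write_samples(table: SampleTable, path: str) -> None:
    """Write a site table; numeric precision 12 significant digits."""
    table.df.to_csv(path, index=False, float_format="%.12g")


def write_manifest(
    path: str,
    *,
    command: str,
    seed: int | None,
    config_hash: str,
    assumptions: Iterable[str] = (),
    extra: dict | None = None,
) -> None:
    """Machine-readable run manifest enabling exact replay."""
    manifest = {
        "command": command,
        "seed": seed,
        "config_hash": config_hash,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "assumptions": list(assumptions),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
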