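"""Occurrence-climate cleaning and per-species summaries.

Occurrence tables carry one row per georeferenced record with the 19
bioclim values (CHELSA-style units: temperatures in 0.1 degC,
precipitation in mm) already extracted.  Cleaning removes exact
duplicate (species, lon, lat) rows and (0, 0) coordinates; summaries are
the per-species mean and the 5%/95% linear-interpolation quantiles of
each variable — one value per species for the phylogenetic correlation
tests, bracketing the intraspecific range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import BIOCLIM_COLUMNS

__all__ = ["clean_occurrences", "summarize_climate", "CleaningReport"]

SUMMARIES = ("mean", "q05", "q95")


@dataclass
class CleaningReport:
    n_in: int
    n_out: int
    removed_duplicate: int
    removed_zero_coord: int
    bad_rows: list[int]

    def as_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_out": self.n_out,
            "duplicate": self.removed_duplicate,
            "zero_coord": self.removed_zero_coord,
            "unparseable": len(self.bad_rows),
        }


def _check_columns(df: pd.DataFrame, column_map: dict | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns=column_map)
    required = ["species", "longitude", "latitude"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    return df


def clean_occurrences(
    raw: pd.DataFrame, column_map: dict | None = None
) -> tuple[pd.DataFrame, CleaningReport]:
    """Remove (0, 0) coordinates and exact duplicate (species, lon, lat)
    rows; rows with unparseable or out-of-range coordinates are dropped
    and reported by index.  Idempotent: cleaning twice equals cleaning
    once."""
    df = _check_columns(raw.copy(), column_map)
    n_in = len(df)
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    in_range = (lon >= -180) & (lon <= 180) & (lat >= -90) & (lat <= 90)
    bad = df.index[lon.isna() | lat.isna() | ~in_range].tolist()
    df = df.drop(index=bad)
    df["longitude"] = lon.loc[df.index]
    df["latitude"] = lat.loc[df.index]
    zero = (df["longitude"] == 0.0) & (df["latitude"] == 0.0)
    n_zero = int(zero.sum())
    df = df[~zero]
    dup = df.duplicated(subset=["species", "longitude", "latitude"], keep="first")
    n_dup = int(dup.sum())
    df = df[~dup].reset_index(drop=True)
    report = CleaningReport(
        n_in=n_in,
        n_out=len(df),
        removed_duplicate=n_dup,
        removed_zero_coord=n_zero,
        bad_rows=bad,
    )
    return df, report


def summarize_climate(
    occ: pd.DataFrame, variables: list[str] | None = None
) -> pd.DataFrame:
    """Per-species mean, 5% and 95% quantiles of each bioclim variable.

    Quantiles use linear interpolation between order statistics (numpy's
    default, the common 'type 7').  Species with a single occurrence get
    mean = q05 = q95 with a low-sample-size warning.  Returns a species-
    indexed DataFrame with a (variable, summary) column MultiIndex.
    """
    if variables is None:
        variables = [c for c in BIOCLIM_COLUMNS if c in occ.columns]
    if not variables:
        raise ValueError("no bioclim columns found")
    if "species" not in occ.columns:
        raise ValueError("missing 'species' column")
    counts = occ.groupby("species").size()
    singles = counts[counts == 1]
    if len(singles):
        warnings.warn(
            f"{len(singles)} species with a single occurrence; their "
            "quantiles equal the single value",
            UserWarning,
            stacklevel=2,
        )
    g = occ.groupby("species")[variables]
    parts = {
        "mean": g.mean(),
        "q05": g.quantile(0.05),
        "q95": g.quantile(0.95),
    }
    out = pd.concat(parts, axis=1)  # (summary, variable)
    out = out.swaplevel(axis=1).sort_index(axis=1)  # (variable, summary)
    out.index.name = "species"
    return out
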