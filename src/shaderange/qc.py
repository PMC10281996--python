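"""Occurrence cleaning cascade: flag, never drop.

The cascade mirrors standard SDM occurrence hygiene: (i) invalid or
incomplete coordinates, (ii) points off the analysis grid or in the ocean,
(iii) records predating the climate baseline (1969), (iv) records in
climatically marginal positions (outer tails of the species' own climate
distribution, e.g. botanical-garden plantings), (v) fossil/unknown-source
records; then spatial thinning to one record per species per grid cell, and
finally a strict minimum-sample filter (n > 60) on what survives.

Every filter only *adds* boolean flag columns; row count is conserved, so a
full audit of what was removed and why is always reconstructible. A record
is retained iff no flag is set. Re-running the cascade on its own output is
a no-op.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grids import EnvStack, GridSpec

FLAG_COLUMNS = [
    "flag_bad_coord",
    "flag_off_land",
    "flag_pre_baseline",
    "flag_marginal_climate",
    "flag_unknown_source",
    "flag_thinned",
]

DEFAULT_SOURCE_BLACKLIST = frozenset({"fossil", "unknown"})

BASELINE_YEAR = 1969
MIN_SAMPLE = 60
TAIL_FRACTION = 0.10
MIN_RECORDS_FOR_MARGINAL = 20


def ensure_flags(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with all flag columns present (False where absent)."""
    out = table.copy()
    for col in FLAG_COLUMNS:
        if col not in out.columns:
            out[col] = False
    return out


def retained_mask(table: pd.DataFrame) -> pd.Series:
    """True for rows with no QC flag set."""
    flags = [c for c in FLAG_COLUMNS if c in table.columns]
    if not flags:
        return pd.Series(True, index=table.index)
    return ~table[flags].any(axis=1)


def qc_flags(table: pd.DataFrame) -> pd.Series:
    """Per-row set of flag names (audit convenience)."""
    flags = [c for c in FLAG_COLUMNS if c in table.columns]
    return table.apply(
        lambda r: frozenset(c.removeprefix("flag_") for c in flags if r[c]), axis=1
    )


def filter_coordinates(table: pd.DataFrame) -> pd.DataFrame:
    """Flag rows with missing, non-finite or out-of-range lon/lat."""
    if len(table) == 0:
        raise ValueError("empty occurrence table")
    out = ensure_flags(table)
    lon = pd.to_numeric(out["lon"], errors="coerce")
    lat = pd.to_numeric(out["lat"], errors="coerce")
    bad = (
        ~np.isfinite(lon)
        | ~np.isfinite(lat)
        | (lon < -180) | (lon > 180)
        | (lat < -90) | (lat > 90)
    )
    out.loc[bad, "flag_bad_coord"] = True
    return out


def filter_land(table: pd.DataFrame, env: EnvStack) -> pd.DataFrame:
    """Flag rows falling on nodata (ocean) cells or outside the study grid.

    The study grid defines the analysis universe, so off-extent records are
    treated the same as ocean records.
    """
    out = ensure_flags(table)
    candidates = ~out["flag_bad_coord"]
    if candidates.any():
        idx = out.index[candidates]
        row, col = env.grid.cell_of(out.loc[idx, "lon"].to_numpy(float),
                                    out.loc[idx, "lat"].to_numpy(float))
        off = row < 0
        on_grid = ~off
        off[on_grid] = env.nodata_mask[row[on_grid], col[on_grid]]
        out.loc[idx[off], "flag_off_land"] = True
    return out


def filter_year(table: pd.DataFrame, baseline_year: int = BASELINE_YEAR,
                flag_missing: bool = True) -> pd.DataFrame:
    """Flag records collected before the climate baseline year.

    "Before 1969" excludes only strictly earlier years: 1968 is flagged,
    1969 is retained. Records with no collection year are flagged by default
    (conservative: an undated record cannot be placed in the baseline).
    """
    out = ensure_flags(table)
    year = pd.to_numeric(out["year"], errors="coerce")
    old = year < baseline_year
    if flag_missing:
        old = old | year.isna()
    out.loc[old, "flag_pre_baseline"] = True
    return out


def filter_source(table: pd.DataFrame,
                  blacklist: frozenset[str] | set[str] = DEFAULT_SOURCE_BLACKLIST
                  ) -> pd.DataFrame:
    """Flag fossil records and records of unknown provenance by source label."""
    out = ensure_flags(table)
    if "source" not in out.columns:
        return out
    src = out["source"].astype(str).str.lower()
    out.loc[src.isin({s.lower() for s in blacklist}), "flag_unknown_source"] = True
    return out


def filter_marginal_climate(table: pd.DataFrame, env: EnvStack,
                            climatic_layers: list[str] | None = None,
                            tail_fraction: float = TAIL_FRACTION,
                            min_records: int = MIN_RECORDS_FOR_MARGINAL
                            ) -> pd.DataFrame:
    """Flag records in the outer tails of the species' climate distribution.

    Per species and per climatic layer, a record is flagged when its
    extracted value lies strictly outside the empirical
    [tail/2, 1 - tail/2] quantile band for that species on ANY layer.
    Species with fewer than ``min_records`` eligible records are skipped
    with a warning (the empirical distribution is too unstable).

    The species' climate distribution is taken over all records passing the
    *earlier* cascade stages (coordinates, land, baseline year) — not over
    records this filter or later stages may already have flagged — so
    re-running the cascade on its own output reproduces the same quantile
    band and changes nothing.
    """
    if not (0.0 <= tail_fraction < 1.0):
        raise ValueError("tail_fraction must be in [0, 1)")
    if climatic_layers is None:
        climatic_layers = env.layers_of_class("climatic")
    missing = [l for l in climatic_layers if l not in env.layers]
    if missing:
        raise KeyError(f"climatic layers absent from stack: {missing}")
    out = ensure_flags(table)
    if tail_fraction == 0.0:
        return out
    usable = ~(out["flag_bad_coord"] | out["flag_off_land"] | out["flag_pre_baseline"])
    for species, grp in out[usable].groupby("species"):
        if len(grp) < min_records:
            warnings.warn(
                f"species {species!r}: only {len(grp)} retained records, "
                "skipping marginal-climate filter", stacklevel=2)
            continue
        vals = env.extract(grp["lon"].to_numpy(float), grp["lat"].to_numpy(float),
                           climatic_layers)
        flagged = np.zeros(len(grp), dtype=bool)
        for layer in climatic_layers:
            v = vals[layer].to_numpy()
            lo = np.nanquantile(v, tail_fraction / 2.0)
            hi = np.nanquantile(v, 1.0 - tail_fraction / 2.0)
            flagged |= (v < lo) | (v > hi)
        out.loc[grp.index[flagged], "flag_marginal_climate"] = True
    return out


def thin_to_grid(table: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Keep one retained record per species per grid cell; flag the rest.

    Tie-break: most recent year first, then lowest input index — deterministic
    and audit-friendly. Idempotent: re-thinning changes nothing.
    """
    out = ensure_flags(table)
    usable = retained_mask(out)
    if not usable.any():
        return out
    sub = out[usable]
    row, col = grid.cell_of(sub["lon"].to_numpy(float), sub["lat"].to_numpy(float))
    key = pd.DataFrame({
        "species": sub["species"].to_numpy(),
        "row": row, "col": col,
        "year": pd.to_numeric(sub["year"], errors="coerce").fillna(-np.inf).to_numpy(),
        "idx": sub.index.to_numpy(),
    })
    # within each (species, cell): keep max year, then min index
    key = key.sort_values(["species", "row", "col", "year", "idx"],
                          ascending=[True, True, True, False, True],
                          kind="stable")
    dup = key.duplicated(subset=["species", "row", "col"], keep="first")
    out.loc[key.loc[dup.to_numpy(), "idx"].to_numpy(), "flag_thinned"] = True
    return out


def apply_min_sample(table: pd.DataFrame, min_n: int = MIN_SAMPLE) -> set[str]:
    """Species with strictly more than ``min_n`` retained records."""
    if len(table) == 0:
        return set()
    counts = table[retained_mask(table)].groupby("species").size()
    return set(counts[counts > min_n].index)


def qc_report(table: pd.DataFrame) -> pd.DataFrame:
    """Per-species counts of rows caught by each filter, plus retained."""
    flags = [c for c in FLAG_COLUMNS if c in table.columns]
    rep = table.groupby("species")[flags].sum().astype(int)
    rep["n_input"] = table.groupby("species").size()
    rep["n_retained"] = table[retained_mask(table)].groupby("species").size()
    rep["n_retained"] = rep["n_retained"].fillna(0).astype(int)
    return rep.reset_index()


def run_qc(table: pd.DataFrame, env: EnvStack, grid: GridSpec | None = None,
           baseline_year: int = BASELINE_YEAR,
           tail_fraction: float = TAIL_FRACTION,
           source_blacklist: frozenset[str] | set[str] = DEFAULT_SOURCE_BLACKLIST,
           min_n: int = MIN_SAMPLE) -> tuple[pd.DataFrame, set[str], pd.DataFrame]:
    """Run the full cascade in order; returns (flagged table, kept species,
    per-species report)."""
    grid = grid or env.grid
    out = filter_coordinates(table)
    out = filter_land(out, env)
    out = filter_year(out, baseline_year=baseline_year)
    out = filter_marginal_climate(out, env, tail_fraction=tail_fraction)
    out = filter_source(out, blacklist=source_blacklist)
    out = thin_to_grid(out, grid)
    kept = apply_min_sample(out, min_n=min_n)
    return out, kept, qc_report(out)
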