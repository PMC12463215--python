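"""Biodiversity surfaces from simulation records.

α richness, per-cell speciation and extinction rates, net
diversification (speciation − extinction) and turnover
((speciation + extinction)/richness), as grids, latitudinal profiles
(cos(lat)-weighted band means, land cells only) and ensemble averages.

Event attribution: an origination contributes weight 1/n_cells to every
cell of the founding cluster; an extinction likewise to the species'
last occupied cells — global event counts are conserved by the spatial
maps. Normalization (÷ series maximum) is always applied after any
ensemble averaging, never before.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .ecoevo.simulation import SimulationRecord

METRICS = ("richness", "speciation", "extinction", "net", "turnover")


@dataclass
class DiversitySummary:
    """Per-step grids for each biodiversity metric, plus the land mask
    stack and grid geometry needed for profiles."""

    grid: "object"
    ages: np.ndarray
    fields: dict[str, np.ndarray]  # name -> (n_steps, nlat, nlon)
    land: np.ndarray  # (n_steps, nlat, nlon) bool
    spinup_steps: int = 0


def event_grids(record: SimulationRecord) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell per-step origination and extinction weights."""
    nlat, nlon = record.grid.shape
    spec = np.zeros((record.n_steps, nlat * nlon))
    ext = np.zeros_like(spec)
    for e in record.events:
        if not e.cells:
            continue
        w = 1.0 / len(e.cells)
        target = spec if e.kind == "origination" else ext
        for c in e.cells:
            target[e.step, c] += w
    return spec.reshape(-1, nlat, nlon), ext.reshape(-1, nlat, nlon)


def rates(record: SimulationRecord, land: np.ndarray | None = None) -> DiversitySummary:
    """Richness, speciation, extinction, net and turnover grids.

    Turnover is NaN (masked) where richness is 0, not 0. Raises if the
    event ledger and the richness bookkeeping disagree.
    """
    record.check_bookkeeping()
    spec, ext = event_grids(record)
    rich = record.richness.astype(float)
    net = spec - ext
    with np.errstate(invalid="ignore", divide="ignore"):
        turnover = np.where(rich > 0, (spec + ext) / np.where(rich > 0, rich, 1), np.nan)
    if land is None:
        land = np.ones(rich.shape, dtype=bool)
    return DiversitySummary(
        grid=record.grid,
        ages=record.ages,
        fields={
            "richness": rich,
            "speciation": spec,
            "extinction": ext,
            "net": net,
            "turnover": turnover,
        },
        land=np.asarray(land, dtype=bool),
        spinup_steps=record.spinup_steps,
    )


def latitudinal_profile(
    summary: DiversitySummary,
    metric: str,
    exclude_spinup: bool = True,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-latitude-band, per-time cos(lat)-weighted mean over land cells.

    Bands aggregate cell centers (one band per distinct center latitude).
    Optionally normalized by the profile's maximum over all bands and
    times; with `exclude_spinup` the record's spin-up steps are dropped
    first. Bands with no land are NaN.

    Returns a DataFrame indexed by age (Ma) with one column per band
    latitude (north to south).
    """
    vals = summary.fields[metric]
    land = summary.land
    ages = summary.ages
    start = summary.spinup_steps if exclude_spinup else 0
    start = min(start, vals.shape[0] - 1)
    vals, land, ages = vals[start:], land[start:], ages[start:]
    lats = summary.grid.lat
    w = np.cos(np.deg2rad(summary.grid.lat_grid()))
    prof = np.full((vals.shape[0], lats.size), np.nan)
    for i in range(lats.size):
        band_land = land[:, i, :]
        band_vals = vals[:, i, :]
        band_w = np.broadcast_to(w[i, :], band_vals.shape)
        ok = band_land & np.isfinite(band_vals)
        wsum = np.where(ok, band_w, 0.0).sum(axis=1)
        vsum = np.where(ok, band_w * np.nan_to_num(band_vals), 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            prof[:, i] = np.where(wsum > 0, vsum / wsum, np.nan)
    if normalize:
        m = np.nanmax(np.abs(prof)) if np.isfinite(prof).any() else np.nan
        if m and np.isfinite(m) and m > 0:
            prof = prof / m
    return pd.DataFrame(prof, index=pd.Index(ages, name="age"), columns=lats)


def ensemble_average(summaries: list[DiversitySummary]) -> DiversitySummary:
    """Arithmetic mean of each metric across an ensemble (equal weights),
    taken before any normalization. All members must share grid/times."""
    if not summaries:
        raise ValueError("empty ensemble")
    ref = summaries[0]
    for s in summaries[1:]:
        if s.fields["richness"].shape != ref.fields["richness"].shape or not np.array_equal(
            s.ages, ref.ages
        ):
            raise ValueError("ensemble members must share grid and time axes")
    fields = {}
    for name in ref.fields:
        stack = np.stack([s.fields[name] for s in summaries])
        cnt = np.isfinite(stack).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            fields[name] = np.where(cnt > 0, np.nansum(stack, axis=0) / cnt, np.nan)
    land = np.stack([s.land for s in summaries]).any(axis=0)
    return DiversitySummary(
        grid=ref.grid, ages=ref.ages, fields=fields, land=land,
        spinup_steps=ref.spinup_steps,
    )


def spearman_compare(
    model: np.ndarray,
    empirical: np.ndarray,
    lat_grid: np.ndarray,
    valid: np.ndarray | None = None,
    lat_range: tuple[float, float] = (-54.0, 71.0),
) -> float:
    """Spearman rank correlation between a modeled and an empirical
    richness grid over shared valid cells within the latitude range."""
    model = np.asarray(model, dtype=float)
    empirical = np.asarray(empirical, dtype=float)
    if valid is None:
        valid = np.ones(model.shape, dtype=bool)
    ok = (
        np.asarray(valid, dtype=bool)
        & np.isfinite(model)
        & np.isfinite(empirical)
        & (lat_grid >= lat_range[0])
        & (lat_grid <= lat_range[1])
    )
    if ok.sum() < 10:
        raise ValueError("fewer than 10 shared valid cells")
    rho, _ = spearmanr(model[ok], empirical[ok])
    return float(rho)


def summary_table(summary: DiversitySummary, exclude_spinup: bool = True) -> pd.DataFrame:
    """Long-format (time, lat, metric, value) table of all profiles."""
    frames = []
    for metric in METRICS:
        prof = latitudinal_profile(summary, metric, exclude_spinup=exclude_spinup)
        long = prof.reset_index().melt(id_vars="age", var_name="lat",
                                       value_name="value")
        long["metric"] = metric
        frames.append(long)
    return pd.concat(frames, ignore_index=True)[["age", "lat", "metric", "value"]]
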