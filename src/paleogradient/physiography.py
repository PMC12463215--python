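"""Terrain morphometrics and the physiographic diversity index.

From an elevation/discharge slice this module derives:

* TPI — topographic position index: local elevation minus the mean
  elevation over an annular neighbourhood (positive on ridges, negative
  in valleys), computed at a fine and a coarse scale band and
  standardized (x100, grid mean/sd) so the two scales are comparable;
* slope — arctan of the maximum absolute elevation gradient towards the
  8-neighbourhood, in degrees;
* hierarchical categories — 10 decile classes for standardized TPI,
  10 threshold classes for slope, 5 log-spaced classes for water
  discharge (the hydrological categories H);
* Φ — physiographic diversity: per-cell Shannon equitability of the
  three categorical layers over a moving window, averaged across the
  layers, bounded in [0, 1].

Sea cells never contribute observations; neighbourhoods are clipped at
coastlines and at the poles, and wrap in longitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import EARTH_RADIUS_KM, GridSpec, NEIGHBOR_OFFSETS, shift

#: Slope category lower bounds, degrees (category k+1 applies from bound k).
SLOPE_BOUNDS = np.array([0.03, 0.11, 0.3, 0.5, 0.85, 1.65, 2.4, 3.5, 4.5])
#: Water-discharge category bounds, log10 m^3/yr.
FLUX_BOUNDS = np.array([7.0, 8.0, 9.0, 10.0])

N_TPI_CATEGORIES = 10
N_SLOPE_CATEGORIES = 10
N_FLUX_CATEGORIES = 5


@dataclass(frozen=True)
class ScaleBand:
    """Annular neighbourhood: cells at Chebyshev radius r with
    inner < r <= outer (grid-cell units)."""

    inner: int
    outer: int

    def __post_init__(self) -> None:
        if not 0 <= self.inner < self.outer:
            raise ValueError("require 0 <= inner < outer")

    def offsets(self) -> list[tuple[int, int]]:
        out = []
        for dr in range(-self.outer, self.outer + 1):
            for dc in range(-self.outer, self.outer + 1):
                r = max(abs(dr), abs(dc))
                if self.inner < r <= self.outer:
                    out.append((dr, dc))
        return out


#: Fine and coarse bands at the working resolution (ring of radius 1;
#: rings of radii 2-3).
FINE_BAND = ScaleBand(0, 1)
COARSE_BAND = ScaleBand(1, 3)


@dataclass
class PhysiographyLayers:
    """Per-slice derived layers. Arrays are (nlat, nlon); non-land cells
    hold NaN (float layers) or 0 (category layers)."""

    tpi_fine: np.ndarray
    tpi_coarse: np.ndarray
    tpi_s: np.ndarray  # mean of the two standardized TPI maps
    slope: np.ndarray
    tpi_cat: np.ndarray
    slope_cat: np.ndarray
    flux_cat: np.ndarray
    hydro: np.ndarray  # H, same classes as flux_cat
    phi: np.ndarray
    degenerate_tpi: bool = False


def compute_tpi(elevation: np.ndarray, band: ScaleBand,
                land: np.ndarray | None = None) -> np.ndarray:
    """TPI_i = z_i - mean(z_k over the annulus); sea neighbours excluded.

    Cells with zero valid neighbours (and sea cells) are NaN.
    """
    elevation = np.asarray(elevation, dtype=float)
    if land is None:
        land = np.isfinite(elevation)
    z = np.where(land, elevation, np.nan)
    acc = np.zeros(z.shape)
    cnt = np.zeros(z.shape)
    for dr, dc in band.offsets():
        nb = shift(z, dr, dc, fill=np.nan)
        ok = np.isfinite(nb)
        acc[ok] += nb[ok]
        cnt += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        tpi = z - acc / cnt
    tpi[~land | (cnt == 0)] = np.nan
    return tpi


def standardize_tpi(tpi: np.ndarray) -> tuple[np.ndarray, bool]:
    """TPI_S = 100 * (TPI - mean) / sd over the valid (land) cells.

    Returns (grid, degenerate). A flat field (sd == 0) yields all zeros
    with degenerate=True.
    """
    tpi = np.asarray(tpi, dtype=float)
    valid = np.isfinite(tpi)
    if valid.sum() < 2:
        raise ValueError("standardize_tpi needs at least 2 valid cells")
    mu = tpi[valid].mean()
    sd = tpi[valid].std()
    out = np.full(tpi.shape, np.nan)
    if sd == 0:
        out[valid] = 0.0
        return out, True
    out[valid] = 100.0 * (tpi[valid] - mu) / sd
    return out, False


def compute_slope(elevation: np.ndarray, grid: GridSpec,
                  land: np.ndarray | None = None) -> np.ndarray:
    """Maximum absolute gradient to the 8-neighbourhood, arctan degrees.

    Cell spans come from the grid geometry (dx shrinks with cos lat).
    Isolated land cells get slope 0; sea cells NaN. Invariant to adding
    a constant to all elevations.
    """
    elevation = np.asarray(elevation, dtype=float)
    if land is None:
        land = np.isfinite(elevation)
    z = np.where(land, elevation, np.nan)
    dy = EARTH_RADIUS_KM * 1e3 * np.deg2rad(grid.lat_res)
    dx = EARTH_RADIUS_KM * 1e3 * np.deg2rad(grid.lon_res) * np.clip(
        np.cos(np.deg2rad(grid.lat_grid())), 1e-6, None
    )
    best = np.full(z.shape, -np.inf)
    for dr, dc in NEIGHBOR_OFFSETS:
        nb = shift(z, dr, dc, fill=np.nan)
        run = np.sqrt((dc * dx) ** 2 + (dr * dy) ** 2)
        with np.errstate(invalid="ignore"):
            g = np.abs(z - nb) / run
        best = np.fmax(best, g)
    slope = np.degrees(np.arctan(np.where(np.isfinite(best), best, 0.0)))
    slope[~land] = np.nan
    return slope


def categorize_slope(slope: np.ndarray) -> np.ndarray:
    """Slope classes 1..10 with inclusive lower bounds (Table-style
    hierarchy: <0.03 -> 1, >=0.03 -> 2, ... >=4.5 -> 10)."""
    slope = np.asarray(slope, dtype=float)
    cat = np.where(np.isfinite(slope),
                   1 + np.searchsorted(SLOPE_BOUNDS, slope, side="right"), 0)
    return cat.astype(np.int64)


def categorize_flux(discharge: np.ndarray) -> np.ndarray:
    """Water-discharge classes 1..5 on log10 m^3/yr: <7, 7-8, 8-9,
    9-10, >=10. Zero discharge falls in class 1; negative is an error."""
    discharge = np.asarray(discharge, dtype=float)
    if np.nanmin(discharge) < 0:
        raise ValueError("discharge must be nonnegative")
    with np.errstate(divide="ignore"):
        lg = np.log10(np.where(discharge > 0, discharge, np.nan))
    lg = np.where(discharge == 0, -np.inf, lg)
    cat = np.where(np.isfinite(lg) | np.isneginf(lg),
                   1 + np.searchsorted(FLUX_BOUNDS, lg, side="right"), 0)
    return cat.astype(np.int64)


def hydro_categories(discharge: np.ndarray) -> np.ndarray:
    """Hydrological categorization H: the 5 log-spaced discharge classes."""
    return categorize_flux(discharge)


def categorize_tpi(tpi_s: np.ndarray) -> np.ndarray:
    """Decile classes 1..10 of the valid-cell TPI_S distribution."""
    tpi_s = np.asarray(tpi_s, dtype=float)
    valid = np.isfinite(tpi_s)
    cat = np.zeros(tpi_s.shape, dtype=np.int64)
    if not valid.any():
        return cat
    qs = np.quantile(tpi_s[valid], np.linspace(0.1, 0.9, 9))
    cat[valid] = 1 + np.searchsorted(qs, tpi_s[valid], side="right")
    return cat


def physiographic_diversity(
    tpi_cat: np.ndarray,
    slope_cat: np.ndarray,
    flux_cat: np.ndarray,
    radius: int = 1,
    n_categories: tuple[int, int, int] = (
        N_TPI_CATEGORIES, N_SLOPE_CATEGORIES, N_FLUX_CATEGORIES,
    ),
) -> np.ndarray:
    """Physiographic diversity Φ in [0, 1].

    For each cell's square window (radius cells, clipped at coasts and
    poles, wrapping in longitude), compute each variable's Shannon index
    d = -sum p_k ln p_k over the observed types, normalize by ln(that
    variable's category count) (Shannon equitability), and average the
    three variables. Φ=0 iff all three layers are locally constant;
    windows with no land observations are NaN.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1 cell")
    layers = [np.asarray(a) for a in (tpi_cat, slope_cat, flux_cat)]
    shape = layers[0].shape
    offsets = [(dr, dc) for dr in range(-radius, radius + 1)
               for dc in range(-radius, radius + 1)]
    equit = np.zeros(shape)
    any_obs = np.zeros(shape, dtype=bool)
    for layer, ncat in zip(layers, n_categories):
        counts = np.zeros((ncat + 1,) + shape)
        for dr, dc in offsets:
            nb = shift(layer.astype(np.int64), dr, dc, fill=0)
            np.clip(nb, 0, ncat, out=nb)
            for k in range(1, ncat + 1):
                counts[k] += nb == k
        total = counts[1:].sum(axis=0)
        any_obs |= total > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            p = counts[1:] / total
            d = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=0)
            equit += np.where(total > 0, d / np.log(ncat), 0.0)
    phi = equit / len(layers)
    phi[~any_obs] = np.nan
    # a cell is only defined where it is itself an observation (land)
    phi[layers[0] == 0] = np.nan
    return phi


def compute_physiography(
    elevation: np.ndarray,
    discharge: np.ndarray,
    land: np.ndarray,
    grid: GridSpec,
    fine_band: ScaleBand = FINE_BAND,
    coarse_band: ScaleBand = COARSE_BAND,
    phi_radius: int = 1,
) -> PhysiographyLayers:
    """Full per-slice pipeline: multi-scale TPI -> standardization ->
    categorical layers -> H and Φ."""
    tpi_f = compute_tpi(elevation, fine_band, land)
    tpi_c = compute_tpi(elevation, coarse_band, land)
    s_f, deg_f = standardize_tpi(tpi_f)
    s_c, deg_c = standardize_tpi(tpi_c)
    stack = np.stack([s_f, s_c])
    cnt = np.isfinite(stack).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpi_s = np.where(cnt > 0, np.nansum(stack, axis=0) / cnt, np.nan)
    slope = compute_slope(elevation, grid, land)
    tpi_cat = categorize_tpi(tpi_s)
    slope_cat = categorize_slope(slope)
    flux = np.where(land, np.nan_to_num(discharge, nan=0.0), np.nan)
    flux_cat = categorize_flux(np.where(land, flux, np.nan))
    flux_cat[~land] = 0
    slope_cat[~land] = 0
    tpi_cat[~land] = 0
    phi = physiographic_diversity(tpi_cat, slope_cat, flux_cat, radius=phi_radius)
    return PhysiographyLayers(
        tpi_fine=tpi_f, tpi_coarse=tpi_c, tpi_s=tpi_s, slope=slope,
        tpi_cat=tpi_cat, slope_cat=slope_cat, flux_cat=flux_cat,
        hydro=flux_cat.copy(), phi=phi, degenerate_tpi=deg_f or deg_c,
    )


def physiography_to_dataset(layers: PhysiographyLayers, grid: GridSpec):
    """Pack a PhysiographyLayers into an xarray Dataset (lat, lon)."""
    import xarray as xr

    data = {
        "tpi_s": layers.tpi_s, "slope": layers.slope,
        "tpi_cat": layers.tpi_cat, "slope_cat": layers.slope_cat,
        "hydro": layers.hydro, "phi": layers.phi,
    }
    return xr.Dataset(
        {k: (("lat", "lon"), np.asarray(v, dtype=float)) for k, v in data.items()},
        coords={"lat": grid.lat, "lon": grid.lon},
        attrs={"lon_res": grid.lon_res, "lat_res": grid.lat_res},
    )
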