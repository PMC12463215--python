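"""Synthetic dynamic paleo-landscapes.

Generates time series of gridded worlds — elevation, temperature,
precipitation, water discharge and a land–sea mask — with the gross
statistical structure of Earth's deep-time reconstructions: a
pole-to-equator temperature gradient, tropics-peaked precipitation, a
configurable Northern-Hemisphere land-area excess, drifting and
fragmenting continents, orogeny pulses, and a transient cooling/drying
step standing in for the K-Pg climate deterioration.

The generator is a stand-in for published reconstruction stacks; it
makes no attempt at plate-tectonic realism beyond smoothly advected
continental blobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import xarray as xr

from .grid import ConfigurationError, GridSpec, NEIGHBOR_OFFSETS, shift

VARIABLES = ("elevation", "temperature", "precipitation", "discharge", "land")

#: nominal fine-mesh cell span (degrees) whose area sets the local runoff
#: contribution per cell; emulates discharge fields computed on a fine
#: source mesh and *interpolated* (not aggregated) to the working grid.
FINE_MESH_DEG = 0.05


@dataclass(frozen=True)
class OrogenyEvent:
    """A mountain-building pulse: a Gaussian bump in elevation that ramps
    up over ~5 Myr after `time` (Ma) and then persists."""

    time: float  # Ma (event onset; active for ages <= time)
    lon: float
    lat: float
    amplitude: float  # m
    radius_deg: float = 15.0


@dataclass(frozen=True)
class WorldConfig:
    seed: int = 0
    n_steps: int = 151  # ages n_steps-1 .. 0 Ma inclusive, 1 Ma apart
    lon_res: float = 2.0
    lat_res: float = 2.0
    n_continents: int = 6
    hemisphere_asymmetry: float = 0.3  # 0 = symmetric land area in expectation
    land_fraction: float = 0.3
    orogeny: tuple[OrogenyEvent, ...] = ()
    fragmentation_times: tuple[float, ...] = ()  # Ma at which one blob splits
    kpg_time: float | None = 66.0  # Ma; None disables the event
    kpg_severity: float = 0.25  # fractional T and P drop
    kpg_duration: int = 2  # steps at full severity
    kpg_recovery: int = 5  # steps of linear recovery
    equator_T: float = 27.0  # deg C zonal profile anchors
    pole_T: float = -18.0
    tropics_P: float = 1.8  # m/yr
    pole_P: float = 0.3
    trend_amplitude_T: float = 3.0  # mid-series thermal maximum, deg C
    fluctuation_T: float = 1.5  # AR(1) step-to-step wobble, deg C
    fluctuation_P: float = 0.10  # AR(1) fractional wobble of the P profile
    drift_deg_per_myr: float = 0.12
    terrain_noise: float = 0.18  # relative to blob amplitude

    def __post_init__(self) -> None:
        if self.equator_T <= self.pole_T:
            raise ConfigurationError("equator_T must exceed pole_T")
        if self.tropics_P <= self.pole_P:
            raise ConfigurationError("tropics_P must exceed pole_P")
        if not 0 <= self.hemisphere_asymmetry <= 1:
            raise ConfigurationError("hemisphere_asymmetry must be in [0, 1]")
        if not 0 < self.land_fraction < 1:
            raise ConfigurationError("land_fraction must be in (0, 1)")
        if self.n_steps < 2:
            raise ConfigurationError("need at least 2 time steps")
        GridSpec(self.lon_res, self.lat_res)  # validates resolution

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.lon_res, self.lat_res)


class LandscapeSeries:
    """A time-stamped stack of world grids, backed by an xarray Dataset
    with dims (time, lat, lon) and variables elevation (m), temperature
    (degC), precipitation (m/yr), discharge (m3/yr), land (0/1).

    `time` holds ages in Ma, strictly decreasing (forward in time).
    """

    def __init__(self, ds: xr.Dataset):
        missing = [v for v in VARIABLES if v not in ds]
        if missing:
            raise FormatError(f"missing variable(s): {', '.join(missing)}")
        self.ds = ds
        self._validate()

    def _validate(self) -> None:
        t = self.ds["time"].values
        if t.size < 2 or not np.all(np.diff(t) < 0):
            raise FormatError("time (age, Ma) must be strictly decreasing")
        land = self.land
        for name in ("elevation", "temperature", "precipitation", "discharge"):
            v = self.ds[name].values
            if v.shape != land.shape:
                raise FormatError(f"inconsistent shape for layer: {name}")
            if np.isnan(v[land]).any():
                raise FormatError(f"missing values on land cells in layer: {name}")
        for name in ("precipitation", "discharge"):
            v = self.ds[name].values
            if np.nanmin(v) < 0:
                raise FormatError(f"negative values in layer: {name}")
        frac = land.mean(axis=(1, 2))
        if np.any(frac <= 0) or np.any(frac >= 1):
            raise FormatError("land fraction must be in (0, 1) at every step")

    # -- accessors ---------------------------------------------------
    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            float(self.ds.attrs["lon_res"]), float(self.ds.attrs["lat_res"])
        )

    @property
    def times(self) -> np.ndarray:
        return self.ds["time"].values

    @property
    def n_steps(self) -> int:
        return self.times.size

    @property
    def land(self) -> np.ndarray:
        return self.ds["land"].values.astype(bool)

    def layer(self, name: str, step: int) -> np.ndarray:
        return self.ds[name].values[step]

    def slice(self, step: int) -> dict[str, np.ndarray]:
        out = {v: self.ds[v].values[step] for v in VARIABLES}
        out["land"] = out["land"].astype(bool)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, LandscapeSeries):
            return NotImplemented
        return self.ds.identical(other.ds)


class FormatError(ValueError):
    """Raised when a landscape file or dataset is malformed."""


# ---------------------------------------------------------------------
# flow accumulation
# ---------------------------------------------------------------------

def flow_accumulate(
    elevation: np.ndarray,
    precipitation: np.ndarray,
    cell_areas: np.ndarray,
    land: np.ndarray | None = None,
) -> np.ndarray:
    """Single-flow-direction (steepest descent) discharge accumulation.

    discharge(cell) = local P*area + sum over upstream donors. Flow goes
    to the lowest of the 8 neighbours if strictly lower; pits (and flat
    cells) retain their accumulated flux as a lake proxy. Sea cells are
    excluded entirely. Longitude wraps; latitude does not.

    Returns discharge in m^3/yr with NaN on sea cells.
    """
    elevation = np.asarray(elevation, dtype=float)
    if land is None:
        land = np.ones(elevation.shape, dtype=bool)
    if not (elevation.shape == precipitation.shape == cell_areas.shape == land.shape):
        raise ValueError("flow_accumulate: input grids must share one shape")

    nlat, nlon = elevation.shape
    # receiver index per cell (flattened), -1 = sink
    receiver = np.full(elevation.size, -1, dtype=np.int64)
    elev_work = np.where(land, elevation, np.nan)
    best_drop = np.zeros(elevation.shape)
    for drow, dcol in NEIGHBOR_OFFSETS:
        nb = shift(elev_work, drow, dcol, fill=np.nan)
        drop = elev_work - nb
        better = land & np.isfinite(drop) & (drop > best_drop)
        if not better.any():
            continue
        rows, cols = np.nonzero(better)
        nrows = rows + drow
        ncols = (cols + dcol) % nlon
        receiver[rows * nlon + cols] = nrows * nlon + ncols
        best_drop[better] = drop[better]

    local = np.where(land, precipitation * cell_areas, 0.0).ravel()
    discharge = local.copy()
    order = np.argsort(elev_work.ravel())[::-1]  # NaNs (sea) sort first, reversed last
    for idx in order:
        if not land.ravel()[idx]:
            continue
        r = receiver[idx]
        if r >= 0:
            discharge[r] += discharge[idx]
    out = discharge.reshape(elevation.shape)
    return np.where(land, out, np.nan)


# ---------------------------------------------------------------------
# world generation
# ---------------------------------------------------------------------

def _smooth(grid: np.ndarray, passes: int = 2) -> np.ndarray:
    """Cheap 3x3 smoothing with lon wrap / lat clamp."""
    out = grid.astype(float)
    for _ in range(passes):
        acc = out.copy()
        cnt = np.ones_like(out)
        for drow, dcol in NEIGHBOR_OFFSETS:
            nb = shift(out, drow, dcol, fill=np.nan)
            ok = np.isfinite(nb)
            acc[ok] += nb[ok]
            cnt += ok
        out = acc / cnt
    return out


def _angular_distance_deg(lat_g, lon_g, lat0, lon0):
    """Great-circle separation in degrees of arc."""
    p1, p2 = np.deg2rad(lat_g), np.deg2rad(lat0)
    dlam = np.deg2rad(lon_g - lon0)
    a = np.sin((p2 - p1) / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return np.rad2deg(2 * np.arcsin(np.sqrt(np.clip(a, 0, 1))))


def _kpg_factor(age: float, cfg: WorldConfig) -> float:
    """Multiplicative climate factor: 1 outside the pseudo-K-Pg window,
    (1 - severity) during the event, linear recovery afterwards."""
    if cfg.kpg_time is None or cfg.kpg_severity == 0:
        return 1.0
    # event occupies ages kpg_time .. kpg_time - duration + 1
    steps_since = cfg.kpg_time - age
    if steps_since < 0:
        return 1.0
    if steps_since < cfg.kpg_duration:
        return 1.0 - cfg.kpg_severity
    rec = steps_since - cfg.kpg_duration
    if rec < cfg.kpg_recovery:
        return 1.0 - cfg.kpg_severity * (1.0 - (rec + 1) / (cfg.kpg_recovery + 1))
    return 1.0


def _terrain_series(config: WorldConfig, mirror: bool):
    """Blob/drift/noise terrain structure, independent of climate.

    Returns per-step (land masks, base elevations). With `mirror` every
    latitude quantity is negated and the noise fields are flipped, so the
    realized land masks are the exact north-south mirror of the
    unmirrored run (used to enforce the configured hemispheric excess).
    """
    grid = config.grid
    nlat, nlon = grid.shape
    lat_g, lon_g = grid.lat_grid(), grid.lon_grid()
    ages = np.arange(config.n_steps - 1, -1, -1, dtype=float)
    sgn = -1.0 if mirror else 1.0

    rng_struct = np.random.default_rng([config.seed, 11])
    rng_noise = np.random.default_rng([config.seed, 13])

    n = config.n_continents
    p_north = (1.0 + config.hemisphere_asymmetry) / 2.0
    north = rng_struct.random(n) < p_north
    # centers area-uniform on the sphere up to 65 deg (as on Earth, some
    # continents straddle the equator), hemisphere chosen by the bias
    alat = np.rad2deg(np.arcsin(rng_struct.uniform(0, np.sin(np.deg2rad(65)), n)))
    lat0 = sgn * alat * np.where(north, 1, -1)
    lon0 = rng_struct.uniform(-180, 180, n)
    radius = rng_struct.uniform(10, 20, n)  # degrees of arc
    amp = rng_struct.uniform(0.8, 1.2, n)
    v_lon = rng_struct.uniform(-1, 1, n) * config.drift_deg_per_myr
    v_lat = sgn * rng_struct.uniform(-0.5, 0.5, n) * config.drift_deg_per_myr
    frag_angles = rng_struct.uniform(0, 2 * np.pi, len(config.fragmentation_times))

    # fragmentation: at each configured age, the largest blob splits in two
    frag = sorted(config.fragmentation_times, reverse=True)
    frag_i = 0

    def draw_noise():
        f = _smooth(rng_noise.standard_normal((nlat, nlon)), passes=2)
        return f[::-1, :] if mirror else f

    # temporally coherent terrain noise (AR(1) on a smoothed white field);
    # frozen inside the K-Pg window (see generate_world)
    noise = draw_noise()
    rho = 0.9

    lands = np.empty((config.n_steps, nlat, nlon), dtype=bool)
    elevs = np.empty((config.n_steps, nlat, nlon))
    noises = np.empty((config.n_steps, nlat, nlon))
    c_lat, c_lon = lat0.copy(), lon0.copy()
    c_rad, c_amp = radius.copy(), amp.copy()
    c_vlat, c_vlon = v_lat.copy(), v_lon.copy()

    for k, age in enumerate(ages):
        in_window = _kpg_factor(age, config) < 1.0
        if k > 0:
            c_lat = np.clip(c_lat + c_vlat, -80, 80)
            c_lon = ((c_lon + c_vlon + 180) % 360) - 180
            if not in_window:
                noise = rho * noise + np.sqrt(1 - rho**2) * draw_noise()
        while frag and age <= frag[0]:
            frag.pop(0)
            i = int(np.argmax(c_amp * c_rad**2))
            off = c_rad[i] * 0.45
            ang = frag_angles[frag_i]
            frag_i += 1
            dlat, dlon = sgn * off * np.sin(ang), off * np.cos(ang)
            new_rad = c_rad[i] / np.sqrt(2)
            c_lat = np.append(c_lat, np.clip(c_lat[i] - dlat, -80, 80))
            c_lon = np.append(c_lon, c_lon[i] - dlon)
            c_rad = np.append(c_rad, new_rad)
            c_amp = np.append(c_amp, c_amp[i])
            c_vlat = np.append(c_vlat, -c_vlat[i])
            c_vlon = np.append(c_vlon, -c_vlon[i] * 0.5)
            c_lat[i] = np.clip(c_lat[i] + dlat, -80, 80)
            c_lon[i] += dlon
            c_rad[i] = new_rad

        field = np.zeros((nlat, nlon))
        for i in range(c_lat.size):
            d = _angular_distance_deg(lat_g, lon_g, c_lat[i], c_lon[i])
            field += c_amp[i] * np.exp(-(d**2) / (2 * c_rad[i] ** 2))
        field += config.terrain_noise * noise * field.std()

        sea_level = np.quantile(field, 1 - config.land_fraction)
        land = field > sea_level
        span_up = max(field.max() - sea_level, 1e-12)
        span_dn = max(sea_level - field.min(), 1e-12)
        elevs[k] = np.where(
            land,
            (field - sea_level) / span_up * 2500.0,
            (field - sea_level) / span_dn * 4000.0,
        )
        lands[k] = land
        noises[k] = noise
    return ages, lands, elevs, noises


def generate_world(config: WorldConfig) -> LandscapeSeries:
    """Generate a deterministic synthetic landscape series from a config.

    Continents are smoothed Gaussian blobs advected by per-continent
    velocities; the land mask is the exceedance set of the configured
    areal land fraction, mirrored north-south if needed so a positive
    hemisphere_asymmetry always yields the configured northern excess.
    Zonal temperature declines monotonically with |lat|; precipitation
    peaks at the tropics. Discharge accumulates precipitation down the
    steepest-descent drainage network.
    """
    grid = config.grid
    nlat, nlon = grid.shape
    lat_g, lon_g = grid.lat_grid(), grid.lon_grid()
    areas = grid.cell_areas_m2()

    ages, lands, elevs, noises = _terrain_series(config, mirror=False)
    if config.hemisphere_asymmetry > 0:
        w = (lands * areas[None]).sum(axis=(0, 2))
        n_area, s_area = w[grid.lat > 0].sum(), w[grid.lat < 0].sum()
        if n_area < s_area:
            ages, lands, elevs, noises = _terrain_series(config, mirror=True)

    rng = np.random.default_rng([config.seed, 17])

    # AR(1) climate wobble; wobble and terrain noise are frozen inside
    # the K-Pg window so the event's step-over-step relative drop equals
    # the configured severity exactly.
    wobble = 0.0
    wobble_p = 0.0
    frozen_offset = 0.0
    frozen_pfac = 1.0

    elev_t = np.empty((config.n_steps, nlat, nlon))
    temp_t = np.empty_like(elev_t)
    prec_t = np.empty_like(elev_t)
    disc_t = np.empty_like(elev_t)
    land_t = np.empty((config.n_steps, nlat, nlon), dtype=np.int8)

    start_age = ages[0]
    fine_area_scale = (FINE_MESH_DEG / config.lat_res) ** 2

    for k, age in enumerate(ages):
        elapsed = start_age - age
        f = _kpg_factor(age, config)
        in_window = f < 1.0
        land = lands[k]
        elev = elevs[k]
        noise = noises[k]
        for ev in config.orogeny:
            if age <= ev.time:
                ramp = min(1.0, (ev.time - age + 1) / 5.0)
                d = _angular_distance_deg(lat_g, lon_g, ev.lat, ev.lon)
                bump = ev.amplitude * ramp * np.exp(-(d**2) / (2 * ev.radius_deg**2))
                elev = np.where(land, elev + bump, elev)

        # --- climate ------------------------------------------------
        if in_window:
            offset = frozen_offset
            pfac = frozen_pfac
        else:
            wobble = 0.85 * wobble + np.sqrt(1 - 0.85**2) * rng.normal(
                0, config.fluctuation_T
            )
            wobble_p = 0.85 * wobble_p + np.sqrt(1 - 0.85**2) * rng.normal(
                0, config.fluctuation_P
            )
            trend = config.trend_amplitude_T * np.sin(
                np.pi * elapsed / max(ages[0], 1)
            )
            offset = trend + wobble
            pfac = max(0.2, 1.0 + wobble_p)
            frozen_offset = offset
            frozen_pfac = pfac
        coslat = np.cos(np.deg2rad(lat_g))
        t_zonal = config.pole_T + (config.equator_T - config.pole_T) * coslat
        temp = f * (t_zonal + offset)

        p_zonal = config.pole_P + (config.tropics_P - config.pole_P) * np.exp(
            -((lat_g / 22.0) ** 2)
        )
        prec = f * pfac * p_zonal
        # spatial texture (smooth, mean ~1) for drainage variety
        prec = prec * np.clip(1.0 + 0.35 * noise / max(noise.std(), 1e-9) * 0.5, 0.2, None)

        disc = flow_accumulate(elev, prec, areas * fine_area_scale, land)

        elev_t[k], temp_t[k], prec_t[k] = elev, temp, prec
        disc_t[k] = np.where(land, disc, np.nan)
        land_t[k] = land.astype(np.int8)

    ds = xr.Dataset(
        {
            "elevation": (("time", "lat", "lon"), elev_t),
            "temperature": (("time", "lat", "lon"), temp_t),
            "precipitation": (("time", "lat", "lon"), prec_t),
            "discharge": (("time", "lat", "lon"), disc_t),
            "land": (("time", "lat", "lon"), land_t),
        },
        coords={"time": ages, "lat": grid.lat, "lon": grid.lon},
        attrs={
            "lon_res": config.lon_res,
            "lat_res": config.lat_res,
            "seed": config.seed,
            "hemisphere_asymmetry": config.hemisphere_asymmetry,
        },
    )
    series = LandscapeSeries(ds)
    _assert_zonal_monotone(series)
    return series


def _assert_zonal_monotone(series: LandscapeSeries) -> None:
    """Zonal-mean T must be non-increasing in |lat| at every step."""
    lat = series.grid.lat
    t = series.ds["temperature"].values.mean(axis=2)  # (time, lat)
    order = np.argsort(np.abs(lat), kind="stable")
    prof = t[:, order]
    if not np.all(np.diff(prof, axis=1) <= 1e-9):
        raise AssertionError("zonal-mean temperature not monotone in |lat|")
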