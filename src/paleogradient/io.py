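"""Reading and writing landscape series.

Two on-disk forms:

* netCDF (classic format via the scipy backend): one file, dims
  (time, lat, lon), variables elevation/temperature/precipitation/
  discharge/land. Round-trips bit-exactly.
* CSV stack: a directory with one file per variable per step
  (``<var>_step0000.csv`` ...), row-major, ``#``-prefixed header lines
  carrying the grid metadata. Round-trips to the written float
  precision (6 significant digits by default).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import xarray as xr

from .world import FormatError, LandscapeSeries, VARIABLES

_CSV_FMT = "%.6e"


def write_landscape(series: LandscapeSeries, path: str | Path, format: str = "netcdf") -> Path:
    path = Path(path)
    if format == "netcdf":
        ds = series.ds.copy()
        ds["land"] = ds["land"].astype(np.int8)
        ds.to_netcdf(path, engine="scipy")
        return path
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        g = series.grid
        for k, age in enumerate(series.times):
            for var in VARIABLES:
                header = (
                    f"# variable={var} step={k} age_ma={age:.6f}\n"
                    f"# lon_res={g.lon_res} lat_res={g.lat_res} "
                    f"nlat={g.nlat} nlon={g.nlon}\n"
                    "# rows north-to-south, columns west-to-east\n"
                )
                fname = path / f"{var}_step{k:04d}.csv"
                arr = series.ds[var].values[k]
                with open(fname, "w") as fh:
                    fh.write(header)
                    np.savetxt(fh, arr, fmt="%d" if var == "land" else _CSV_FMT,
                               delimiter=",")
        return path
    raise ValueError(f"unknown landscape format: {format!r}")


def read_landscape(path: str | Path, format: str = "netcdf") -> LandscapeSeries:
    path = Path(path)
    if format == "netcdf":
        ds = xr.open_dataset(path, engine="scipy").load()
        missing = [v for v in VARIABLES if v not in ds]
        if missing:
            raise FormatError(f"missing variable(s): {', '.join(missing)}")
        return LandscapeSeries(ds)
    if format == "csv":
        return _read_csv_stack(path)
    raise ValueError(f"unknown landscape format: {format!r}")


def _read_csv_stack(path: Path) -> LandscapeSeries:
    files: dict[str, dict[int, Path]] = {v: {} for v in VARIABLES}
    for f in sorted(path.glob("*_step*.csv")):
        var, _, step = f.stem.rpartition("_step")
        if var in files:
            files[var][int(step)] = f
    steps = sorted(files["elevation"])
    if not steps:
        raise FormatError("missing variable(s): elevation")
    for var in VARIABLES:
        if sorted(files[var]) != steps:
            raise FormatError(f"missing variable(s): {var}")

    meta: dict[str, float] = {}
    ages = []
    data = {v: [] for v in VARIABLES}
    for k in steps:
        for var in VARIABLES:
            header: dict[str, str] = {}
            body = _io.StringIO()
            with open(files[var][k]) as fh:
                for line in fh:
                    if line.startswith("#"):
                        for tok in line[1:].split():
                            if "=" in tok:
                                key, _, val = tok.partition("=")
                                header[key] = val
                    else:
                        body.write(line)
            body.seek(0)
            arr = np.loadtxt(body, delimiter=",", ndmin=2)
            data[var].append(arr)
            if var == "elevation":
                ages.append(float(header["age_ma"]))
                meta.setdefault("lon_res", float(header["lon_res"]))
                meta.setdefault("lat_res", float(header["lat_res"]))

    from .grid import GridSpec

    grid = GridSpec(meta["lon_res"], meta["lat_res"])
    shapes = {v: np.asarray(data[v]).shape for v in VARIABLES}
    for v, s in shapes.items():
        if s[1:] != grid.shape:
            raise FormatError(f"inconsistent shape for layer: {v}")
    ds = xr.Dataset(
        {
            v: (
                ("time", "lat", "lon"),
                np.asarray(data[v], dtype=np.int8 if v == "land" else float),
            )
            for v in VARIABLES
        },
        coords={"time": np.asarray(ages), "lat": grid.lat, "lon": grid.lon},
        attrs={"lon_res": grid.lon_res, "lat_res": grid.lat_res},
    )
    return LandscapeSeries(ds)
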