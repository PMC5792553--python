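"""NetCDF / JSON / YAML interfaces for the gridded data structures.

Gridded fields travel as CF-style NetCDF (dims: time, cell; PFT as an extra
dimension), scenarios as a directory of forcing.nc, pft_map.nc, kg.nc,
sif_obs.nc, truth.json and scenario.yaml.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import xarray as xr
import yaml

from siftwin.param_space import ParameterVector, build_parameter_vector, default_parameter_table
from siftwin.sif_operator import SIFField
from siftwin.surrogate import Forcing, GPPField, PFTMap
from siftwin.synthetic import Grid, SyntheticScenario

__all__ = [
    "write_forcing", "read_forcing",
    "write_pft_map", "read_pft_map",
    "write_sif", "read_sif",
    "write_gpp", "save_scenario", "load_scenario",
]


def write_forcing(forcing: Forcing, path) -> None:
    ds = xr.Dataset(
        {
            "air_temperature": (("time", "cell"), forcing.air_temperature),
            "shortwave": (("time", "cell"), forcing.shortwave),
            "soil_moisture": (("time", "cell"), forcing.soil_moisture),
        },
        coords={
            "lat": ("cell", forcing.lat),
            "lon": ("cell", forcing.lon),
        },
        attrs={"year0": forcing.year0},
    )
    ds.to_netcdf(path)


def read_forcing(path) -> Forcing:
    with xr.open_dataset(path) as ds:
        return Forcing(
            air_temperature=ds["air_temperature"].values,
            shortwave=ds["shortwave"].values,
            soil_moisture=ds["soil_moisture"].values,
            lat=ds["lat"].values,
            lon=ds["lon"].values,
            year0=int(ds.attrs["year0"]),
        )


def write_pft_map(pft_map: PFTMap, path) -> None:
    ds = xr.Dataset(
        {
            "fraction": (("cell", "pft"), pft_map.fractions),
            "bare": ("cell", pft_map.bare),
            "area": ("cell", pft_map.area),
        },
        coords={"pft": list(pft_map.pft_indices)},
    )
    ds.to_netcdf(path)


def read_pft_map(path) -> PFTMap:
    with xr.open_dataset(path) as ds:
        return PFTMap(
            fractions=ds["fraction"].values,
            bare=ds["bare"].values,
            area=ds["area"].values,
            pft_indices=tuple(int(p) for p in ds["pft"].values),
        )


def write_sif(field: SIFField, path) -> None:
    ds = xr.Dataset(
        {
            "sif": (("time", "cell"), field.sif),
            "sif_err": (("time", "cell"), field.sigma_obs),
            "mask": (("time", "cell"), field.mask.astype(np.int8)),
        },
        attrs={"year0": field.year0},
    )
    ds.to_netcdf(path)


def read_sif(path) -> SIFField:
    with xr.open_dataset(path) as ds:
        return SIFField(
            sif=ds["sif"].values,
            sigma_obs=ds["sif_err"].values,
            mask=ds["mask"].values.astype(bool),
            year0=int(ds.attrs["year0"]),
        )


def write_gpp(field: GPPField, path) -> None:
    ds = xr.Dataset(
        {
            "gpp": (("time", "cell", "pft"), field.gpp),
            "gpp_aggregate": (("time", "cell"), field.aggregate),
        },
        coords={"pft": list(field.pft_indices)},
        attrs={"year0": field.year0},
    )
    ds.to_netcdf(path)


def _truth_to_json(truth: ParameterVector, path) -> None:
    rows = [
        {"name": name, "pft": pft, "value": float(truth.values[i])}
        for (name, pft), i in sorted(truth.index_map.items(), key=lambda kv: kv[1])
    ]
    Path(path).write_text(json.dumps(rows, indent=1))


def save_scenario(scenario: SyntheticScenario, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_forcing(scenario.forcing, d / "forcing.nc")
    write_pft_map(scenario.pft_map, d / "pft_map.nc")
    write_sif(scenario.observations, d / "sif_obs.nc")
    xr.Dataset({"kg": ("cell", scenario.kg.astype("U1"))}).to_netcdf(d / "kg.nc")
    _truth_to_json(scenario.truth, d / "truth.json")
    meta = {
        "seed": scenario.seed,
        "years": scenario.years,
        "noise_sd": scenario.noise_sd,
        "grid": {
            "n_lat": scenario.grid.n_lat,
            "n_lon": scenario.grid.n_lon,
            "lat_min": scenario.grid.lat_min,
            "lat_max": scenario.grid.lat_max,
        },
    }
    (d / "scenario.yaml").write_text(yaml.safe_dump(meta))


def load_scenario(directory) -> SyntheticScenario:
    d = Path(directory)
    meta = yaml.safe_load((d / "scenario.yaml").read_text())
    grid = Grid(**meta["grid"])
    table = default_parameter_table()
    truth = build_parameter_vector(table)
    for row in json.loads((d / "truth.json").read_text()):
        truth.set(row["name"], row["pft"], row["value"])
    with xr.open_dataset(d / "kg.nc") as ds:
        kg = ds["kg"].values.astype("U1")
    return SyntheticScenario(
        grid=grid,
        seed=int(meta["seed"]),
        years=int(meta["years"]),
        truth=truth,
        noise_sd=float(meta["noise_sd"]),
        forcing=read_forcing(d / "forcing.nc"),
        pft_map=read_pft_map(d / "pft_map.nc"),
        kg=kg,
        observations=read_sif(d / "sif_obs.nc"),
        table=table,
    )
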