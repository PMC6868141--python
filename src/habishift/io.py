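"""Serialization of landscapes and run artifacts.

Rasters travel as NetCDF (via xarray) with one variable per layer family,
or as plain CSV grid dumps for tiny fixtures; occurrences, traits and area
records as CSV; models as JSON; configs as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GridSpec
from .landscapes import LANDUSE_CLASSES, LandscapeBundle


def landscape_to_dataset(bundle: LandscapeBundle) -> xr.Dataset:
    dims2 = ("row", "col")
    return xr.Dataset(
        {
            "tmin": (("month", *dims2), bundle.tmin),
            "tmax": (("month", *dims2), bundle.tmax),
            "prec": (("month", *dims2), bundle.prec),
            "landuse": (("lu_class", *dims2), bundle.landuse),
            "bathymetry": (dims2, bundle.bathymetry),
            "region": (dims2, bundle.region),
        },
        coords={"month": np.arange(1, 13), "lu_class": list(LANDUSE_CLASSES)},
        attrs={
            "cell_size": bundle.grid.cell_size,
            "mode": bundle.grid.mode,
            "lat_top": bundle.grid.lat_top,
        },
    )


def save_landscape(bundle: LandscapeBundle, path: str | Path) -> None:
    landscape_to_dataset(bundle).to_netcdf(path)


def load_landscape(path: str | Path) -> LandscapeBundle:
    ds = xr.load_dataset(path)
    grid = GridSpec(
        n_rows=ds.sizes["row"],
        n_cols=ds.sizes["col"],
        cell_size=float(ds.attrs["cell_size"]),
        mode=str(ds.attrs["mode"]),
        lat_top=float(ds.attrs["lat_top"]),
    )
    return LandscapeBundle(
        grid=grid,
        tmin=ds["tmin"].to_numpy(),
        tmax=ds["tmax"].to_numpy(),
        prec=ds["prec"].to_numpy(),
        landuse=ds["landuse"].to_numpy(),
        bathymetry=ds["bathymetry"].to_numpy(),
        region=ds["region"].to_numpy().astype(int),
    )


def raster_to_csv(values: np.ndarray, path: str | Path) -> None:
    """Plain CSV grid dump (rows x cols) for tiny fixtures."""
    pd.DataFrame(values).to_csv(path, header=False, index=False)


def raster_from_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, header=None).to_numpy()


def occurrences_to_csv(records: np.ndarray, species_id: str, path: str | Path) -> None:
    df = pd.DataFrame(records, columns=["row", "col"])
    df.insert(0, "species_id", species_id)
    df.to_csv(path, index=False)
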