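"""Habitat maps and dispersal-constrained projection.

A suitability raster becomes a boolean habitat map by thresholding, clipping
to the species' native region and to land, and removing habitat on
landmasses that were never connected — at a paleo sea level 130 m below the
present coastline — to a landmass holding an occurrence record.

Future habitat is projected as PFH-CDD (potential future habitat constrained
by dispersal distance): the future suitable map intersected with the buffer
of radius D around the previously occupied habitat, where D comes from the
trait-based dispersal estimate.  Projections chain across horizons: the
second-horizon buffer grows from the first-horizon PFH-CDD, driver set by
driver set (LU, CC, LUCC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import GridSpec
from .landscapes import ScenarioSet, ARMS, DRIVER_SETS, HORIZONS

_STRUCTURE_8 = np.ones((3, 3), dtype=bool)
_STRUCTURE_4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class HabitatMap:
    """Boolean suitable/unsuitable raster for one species under one scenario."""

    mask: np.ndarray  # bool (n_rows, n_cols)
    grid: GridSpec
    species_id: str = ""
    tag: str = "current"

    @property
    def area(self) -> float:
        """Total habitat area in km^2 (cell-area weighted)."""
        return float(self.grid.cell_areas()[self.mask].sum())


def make_habitat_map(
    suitability: np.ndarray,
    threshold: float,
    native_mask: np.ndarray,
    grid: GridSpec,
    land_mask: np.ndarray | None = None,
    species_id: str = "",
    tag: str = "current",
) -> HabitatMap:
    """Cell is habitat iff suitability >= threshold, inside the native mask, on land."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    if not native_mask.any():
        raise ValueError("empty native mask")
    mask = (suitability >= threshold) & native_mask
    if land_mask is not None:
        mask = mask & land_mask
    return HabitatMap(mask=mask, grid=grid, species_id=species_id, tag=tag)


def connectivity_filter(
    hmap: HabitatMap,
    bathymetry: np.ndarray,
    occurrence_cells: np.ndarray,
    sea_level_offset: float = -130.0,
    connectivity: int = 8,
) -> HabitatMap:
    """Drop habitat on paleo-landmasses holding no occurrence record.

    The paleo landmass is every cell with elevation >= ``sea_level_offset``
    (m, negative below present sea level); its connected components (8- or
    4-connectivity) that contain at least one occurrence cell keep their
    habitat, all others lose it.
    """
    if bathymetry.shape != hmap.mask.shape:
        raise ValueError("bathymetry grid mismatch")
    structure = _STRUCTURE_8 if connectivity == 8 else _STRUCTURE_4
    paleo_land = bathymetry >= sea_level_offset
    labels, _ = ndimage.label(paleo_land, structure=structure)
    occ = np.asarray(occurrence_cells, dtype=int).reshape(-1, 2)
    occ_labels = set(labels[occ[:, 0], occ[:, 1]].tolist()) - {0}
    if not occ_labels:
        raise ValueError("no occurrence cell lies on a paleo landmass")
    keep = np.isin(labels, sorted(occ_labels))
    return HabitatMap(
        mask=hmap.mask & keep, grid=hmap.grid, species_id=hmap.species_id, tag=hmap.tag
    )


def pfh_cdd(previous: HabitatMap, future_suitable: HabitatMap, D: float) -> HabitatMap:
    """Future suitable cells within centre-to-centre distance D (km) of previous habitat.

    A cell is within distance 0 of itself, so D = 0 keeps exactly the
    previously occupied cells that remain suitable.
    """
    if previous.mask.shape != future_suitable.mask.shape:
        raise ValueError("grid mismatch between previous and future maps")
    if D < 0:
        raise ValueError("dispersal distance must be >= 0")
    if not previous.mask.any():
        reachable = np.zeros_like(previous.mask)
    else:
        dist = ndimage.distance_transform_edt(~previous.mask) * previous.grid.cell_size_km()
        reachable = dist <= D + 1e-9
    return HabitatMap(
        mask=future_suitable.mask & reachable,
        grid=future_suitable.grid,
        species_id=future_suitable.species_id,
        tag=future_suitable.tag,
    )


def project_species(
    predict_fn,
    threshold: float,
    native_mask: np.ndarray,
    occurrence_cells: np.ndarray,
    dispersal_km: tuple[float, float],
    scenarios: ScenarioSet,
    species_id: str = "",
    sea_level_offset: float = -130.0,
) -> dict:
    """Chain PFH-CDD projections across horizons for every arm and driver set.

    Parameters
    ----------
    predict_fn
        Callable mapping a landscape bundle to a suitability raster.
    dispersal_km
        (D for t0 -> h1, D for h1 -> h2), already converted via the
        dispersal estimate for the corresponding year spans.
    Returns a dict with key "current" -> HabitatMap and keys
    (arm, horizon, driver) -> HabitatMap.
    """
    grid = scenarios.current.grid
    land = scenarios.current.land_mask
    bathy = scenarios.current.bathymetry

    def habitat(landscape, tag):
        suit = predict_fn(landscape)
        hm = make_habitat_map(
            suit, threshold, native_mask, grid, land_mask=land,
            species_id=species_id, tag=tag,
        )
        return connectivity_filter(hm, bathy, occurrence_cells, sea_level_offset)

    out: dict = {"current": habitat(scenarios.current, "current")}
    d1, d2 = dispersal_km
    for arm in ARMS:
        for driver in DRIVER_SETS:
            prev = out["current"]
            for hz, d in zip(HORIZONS, (d1, d2)):
                suitable = habitat(scenarios.get(arm, hz, driver), f"{arm}:{hz}:{driver}")
                proj = pfh_cdd(prev, suitable, d)
                out[(arm, hz, driver)] = proj
                prev = proj
    return out
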