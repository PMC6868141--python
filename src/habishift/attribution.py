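"""Driver attribution: six-way decomposition of habitat loss and gain.

Loss is defined against the realistic combined scenario: a cell is lost when
it is habitat now (H0) but not in the LUCC projection.  The single-driver
counterfactual maps assign blame:

* lost to land use   — lost, not in LU, but in CC;
* lost to climate    — lost, not in CC, but in LU;
* lost to combined   — every remaining lost cell (unsuitable under either
  driver alone, or only under their joint action).

Gains mirror this with the roles reversed (gained = LUCC but not H0; gained
by the driver whose single-driver map also contains the cell while the other
does not).  The eight categories, together with unchanged suitable and
unchanged unsuitable, partition the land cells exactly, so per-driver areas
sum to the total loss and gain by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .habitat import HabitatMap

CATEGORY_NAMES = (
    "unchanged_unsuitable",  # 0
    "unchanged_suitable",    # 1
    "lost_LU",               # 2
    "lost_CC",               # 3
    "lost_combined",         # 4
    "gained_LU",             # 5
    "gained_CC",             # 6
    "gained_combined",       # 7
)

LOSS_CATEGORIES = ("lost_LU", "lost_CC", "lost_combined")
GAIN_CATEGORIES = ("gained_LU", "gained_CC", "gained_combined")


@dataclass
class AttributionResult:
    """Per-cell category raster and per-category areas for one species/scenario."""

    category: np.ndarray  # int8 raster, codes index CATEGORY_NAMES; -1 off-domain
    areas: dict  # category name -> km^2
    species_id: str = ""
    arm: str = ""
    horizon: str = ""

    @property
    def lost_total(self) -> float:
        return sum(self.areas[c] for c in LOSS_CATEGORIES)

    @property
    def gained_total(self) -> float:
        return sum(self.areas[c] for c in GAIN_CATEGORIES)


def decompose_change(
    h0: HabitatMap,
    lu: HabitatMap,
    cc: HabitatMap,
    lucc: HabitatMap,
    domain: np.ndarray | None = None,
) -> AttributionResult:
    """Classify every cell of the domain into the eight change categories.

    ``domain`` defaults to all cells; typically the species' native land
    mask.  Cells outside the domain get code -1.
    """
    maps = (h0, lu, cc, lucc)
    shape = h0.mask.shape
    if any(m.mask.shape != shape for m in maps):
        raise ValueError("grid mismatch among the four habitat maps")
    ids = {m.species_id for m in maps if m.species_id}
    if len(ids) > 1:
        raise ValueError(f"maps from different species: {sorted(ids)}")

    H0, LU, CC, LUCC = (m.mask for m in maps)
    lost = H0 & ~LUCC
    gained = ~H0 & LUCC

    cat = np.zeros(shape, dtype=np.int8)
    cat[H0 & LUCC] = 1
    cat[lost & ~LU & CC] = 2
    cat[lost & ~CC & LU] = 3
    cat[lost & (cat == 0)] = 4  # remaining lost cells
    # at this point every lost cell is 2/3/4; remaining zeros are non-lost
    cat[gained & LU & ~CC] = 5
    cat[gained & CC & ~LU] = 6
    cat[gained & ~((LU & ~CC) | (CC & ~LU))] = 7

    if domain is None:
        domain = np.ones(shape, dtype=bool)
    cat = np.where(domain, cat, -1).astype(np.int8)

    cell_areas = h0.grid.cell_areas()
    areas = {
        name: float(cell_areas[(cat == code) & domain].sum())
        for code, name in enumerate(CATEGORY_NAMES)
    }
    return AttributionResult(category=cat, areas=areas, species_id=h0.species_id)


def summarize_areas(
    results: list,
    meta: pd.DataFrame,
    current_areas: dict,
    area_floor: float = 1e-6,
) -> pd.DataFrame:
    """Tidy per-species area records for the downstream statistics.

    Parameters
    ----------
    results
        List of ``AttributionResult`` with ``species_id``, ``arm`` and
        ``horizon`` set; optionally an ``ssp``/``replicate`` attribute pair
        attached by the caller (read with getattr).
    meta
        One row per species: columns ``species_id``, ``taxon_group``,
        ``region`` (native-region label, or "multiple").
    current_areas
        species_id -> current habitat area (km^2); floored at ``area_floor``.
    """
    meta = meta.set_index("species_id")
    rows = []
    for res in results:
        if res.species_id not in meta.index:
            raise KeyError(f"missing region/taxon metadata for {res.species_id}")
        cur = max(float(current_areas[res.species_id]), area_floor)
        info = meta.loc[res.species_id]
        row = {
            "species_id": res.species_id,
            "taxon_group": info["taxon_group"],
            "region": info["region"],
            "arm": res.arm,
            "horizon": res.horizon,
            "ssp": getattr(res, "ssp", "SSP2"),
            "replicate": getattr(res, "replicate", "rep0"),
            "current_area": cur,
            "lost_total": res.lost_total,
            "gained_total": res.gained_total,
        }
        for c in LOSS_CATEGORIES + GAIN_CATEGORIES:
            row[c] = res.areas[c]
        for c in ("lost_total", "gained_total") + LOSS_CATEGORIES + GAIN_CATEGORIES:
            row[f"prop_{c}"] = row[c] / cur
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_by_region(
    records: pd.DataFrame, value: str = "prop_lost_LU", drop_multi_region: bool = True
) -> pd.DataFrame:
    """Species-equal averages per region x taxon x arm x horizon.

    Species labelled as occupying multiple regions are excluded, matching
    the convention for regional regressions.
    """
    df = records
    if drop_multi_region:
        df = df[df["region"] != "multiple"]
    keys = ["region", "taxon_group", "arm", "horizon", "ssp"]
    return df.groupby(keys, as_index=False)[value].mean()
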