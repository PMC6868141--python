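"""The 19 bioclimatic variables derived from monthly tmin/tmax/precipitation.

Definitions follow the WorldClim/ANUCLIM conventions: monthly mean
temperature is (tmin + tmax) / 2; "quarters" are running three-month windows
with December-January wraparound (ties broken by the earliest window);
temperature seasonality (bio4) is 100 x the population standard deviation of
monthly means; precipitation seasonality (bio15) is the coefficient of
variation of monthly precipitation with the mean floored at 1 mm to avoid
division by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BIOCLIM_NAMES = tuple(f"bio{i}" for i in range(1, 20))

#: human-readable definitions, for reports
BIOCLIM_LABELS = {
    "bio1": "annual mean temperature",
    "bio2": "mean diurnal range",
    "bio3": "isothermality (100 * bio2 / bio7)",
    "bio4": "temperature seasonality (100 * SD of monthly means)",
    "bio5": "max temperature of warmest month",
    "bio6": "min temperature of coldest month",
    "bio7": "temperature annual range",
    "bio8": "mean temperature of wettest quarter",
    "bio9": "mean temperature of driest quarter",
    "bio10": "mean temperature of warmest quarter",
    "bio11": "mean temperature of coldest quarter",
    "bio12": "annual precipitation",
    "bio13": "precipitation of wettest month",
    "bio14": "precipitation of driest month",
    "bio15": "precipitation seasonality (CV)",
    "bio16": "precipitation of wettest quarter",
    "bio17": "precipitation of driest quarter",
    "bio18": "precipitation of warmest quarter",
    "bio19": "precipitation of coldest quarter",
}


@dataclass
class BioclimStack:
    """19 bioclim layers over an arbitrary trailing cell shape."""

    layers: np.ndarray  # (19, ...) in the order of BIOCLIM_NAMES
    names: tuple = BIOCLIM_NAMES

    def get(self, name: str) -> np.ndarray:
        return self.layers[self.names.index(name)]


def _select_by_index(values: np.ndarray, index: np.ndarray) -> np.ndarray:
    """values (12, ...) picked per-cell at month/window ``index`` (...)."""
    return np.take_along_axis(values, index[None], axis=0)[0]


def compute_bioclim(tmin: np.ndarray, tmax: np.ndarray, prec: np.ndarray) -> BioclimStack:
    """Compute the 19 bioclim layers from 12-month climate stacks.

    Parameters
    ----------
    tmin, tmax, prec
        Arrays of shape ``(12, ...)``; any trailing cell shape is accepted
        (gridded rasters or flat cell vectors alike).
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    prec = np.asarray(prec, dtype=float)
    for name, arr in (("tmin", tmin), ("tmax", tmax), ("prec", prec)):
        if arr.shape[0] != 12:
            raise ValueError(f"{name} must have 12 months on axis 0, got {arr.shape}")
    if tmin.shape != tmax.shape or tmin.shape != prec.shape:
        raise ValueError("tmin, tmax and prec shapes must match")
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin in some cell-month")

    tavg = (tmin + tmax) / 2.0
    cell_shape = tavg.shape[1:]

    bio1 = tavg.mean(axis=0)
    bio2 = (tmax - tmin).mean(axis=0)
    bio4 = 100.0 * tavg.std(axis=0)  # population SD
    bio5 = tmax.max(axis=0)
    bio6 = tmin.min(axis=0)
    bio7 = bio5 - bio6
    with np.errstate(divide="ignore", invalid="ignore"):
        bio3 = np.where(bio7 > 0, 100.0 * bio2 / np.where(bio7 > 0, bio7, 1.0), 0.0)

    # running quarters with wraparound; window w covers months w, w+1, w+2
    q_idx = (np.arange(12)[:, None] + np.arange(3)[None, :]) % 12
    q_prec = prec[q_idx].sum(axis=1)  # (12, ...)
    q_temp = tavg[q_idx].mean(axis=1)

    wettest = q_prec.argmax(axis=0)
    driest = q_prec.argmin(axis=0)
    warmest = q_temp.argmax(axis=0)
    coldest = q_temp.argmin(axis=0)

    bio8 = _select_by_index(q_temp, wettest)
    bio9 = _select_by_index(q_temp, driest)
    bio10 = q_temp.max(axis=0)
    bio11 = q_temp.min(axis=0)
    bio12 = prec.sum(axis=0)
    bio13 = prec.max(axis=0)
    bio14 = prec.min(axis=0)
    pmean = prec.mean(axis=0)
    bio15 = 100.0 * prec.std(axis=0) / np.maximum(pmean, 1.0)
    bio16 = q_prec.max(axis=0)
    bio17 = q_prec.min(axis=0)
    bio18 = _select_by_index(q_prec, warmest)
    bio19 = _select_by_index(q_prec, coldest)

    layers = np.stack(
        [bio1, bio2, bio3, bio4, bio5, bio6, bio7, bio8, bio9, bio10, bio11,
         bio12, bio13, bio14, bio15, bio16, bio17, bio18, bio19]
    ).reshape((19, *cell_shape))
    return BioclimStack(layers=layers)
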