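"""Aggregate species occurrence records into source/sink habitat sites.

Occurrences are snapped to a fixed equal-angle grid whose latitudinal
step corresponds to the stated resolution (km / 111.32 km-per-degree)
and whose longitudinal step is scaled by cos(latitude of the domain
centre), giving near-square ~resolution-sized cells without per-row
grids. One site is created per occupied cell, at the cell centre.
Cell indexing is 0-based and half-open (a cell owns its lower/left
edge), anchored at (-180, -90), so aggregation is order-independent
and idempotent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import KM_PER_DEG, haversine_km

#: how many cells away a land-stranded occurrence may be snapped
SNAP_RANGE_CELLS = 2


@dataclass
class SiteSet:
    """Habitat sites: one row per occupied grid cell.

    ``table`` columns: site_id (contiguous from 0), lon, lat (cell
    centre), cell_i, cell_j, n_occ. ``n_dropped`` counts occurrences
    on land beyond snapping range.
    """

    table: pd.DataFrame
    resolution_km: float
    lon_step: float
    lat_step: float
    n_dropped: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, resolution_km: float = 1.0) -> "SiteSet":
        t = pd.read_csv(path)
        lat_step = resolution_km / KM_PER_DEG
        lon_step = lat_step / max(math.cos(math.radians(t["lat"].mean())), 1e-9)
        return cls(table=t, resolution_km=resolution_km,
                   lon_step=lon_step, lat_step=lat_step)


def aggregate_occurrences(occ: pd.DataFrame, resolution_km: float,
                          field=None, lat_center: float | None = None) -> SiteSet:
    """Aggregate an occurrence table (columns lon, lat) into a SiteSet.

    ``lat_center`` fixes the latitude at which the longitudinal step is
    scaled; by default it is the occurrence bounding-box midpoint
    rounded to the nearest degree (rounding keeps re-aggregation of the
    resulting site centres on the identical grid). When a velocity
    ``field`` (with a land mask) is given, occurrences falling in
    land-centred cells are snapped to the nearest ocean-centred cell
    within 2 cells, else dropped (counted in ``n_dropped``; a warning
    is emitted). Raises on an empty table or if every occurrence is
    un-snappable land.
    """
    if occ is None or len(occ) == 0:
        raise ValueError("empty occurrence table")
    if resolution_km <= 0:
        raise ValueError("resolution_km must be > 0")
    lon = occ["lon"].to_numpy(dtype=float)
    lat = occ["lat"].to_numpy(dtype=float)
    if np.any((lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)):
        raise ValueError("coordinates outside valid lon/lat ranges")

    lat_step = resolution_km / KM_PER_DEG
    if lat_center is None:
        lat_center = round(float((lat.min() + lat.max()) / 2.0))
    lon_step = lat_step / max(math.cos(math.radians(lat_center)), 1e-9)

    def cell_of(lo, la):
        return (np.floor((lo + 180.0) / lon_step).astype(int),
                np.floor((la + 90.0) / lat_step).astype(int))

    def center_of(ci, cj):
        return ((np.asarray(ci) + 0.5) * lon_step - 180.0,
                (np.asarray(cj) + 0.5) * lat_step - 90.0)

    ci, cj = cell_of(lon, lat)
    keep = np.ones(len(lon), dtype=bool)
    if field is not None:
        clon, clat = center_of(ci, cj)
        on_land = np.asarray(field.is_land(clon, clat))
        offs = [(di, dj) for di in range(-SNAP_RANGE_CELLS, SNAP_RANGE_CELLS + 1)
                for dj in range(-SNAP_RANGE_CELLS, SNAP_RANGE_CELLS + 1)
                if (di, dj) != (0, 0)]
        for k in np.flatnonzero(on_land):
            best, best_d = None, np.inf
            for di, dj in offs:
                nlon, nlat = center_of(ci[k] + di, cj[k] + dj)
                if not bool(field.is_land(nlon, nlat)):
                    d = float(haversine_km(lon[k], lat[k], nlon, nlat))
                    if d < best_d:
                        best, best_d = (ci[k] + di, cj[k] + dj), d
            if best is None:
                keep[k] = False
            else:
                ci[k], cj[k] = best
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} occurrence(s) on land beyond snap range dropped")
    if not keep.any():
        raise ValueError("all occurrences on land beyond snapping range")

    df = pd.DataFrame({"cell_i": ci[keep], "cell_j": cj[keep]})
    grouped = df.groupby(["cell_i", "cell_j"], sort=True).size().reset_index(name="n_occ")
    clon, clat = center_of(grouped["cell_i"].to_numpy(), grouped["cell_j"].to_numpy())
    table = pd.DataFrame({
        "site_id": np.arange(len(grouped)),
        "lon": clon,
        "lat": clat,
        "cell_i": grouped["cell_i"],
        "cell_j": grouped["cell_j"],
        "n_occ": grouped["n_occ"],
    })
    return SiteSet(table=table, resolution_km=resolution_km,
                   lon_step=lon_step, lat_step=lat_step, n_dropped=n_dropped)
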