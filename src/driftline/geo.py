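"""Spherical-earth geometry helpers shared across the simulation modules.

All distances use a spherical earth of radius 6371 km. Longitudes are
degrees east in [-180, 180], latitudes degrees north.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0
EARTH_RADIUS_M = EARTH_RADIUS_KM * 1000.0
#: kilometres per degree of latitude (and of longitude at the equator)
KM_PER_DEG = 111.32


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Fully vectorised; inputs broadcast against each other.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def displacement_deg(u, v, lat_deg, dt_seconds):
    """Convert a velocity (m/s east, m/s north) held for ``dt_seconds``
    into a (dlon, dlat) displacement in degrees at latitude ``lat_deg``.

    dlon = u*dt / (R cos(phi)) * 180/pi,  dlat = v*dt / R * 180/pi.
    """
    lat_rad = np.radians(np.asarray(lat_deg, dtype=float))
    dlat = np.asarray(v, dtype=float) * dt_seconds / EARTH_RADIUS_M * (180.0 / np.pi)
    coslat = np.cos(lat_rad)
    # degenerate exactly at the poles; synthetic domains never reach them
    dlon = np.asarray(u, dtype=float) * dt_seconds / (EARTH_RADIUS_M * coslat) * (180.0 / np.pi)
    return dlon, dlat


def local_xy_m(lon, lat, lon0, lat0):
    """Equirectangular (flat-earth) coordinates in metres about (lon0, lat0).

    The metric is frozen at the reference latitude, so rigid-rotation
    fields built with it have exactly linear speed-vs-radius profiles
    under the same metric.
    """
    x = np.radians(np.asarray(lon, dtype=float) - lon0) * EARTH_RADIUS_M * np.cos(np.radians(lat0))
    y = np.radians(np.asarray(lat, dtype=float) - lat0) * EARTH_RADIUS_M
    return x, y
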