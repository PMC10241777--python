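import numpy as np
import pandas as pd
import pytest

from driftline.sites import SiteSet
from driftline.geo import KM_PER_DEG


def site_set_from_coords(coords, resolution_km=1.0):
    """Build a SiteSet directly from (lon, lat) pairs, one cell each."""
    lat_step = resolution_km / KM_PER_DEG
    lon_step = lat_step
    table = pd.DataFrame({
        "site_id": np.arange(len(coords)),
        "lon": [c[0] for c in coords],
        "lat": [c[1] for c in coords],
        "cell_i": np.arange(len(coords)),
        "cell_j": np.zeros(len(coords), dtype=int),
        "n_occ": np.ones(len(coords), dtype=int),
    })
    return SiteSet(table=table, resolution_km=resolution_km,
                   lon_step=lon_step, lat_step=lat_step)


def cell_center(lon, lat, resolution_km=1.0, lat_center=None):
    """Centre of the aggregation cell containing (lon, lat) — the same
    fixed-grid convention as sites.aggregate_occurrences."""
    import math

    lat_step = resolution_km / KM_PER_DEG
    if lat_center is None:
        lat_center = round(lat)
    lon_step = lat_step / math.cos(math.radians(lat_center))
    ci = math.floor((lon + 180.0) / lon_step)
    cj = math.floor((lat + 90.0) / lat_step)
    return (ci + 0.5) * lon_step - 180.0, (cj + 0.5) * lat_step - 90.0


@pytest.fixture
def equator_box():
    """Bounds of a small open-ocean box on the equator."""
    return dict(lon_min=-40.0, lon_max=-30.0, lat_min=-5.0, lat_max=5.0)
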