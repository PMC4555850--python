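"""Geodesic helpers shared across the package.

All distances in kilometres use the haversine formula on a sphere of mean
Earth radius 6371.0088 km.  Clustering and HMM emissions, by contrast, work
in raw (lon, lat) degree space; only diagnostics and city matching use km.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088

#: km spanned by one degree of latitude (and of longitude at the equator)
#: under the small-window local approximation used for raster windows.
KM_PER_DEG = 111.32


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between (lon, lat) points in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def deg_arc_km(degrees: float) -> float:
    """Great-circle length of an arc of the given angular size in degrees."""
    return EARTH_RADIUS_KM * np.radians(degrees)
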