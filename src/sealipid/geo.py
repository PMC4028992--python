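"""Great-circle geometry for daily telemetry tracks.

All distances are great-circle (haversine) kilometres on a sphere of
radius 6371 km; no map projection is used anywhere in the package.
Longitudes are taken in (-180, 180] and latitudes in [-90, 90].
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = ["EARTH_RADIUS_KM", "haversine_km"]


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance between points in decimal degrees.

    Parameters are scalars or broadcastable arrays. Latitudes outside
    [-90, 90] raise ``ValueError``.
    """
    lon1, lat1, lon2, lat2 = (np.asarray(v, dtype=float) for v in (lon1, lat1, lon2, lat2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude outside [-90, 90] degrees")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    if d.ndim == 0:
        return float(d)
    return d
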