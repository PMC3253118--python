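"""Lambert cylindrical equal-area projection (spherical, standard parallel 0).

All inter-point distances, ellipse axes and cell areas in the pipeline are
computed in this projected space so that areas are undistorted.  The sphere
uses the authalic Earth radius, so a region's projected area equals its
spherical area exactly.
"""

from __future__ import annotations

import numpy as np

#: Authalic Earth radius in metres (sphere with the WGS84 ellipsoid's area).
EARTH_RADIUS_M = 6_371_007.181


def geographic_to_equal_area(
    lon: np.ndarray | float, lat: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Forward projection: WGS84 degrees -> equal-area metres.

    x = R * lambda,  y = R * sin(phi), with the standard parallel on the
    Equator.  (0, 0) maps to the origin.
    """
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    return EARTH_RADIUS_M * lam, EARTH_RADIUS_M * np.sin(phi)


def equal_area_to_geographic(
    x: np.ndarray | float, y: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse projection: equal-area metres -> WGS84 degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = np.degrees(x / EARTH_RADIUS_M)
    s = np.clip(y / EARTH_RADIUS_M, -1.0, 1.0)
    lat = np.degrees(np.arcsin(s))
    return lon, lat


def cell_area_km2(lat_south: float, lat_north: float, dlon_deg: float) -> float:
    """Exact spherical area (km^2) of a lon/lat cell, via the projection.

    Because the projection is equal-area, this is simply the projected
    rectangle's area.
    """
    x0, y0 = geographic_to_equal_area(0.0, lat_south)
    x1, y1 = geographic_to_equal_area(dlon_deg, lat_north)
    return abs((x1 - x0) * (y1 - y0)) / 1e6
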