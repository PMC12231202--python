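"""Geodesic helpers: haversine distance and a local azimuthal-equidistant plane.

All movement-scale geometry in the pipeline (departure displacement,
confinement radii, kernel home ranges) operates at the tens-of-kilometres
scale of a single lake system, where a spherical Earth model is accurate to
well under 0.5%.
"""

from __future__ import annotations

import numpy as np

#: Mean Earth radius (m), IUGG.
EARTH_RADIUS_M = 6_371_008.8


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres between points in degrees (WGS84 sphere).

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


class LocalProjection:
    """Azimuthal equidistant projection centred on (lon0, lat0).

    Distances from the centre are exact great-circle distances; distortion of
    distances between off-centre points is O((d/R)^2), negligible at the
    <100 km scale this package works at.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._sin0 = np.sin(np.radians(lat0))
        self._cos0 = np.cos(np.radians(lat0))

    def forward(self, lon, lat):
        """Degrees -> local metres (x east, y north)."""
        lam = np.radians(np.asarray(lon, dtype=float) - self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        cos_c = np.clip(self._sin0 * np.sin(phi) + self._cos0 * np.cos(phi) * np.cos(lam), -1.0, 1.0)
        c = np.arccos(cos_c)
        sin_c = np.sin(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(sin_c > 1e-12, c / np.where(sin_c > 1e-12, sin_c, 1.0), 1.0)
        x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(lam)
        y = EARTH_RADIUS_M * k * (self._cos0 * np.sin(phi) - self._sin0 * np.cos(phi) * np.cos(lam))
        return x, y

    def inverse(self, x, y):
        """Local metres -> degrees."""
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_M
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_M
        c = np.hypot(x, y)
        safe_c = np.where(c > 1e-12, c, 1.0)
        phi0 = np.radians(self.lat0)
        phi = np.where(
            c > 1e-12,
            np.arcsin(np.clip(np.cos(safe_c) * np.sin(phi0) + (y * np.sin(safe_c) / safe_c) * np.cos(phi0), -1, 1)),
            phi0,
        )
        lam = np.where(
            c > 1e-12,
            np.arctan2(x * np.sin(safe_c), safe_c * np.cos(safe_c) * np.cos(phi0) - y * np.sin(safe_c) * np.sin(phi0)),
            0.0,
        )
        return self.lon0 + np.degrees(lam), np.degrees(phi)
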