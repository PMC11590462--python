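"""Geographic primitives.

Great-circle distances and a local azimuthal-equidistant plane used to keep
all stochastic-process and density math Euclidean (km) while tracks live in
WGS84 lon/lat.  Distortion of the local plane is negligible at home-range
scales (tens of km).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between two points (decimal degrees).

    Vectorised: any argument may be an array; broadcasting applies.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


class LocalPlane:
    """Azimuthal-equidistant projection about a centre point.

    ``to_km`` maps lon/lat to (east, north) km offsets; ``to_lonlat`` inverts.
    Spherical formulas (Snyder); exact round-trip away from the antipode.
    """

    def __init__(self, centre_lon: float, centre_lat: float):
        self.centre_lon = float(centre_lon)
        self.centre_lat = float(centre_lat)
        self._lam0 = np.radians(self.centre_lon)
        self._phi0 = np.radians(self.centre_lat)

    def to_km(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        dlam = lam - self._lam0
        cosc = np.sin(self._phi0) * np.sin(phi) + np.cos(self._phi0) * np.cos(phi) * np.cos(dlam)
        c = np.arccos(np.clip(cosc, -1.0, 1.0))
        az = np.arctan2(
            np.cos(phi) * np.sin(dlam),
            np.cos(self._phi0) * np.sin(phi) - np.sin(self._phi0) * np.cos(phi) * np.cos(dlam),
        )
        rho = EARTH_RADIUS_KM * c
        return rho * np.sin(az), rho * np.cos(az)

    def to_lonlat(self, x_km, y_km):
        x = np.asarray(x_km, dtype=float)
        y = np.asarray(y_km, dtype=float)
        c = np.hypot(x, y) / EARTH_RADIUS_KM
        az = np.arctan2(x, y)
        sinc, cosc = np.sin(c), np.cos(c)
        phi = np.arcsin(np.clip(cosc * np.sin(self._phi0) + sinc * np.cos(self._phi0) * np.cos(az), -1.0, 1.0))
        lam = self._lam0 + np.arctan2(
            sinc * np.sin(az),
            np.cos(self._phi0) * cosc - np.sin(self._phi0) * sinc * np.cos(az),
        )
        lon = np.degrees(lam)
        # wrap to [-180, 180]
        lon = (lon + 180.0) % 360.0 - 180.0
        return lon, np.degrees(phi)
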