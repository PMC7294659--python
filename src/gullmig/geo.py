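"""Geodesic distances and the local tangent-plane projection.

Reported track distances use the inverse geodesic on the WGS-84
ellipsoid (Vincenty's iterative solution); the spherical haversine is
the fast path used only for the 200 km/h speed filter, where the
< 0.6 % sphere/ellipsoid discrepancy cannot change which fixes survive
a threshold that outliers exceed by an order of magnitude.

Movement is simulated and modelled on a local azimuthal-equirectangular
tangent plane (km east/north of a reference point, usually the breeding
colony); the plane is the *definition* of the process model, and
geographic coordinates are obtained by the inverse projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WGS84_A = 6378137.0          # semi-major axis, m
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)

EARTH_RADIUS_KM = 6371.0088  # mean radius used by the haversine path

KM_PER_DEG_LAT = 110.574     # meridian degree at mid-latitudes


@dataclass(frozen=True)
class GeodesicSpec:
    """Which distance formula reported metrics use.

    ``vincenty_ellipsoid`` (WGS-84) is the default for every reported
    quantity; ``haversine`` exists for speed filtering and cross-checks.
    """

    method: str = "vincenty_ellipsoid"
    ellipsoid: str = "WGS-84"

    def __post_init__(self) -> None:
        if self.method not in ("vincenty_ellipsoid", "haversine"):
            raise ValueError(f"unknown geodesic method {self.method!r}")


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance on the mean-radius sphere, km. Vectorized."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def vincenty_km(lon1: float, lat1: float, lon2: float, lat2: float,
                tol: float = 1e-12, max_iter: int = 200) -> float:
    """Inverse geodesic distance on the WGS-84 ellipsoid, km.

    Vincenty's (1975) iterative inverse solution.  For near-antipodal
    pairs where the iteration fails to converge the haversine result is
    returned instead (documented fallback; the difference is below the
    flattening, ~0.5 %).  Raises ``ValueError`` on non-finite input.
    """
    for v in (lon1, lat1, lon2, lat2):
        if not np.isfinite(v):
            raise ValueError("non-finite coordinate passed to vincenty_km")
    if lon1 == lon2 and lat1 == lat2:
        return 0.0

    a, b, f = WGS84_A, WGS84_B, WGS84_F
    L = np.radians(lon2 - lon1)
    U1 = np.arctan((1.0 - f) * np.tan(np.radians(lat1)))
    U2 = np.arctan((1.0 - f) * np.tan(np.radians(lat2)))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma = np.hypot(cosU2 * sin_lam,
                             cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
        if sin_sigma == 0.0:
            return 0.0  # coincident after reduction
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha ** 2
        if cos2_alpha == 0.0:
            cos_2sigma_m = 0.0  # equatorial line
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
        C = f / 16.0 * cos2_alpha * (4.0 + f * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * f * sin_alpha * (
            sigma + C * sin_sigma * (
                cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)))
        if abs(lam - lam_prev) < tol:
            break
    else:
        # near-antipodal: Vincenty's inverse is known not to converge
        return float(haversine_km(lon1, lat1, lon2, lat2))

    u2 = cos2_alpha * (a ** 2 - b ** 2) / b ** 2
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    delta_sigma = B * sin_sigma * (
        cos_2sigma_m + B / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)
            - B / 6.0 * cos_2sigma_m * (-3.0 + 4.0 * sin_sigma ** 2)
            * (-3.0 + 4.0 * cos_2sigma_m ** 2)))
    return b * A * (sigma - delta_sigma) / 1000.0


def geodesic_km(p1, p2, spec: GeodesicSpec | None = None) -> float:
    """Distance between two (lon, lat) points under ``spec``, km."""
    spec = spec or GeodesicSpec()
    lon1, lat1 = float(p1[0]), float(p1[1])
    lon2, lat2 = float(p2[0]), float(p2[1])
    if spec.method == "haversine":
        return float(haversine_km(lon1, lat1, lon2, lat2))
    return vincenty_km(lon1, lat1, lon2, lat2)


@dataclass(frozen=True)
class TangentPlane:
    """Equirectangular local plane: km east (x) / north (y) of a reference."""

    lon0: float
    lat0: float
    km_per_deg_lon: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "km_per_deg_lon",
            KM_PER_DEG_LAT * np.cos(np.radians(self.lat0)))

    def to_plane(self, lon, lat):
        """(lon, lat) degrees -> (x, y) km. Vectorized."""
        x = (np.asarray(lon, dtype=float) - self.lon0) * self.km_per_deg_lon
        y = (np.asarray(lat, dtype=float) - self.lat0) * KM_PER_DEG_LAT
        return x, y

    def to_lonlat(self, x, y):
        """(x, y) km -> (lon, lat) degrees. Vectorized."""
        lon = self.lon0 + np.asarray(x, dtype=float) / self.km_per_deg_lon
        lat = self.lat0 + np.asarray(y, dtype=float) / KM_PER_DEG_LAT
        return lon, lat
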