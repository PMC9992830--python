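"""Ellipsoidal Lambert azimuthal equal-area projection.

Forward and inverse mappings for the oblique ellipsoidal case, following the
standard geodesy formulation (Snyder; IOGP guidance note 7-2).  The default
parameterization is the European grid (ETRS89-LAEA, EPSG:3035): GRS80
ellipsoid, origin 52N 10E, false easting 4321000 m, false northing 3210000 m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["LaeaProjection", "EUROPEAN_GRID"]

# GRS80
_A = 6378137.0
_F = 1.0 / 298.257222101


def _q(e: float, sinphi: float) -> float:
    esin = e * sinphi
    return (1.0 - e * e) * (
        sinphi / (1.0 - esin * esin)
        - (1.0 / (2.0 * e)) * math.log((1.0 - esin) / (1.0 + esin))
    )


@dataclass(frozen=True)
class LaeaProjection:
    """Oblique Lambert azimuthal equal-area on an ellipsoid of revolution."""

    lat_0: float
    lon_0: float
    false_easting: float = 0.0
    false_northing: float = 0.0
    a: float = _A
    f: float = _F

    def _constants(self):
        e2 = self.f * (2.0 - self.f)
        e = math.sqrt(e2)
        phi0 = math.radians(self.lat_0)
        qp = _q(e, 1.0)
        q0 = _q(e, math.sin(phi0))
        beta0 = math.asin(q0 / qp)
        rq = self.a * math.sqrt(qp / 2.0)
        m0 = math.cos(phi0) / math.sqrt(1.0 - e2 * math.sin(phi0) ** 2)
        d = self.a * m0 / (rq * math.cos(beta0))
        return e, e2, qp, beta0, rq, d

    def forward(self, lon: float, lat: float) -> tuple[float, float]:
        """Geographic degrees -> planar meters (easting, northing)."""
        e, _, qp, beta0, rq, d = self._constants()
        phi = math.radians(lat)
        lam = math.radians(lon - self.lon_0)
        beta = math.asin(max(-1.0, min(1.0, _q(e, math.sin(phi)) / qp)))
        denom = 1.0 + math.sin(beta0) * math.sin(beta) + math.cos(beta0) * math.cos(
            beta
        ) * math.cos(lam)
        b = rq * math.sqrt(2.0 / denom)
        x = b * d * math.cos(beta) * math.sin(lam)
        y = (b / d) * (
            math.cos(beta0) * math.sin(beta)
            - math.sin(beta0) * math.cos(beta) * math.cos(lam)
        )
        return x + self.false_easting, y + self.false_northing

    def inverse(self, x: float, y: float) -> tuple[float, float]:
        """Planar meters -> geographic degrees (lon, lat)."""
        e, e2, qp, beta0, rq, d = self._constants()
        xr = x - self.false_easting
        yr = y - self.false_northing
        rho = math.hypot(xr / d, d * yr)
        if rho == 0.0:
            return self.lon_0, self.lat_0
        ce = 2.0 * math.asin(rho / (2.0 * rq))
        q = qp * (
            math.cos(ce) * math.sin(beta0)
            + d * yr * math.sin(ce) * math.cos(beta0) / rho
        )
        lam = math.atan2(
            xr * math.sin(ce),
            d * rho * math.cos(ce) * math.cos(beta0)
            - d * d * yr * math.sin(ce) * math.sin(beta0),
        )
        # fixed-point iteration for the geodetic latitude from the authalic q
        phi = math.asin(max(-1.0, min(1.0, q / 2.0)))
        for _ in range(30):
            sinphi = math.sin(phi)
            esin = e * sinphi
            corr = (
                (1.0 - esin * esin) ** 2
                / (2.0 * math.cos(phi))
                * (
                    q / (1.0 - e2)
                    - sinphi / (1.0 - esin * esin)
                    + (1.0 / (2.0 * e))
                    * math.log((1.0 - esin) / (1.0 + esin))
                )
            )
            phi += corr
            if abs(corr) < 1e-14:
                break
        return self.lon_0 + math.degrees(lam), math.degrees(phi)


EUROPEAN_GRID = LaeaProjection(
    lat_0=52.0, lon_0=10.0, false_easting=4321000.0, false_northing=3210000.0
)
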