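"""Spherical direction grids and the lat-lon <-> unit-vector convention.

The shell around the target is parametrized by latitude ``phi`` (degrees,
+90 = superior pole = +z) and longitude ``lam`` (degrees, 0 = anterior).
Anterior is the -y world axis by default (patients lie supine on the
scanner bed, which is posterior), configurable for non-standard frames.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SphereFrame", "direction_grid"]


class SphereFrame:
    """Orthonormal frame defining the shell parametrization."""

    def __init__(self, anterior=(0.0, -1.0, 0.0), north=(0.0, 0.0, 1.0)):
        a = np.asarray(anterior, float)
        n = np.asarray(north, float)
        a = a / np.linalg.norm(a)
        n = n - (n @ a) * a
        n = n / np.linalg.norm(n)
        self.anterior = a
        self.north = n
        self.east = np.cross(n, a)

    def direction(self, phi_deg, lam_deg) -> np.ndarray:
        """Unit vector(s) for latitude/longitude in degrees (broadcasting)."""
        phi = np.deg2rad(np.asarray(phi_deg, float))
        lam = np.deg2rad(np.asarray(lam_deg, float))
        cp = np.cos(phi)
        d = (
            (cp * np.cos(lam))[..., None] * self.anterior
            + (cp * np.sin(lam))[..., None] * self.east
            + np.sin(phi)[..., None] * self.north
        )
        return d

    def latlon(self, direction) -> tuple[np.ndarray, np.ndarray]:
        """Inverse of :meth:`direction`; returns (phi_deg, lam_deg)."""
        d = np.asarray(direction, float)
        s = d @ self.north
        phi = np.arcsin(np.clip(s, -1.0, 1.0))
        lam = np.arctan2(d @ self.east, d @ self.anterior)
        return np.rad2deg(phi), np.rad2deg(lam)


def direction_grid(resolution_deg: float, frame: SphereFrame | None = None):
    """Dense lat-lon grid of unit directions.

    Returns ``(phi_deg (nlat,), lam_deg (nlon,), dirs (nlat, nlon, 3))``
    with latitude from +90 down to -90 and longitude from -180 to
    180 - resolution.  ``resolution_deg`` must divide 180 evenly.
    """
    if resolution_deg <= 0 or abs(180.0 / resolution_deg - round(180.0 / resolution_deg)) > 1e-9:
        raise ValueError("resolution_deg must divide 180 evenly")
    frame = frame or SphereFrame()
    nlat = int(round(180.0 / resolution_deg)) + 1
    nlon = int(round(360.0 / resolution_deg))
    phi = 90.0 - np.arange(nlat) * resolution_deg
    lam = -180.0 + np.arange(nlon) * resolution_deg
    dirs = frame.direction(phi[:, None], lam[None, :])
    return phi, lam, dirs
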