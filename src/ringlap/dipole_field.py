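"""Closed-form dipole potential and surface Laplacian in a homogeneous medium.

The validation model is a unit current dipole buried at depth ``z = -depth``
below the measurement plane ``z = 0``, oriented along +Z, in an unbounded
homogeneous medium of conductivity ``sigma``.  With distances in cm, the
conductivity entered as 7.14 (mS/cm, emulating biological tissue) and a unit
dipole moment, the resulting potentials read as volts.

``analytical_laplacian`` implements the standard closed form for the surface
Laplacian of that potential.  Note its orientation: on the source-free
measurement plane the potential is harmonic in 3-D, so this expression
equals ``d2v/dz2 = -(d2v/dx2 + d2v/dy2)`` — the current-source-density sign
convention used throughout electrophysiology, positive above the dipole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Dipole", "potential", "analytical_laplacian"]

#: Tissue-emulating conductivity, entered in mS/cm.
DEFAULT_SIGMA = 7.14


@dataclass(frozen=True)
class Dipole:
    """Dipole location (cm), moment and medium conductivity."""

    location: tuple[float, float, float]
    moment: tuple[float, float, float] = (0.0, 0.0, 1.0)
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"conductivity must be positive, got {self.sigma}")


def _displacements(dipole: Dipole, xp, yp, zp):
    x0, y0, z0 = dipole.location
    dx = np.asarray(xp, dtype=float) - x0
    dy = np.asarray(yp, dtype=float) - y0
    dz = np.asarray(zp, dtype=float) - z0
    dist2 = dx * dx + dy * dy + dz * dz
    if np.any(dist2 == 0):
        raise ValueError("observation point coincides with the dipole location")
    return dx, dy, dz, np.sqrt(dist2)


def potential(dipole: Dipole, xp, yp, zp=0.0):
    """Dipole potential ``v = (r_rel . p) / (4 pi sigma |r_rel|**3)`` (V).

    Accepts scalars or broadcastable arrays of observation coordinates (cm).
    """
    dx, dy, dz, dist = _displacements(dipole, xp, yp, zp)
    px, py, pz = dipole.moment
    dot = dx * px + dy * py + dz * pz
    return dot / (4.0 * np.pi * dipole.sigma * dist**3)


def analytical_laplacian(dipole: Dipole, xp, yp, zp=0.0):
    """Surface Laplacian of the dipole potential (V/cm^2), CSD orientation.

    ``3/(4 pi sigma) * [5 dz^2 (r_rel . p) / |r_rel|^7
    - ((r_rel . p) + 2 dz pz) / |r_rel|^5]``.

    On axis this reduces to ``6 / (4 pi sigma depth**4)`` (positive above a
    +Z dipole); it equals minus the tangential (x, y) Laplacian of
    :func:`potential` wherever the medium is source-free.
    """
    dx, dy, dz, dist = _displacements(dipole, xp, yp, zp)
    px, py, pz = dipole.moment
    dot = dx * px + dy * py + dz * pz
    return (3.0 / (4.0 * np.pi * dipole.sigma)) * (
        5.0 * dz * dz * dot / dist**7 - (dot + 2.0 * dz * pz) / dist**5
    )
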