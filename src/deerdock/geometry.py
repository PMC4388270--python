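"""Internal-coordinate helpers: atom placement from bond/angle/dihedral and
dihedral measurement.

``place_atom`` implements the standard chain-propagation construction (the
natural extension reference frame): given three previously placed atoms
a-b-c, the new atom d is positioned at a given bond length |c-d|, bond angle
b-c-d and dihedral a-b-c-d.  Applied residue by residue this reproduces the
classical recursive polymer-coordinate builds of Sugeta & Miyazawa and
Shimanouchi & Mizushima.
"""

from __future__ import annotations

import numpy as np

__all__ = ["place_atom", "dihedral", "bond_angle", "unit"]


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dihedral_angle: float) -> np.ndarray:
    """Place atom d so that |cd| = bond, angle(b,c,d) = ``angle`` and
    dihedral(a,b,c,d) = ``dihedral_angle``.  Angles in radians.

    Hot path of the chain growers; scalar arithmetic avoids the overhead of
    the generic numpy cross/norm machinery.
    """
    from math import cos, sin, sqrt

    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    nrm = sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    if nrm < 1e-12:
        raise ValueError("zero-length bond vector")
    bcx, bcy, bcz = bcx / nrm, bcy / nrm, bcz / nrm
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = sqrt(nx * nx + ny * ny + nz * nz)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms: dihedral frame degenerate")
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond * cos(angle)
    sa = bond * sin(angle)
    d1 = sa * cos(dihedral_angle)
    d2 = -sa * sin(dihedral_angle)  # sign fixes the standard IUPAC convention
    return np.array([c[0] + d0 * bcx + d1 * mx + d2 * nx,
                     c[1] + d0 * bcy + d1 * my + d2 * ny,
                     c[2] + d0 * bcz + d1 * mz + d2 * nz])


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
             p4: np.ndarray) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in radians, in (-pi, pi]."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, unit(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return float(np.arctan2(y, x))


def bond_angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle p1-p2-p3 in radians."""
    v1 = unit(p1 - p2)
    v2 = unit(p3 - p2)
    return float(np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0)))


def virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral C-beta position from backbone N, CA, C."""
    # 1.53 A bond, 110.5 deg angle to N, -122.5 deg dihedral from C
    return place_atom(c, n, ca, 1.53, np.deg2rad(110.5), np.deg2rad(-122.5))
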