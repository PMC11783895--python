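"""Low-level 3D geometry: internal-coordinate placement and rigid superposition.

Conventions
-----------
An atom placed in internal coordinates is specified by a bond length to a
*parent* atom P, a bond angle against an *angle reference* A, and a torsion
against a *dihedral reference* D.  The torsion X-P-A-D is measured about the
P-A axis with the IUPAC sign convention (right-handed, cis = 0).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "place_atom",
    "bond_angle",
    "dihedral_angle",
    "kabsch_rmsd",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("degenerate reference geometry (zero-length vector)")
    return v / n


def place_atom(p: np.ndarray, a: np.ndarray, d: np.ndarray,
               length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position a new atom X given references P, A, D (NeRF construction).

    ``length`` is |X-P| in Angstrom, ``angle_deg`` the X-P-A angle and
    ``torsion_deg`` the X-P-A-D torsion, both in degrees.
    """
    p = np.asarray(p, float)
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(torsion_deg)
    # local frame at P: bc points from A to P
    bc = _unit(p - a)
    n = _unit(np.cross(a - d, bc))
    m = np.cross(n, bc)
    # spherical offset in that frame
    d2 = np.array([
        -length * np.cos(theta),
        length * np.sin(theta) * np.cos(phi),
        -length * np.sin(theta) * np.sin(phi),
    ])
    return p + d2[0] * bc + d2[1] * m + d2[2] * n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """A-B-C angle in degrees."""
    u = _unit(np.asarray(a, float) - b)
    v = _unit(np.asarray(c, float) - b)
    return float(np.rad2deg(np.arccos(np.clip(u @ v, -1.0, 1.0))))


def dihedral_angle(x: np.ndarray, p: np.ndarray, a: np.ndarray, d: np.ndarray) -> float:
    """Torsion X-P-A-D in degrees, measured about the P-A axis, in (-180, 180]."""
    b0 = np.asarray(x, float) - p
    b1 = np.asarray(a, float) - p
    b2 = np.asarray(d, float) - a
    n1 = np.cross(b0, b1)
    n2 = np.cross(-b1, b2)
    m1 = np.cross(n1, _unit(b1))
    ang = np.arctan2(m1 @ n2, n1 @ n2)
    deg = float(np.rad2deg(ang))
    return 180.0 if deg <= -180.0 else deg


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD between corresponding point sets after optimal rigid fit.

    Least-squares rotation found by SVD of the covariance (Kabsch), with the
    usual determinant correction so only proper rotations are allowed.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    s_corr = s.copy()
    s_corr[-1] *= sign
    # RMSD directly from the singular values: avoids building the rotation
    msd = (np.sum(ac * ac) + np.sum(bc * bc) - 2.0 * np.sum(s_corr)) / a.shape[0]
    return float(np.sqrt(max(msd, 0.0)))
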