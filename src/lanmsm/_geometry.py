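"""Internal-coordinate geometry: dihedrals and peptide chain building."""

from __future__ import annotations

import numpy as np

# Standard peptide backbone internal coordinates (Engh-Huber-like), Angstrom
# and degrees.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_CB = 110.5
TORSION_C_N_CA_CB = -122.0  # fixes side-chain branch orientation

IDEAL_HELIX = (-57.0, -47.0)
EXTENDED = (-139.0, 135.0)


def dihedral(p0, p1, p2, p3):
    """Signed dihedral angle in degrees for points of shape (..., 3)."""
    p0, p1, p2, p3 = (np.asarray(p) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


def place_atom(a, b, c, bond: float, angle: float, torsion: float):
    """NeRF placement: position d bonded to c with angle(b,c,d) and
    torsion(a,b,c,d), in degrees."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    th = np.radians(angle)
    ph = np.radians(torsion)
    d_local = bond * np.array(
        [-np.cos(th), -np.sin(th) * np.cos(ph), -np.sin(th) * np.sin(ph)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def build_backbone(phi, psi, omega: float = 180.0):
    """Build N/CA/C backbone coordinates from per-residue (phi, psi).

    Parameters
    ----------
    phi, psi : sequences of length n_residues, degrees. ``phi[0]`` and
        ``psi[-1]`` are undefined at chain termini and ignored.

    Returns
    -------
    ndarray of shape (n_residues, 3, 3): per residue the N, CA, C positions.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n = len(phi)
    if len(psi) != n or n < 2:
        raise ValueError("phi and psi must share length >= 2")
    coords = np.zeros((n, 3, 3))
    coords[0, 0] = [0.0, 0.0, 0.0]  # N1
    coords[0, 1] = [BOND_N_CA, 0.0, 0.0]  # CA1
    th = np.radians(ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array(
        [-np.cos(th), np.sin(th), 0.0]
    )
    for i in range(n - 1):
        n_i, ca_i, c_i = coords[i]
        n_next = place_atom(n_i, ca_i, c_i, BOND_C_N, ANGLE_CA_C_N, psi[i])
        ca_next = place_atom(ca_i, c_i, n_next, BOND_N_CA, ANGLE_C_N_CA, omega)
        c_next = place_atom(c_i, n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C,
                            phi[i + 1])
        coords[i + 1] = [n_next, ca_next, c_next]
    return coords


def place_cb(n, ca, c):
    """Place a beta-carbon on a residue from its backbone atoms."""
    return place_atom(c, n, ca, BOND_CA_CB, ANGLE_N_CA_CB, TORSION_C_N_CA_CB)
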