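"""Internal geometry helpers: dihedrals and torsion-driven chain building."""

from __future__ import annotations

import numpy as np

# Ideal backbone internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(
    p_a: np.ndarray, p_b: np.ndarray, p_c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """NeRF placement: new atom D with |CD| = bond, angle B-C-D, torsion A-B-C-D."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = p_c - p_b
    bc /= np.linalg.norm(bc)
    ab = p_b - p_a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return p_c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi_psi: list[tuple[float, float]]) -> np.ndarray:
    """Build N-CA-C-O backbone coordinates from per-residue (φ, ψ) torsions.

    φ of the first residue is undefined and ignored; ω is fixed trans.
    Returns an (n_residues, 4, 3) array ordered N, CA, C, O.
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")
    coords = np.zeros((n_res, 4, 3))
    # seed first residue
    coords[0, 0] = [0.0, 0.0, 0.0]                     # N
    coords[0, 1] = [BOND_N_CA, 0.0, 0.0]               # CA
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for r in range(1, n_res):
        psi_prev = phi_psi[r - 1][1]
        phi = phi_psi[r][0]
        n_prev, ca_prev, c_prev = coords[r - 1, 0], coords[r - 1, 1], coords[r - 1, 2]
        coords[r, 0] = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi_prev)
        coords[r, 1] = place_atom(ca_prev, c_prev, coords[r, 0], BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        coords[r, 2] = place_atom(c_prev, coords[r, 0], coords[r, 1], BOND_CA_C, ANGLE_N_CA_C, phi)
    # carbonyl O: trans to the next N (or to the chain direction at the C-terminus)
    for r in range(n_res):
        if r + 1 < n_res:
            ref = dihedral(coords[r, 0], coords[r, 1], coords[r, 2], coords[r + 1, 0])
            tor = ref + 180.0
        else:
            tor = phi_psi[r][1] + 180.0
        coords[r, 3] = place_atom(coords[r, 0], coords[r, 1], coords[r, 2], BOND_C_O, ANGLE_CA_C_O, tor)
    return coords


def backbone_dihedrals(
    n: np.ndarray, ca: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue (φ, ψ) in degrees from (n_res, 3) N/CA/C arrays; NaN at termini."""
    n_res = len(ca)
    phi = np.full(n_res, np.nan)
    psi = np.full(n_res, np.nan)
    for r in range(n_res):
        if r > 0:
            phi[r] = dihedral(c[r - 1], n[r], ca[r], c[r])
        if r + 1 < n_res:
            psi[r] = dihedral(n[r], ca[r], c[r], n[r + 1])
    return phi, psi
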