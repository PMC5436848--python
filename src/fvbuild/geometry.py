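"""Low-level structural geometry: internal-coordinate chain building, rigid
superposition, dihedral angles and inter-domain orientation frames.

All coordinates are float64 numpy arrays of shape (n, 3) in Angstrom.
"""

from __future__ import annotations

import numpy as np

# Ideal backbone geometry (Engh & Huber style averages).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_N_CA_CB = 110.5


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural extension reference frame: place atom d so that |c-d| = bond,
    angle(b,c,d) = angle_deg and torsion(a,b,c,d) = torsion_deg."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise ValueError("colinear reference atoms for internal-coordinate placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle in degrees."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def build_backbone(torsions: list[tuple[float, float, float]],
                   glycine_mask: list[bool] | None = None) -> list[dict[str, np.ndarray]]:
    """Build a polypeptide backbone from per-residue (phi, psi, omega) torsions.

    ``omega[i]`` is the peptide torsion CA(i)-C(i)-N(i+1)-CA(i+1); phi of the
    first residue is unused.  Returns one atom dict per residue with keys
    N, CA, C, O and CB (CB omitted where ``glycine_mask`` is true).
    """
    n_res = len(torsions)
    if glycine_mask is None:
        glycine_mask = [False] * n_res
    residues: list[dict[str, np.ndarray]] = []
    # Seed the first three atoms in a canonical pose.
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    prev = {"N": n0, "CA": ca0, "C": c0}
    for i, (phi, psi, omega) in enumerate(torsions):
        if i == 0:
            atoms = dict(prev)
        else:
            pp = residues[i - 1]
            _, ppsi, pomega = torsions[i - 1]
            n = place_atom(pp["N"], pp["CA"], pp["C"], BOND_C_N, ANGLE_CA_C_N, ppsi)
            ca = place_atom(pp["CA"], pp["C"], n, BOND_N_CA, ANGLE_C_N_CA, pomega)
            c = place_atom(pp["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
            atoms = {"N": n, "CA": ca, "C": c}
        # Carbonyl oxygen anti-periplanar to the following N (psi + 180).
        atoms["O"] = place_atom(atoms["N"], atoms["CA"], atoms["C"],
                                BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        if not glycine_mask[i]:
            atoms["CB"] = place_atom(atoms["C"], atoms["N"], atoms["CA"],
                                     BOND_CA_CB, ANGLE_N_CA_CB, 122.6)
        residues.append(atoms)
    return residues


def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal-geometry CB position from backbone N, CA, C."""
    return place_atom(c, n, ca, BOND_CA_CB, ANGLE_N_CA_CB, 122.6)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (rotation R, translation t, rmsd) such that mobile @ R.T + t
    best fits target; R is a proper rotation (det +1).
    """
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("superposition requires matched (n, 3) coordinate arrays")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    P = mobile - cm
    Q = target - ct
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    moved = P @ R.T + ct
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, t, rmsd


def apply_rigid(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no fitting)."""
    if a.shape != b.shape:
        raise ValueError("RMSD requires matched coordinate arrays")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    theta = np.deg2rad(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def rotation_angle(R: np.ndarray) -> float:
    """Rotation angle of a proper rotation matrix, degrees in [0, 180]."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def domain_frame(coords: np.ndarray) -> np.ndarray:
    """Orthonormal orientation frame of a domain from the principal axes of its
    core coordinates.

    Eigenvector signs are fixed covariantly (against vectors drawn from the
    coordinates themselves), so the frame rotates rigidly with the domain and
    the relative orientation of two frames is well defined.  Raises on
    near-degenerate axes.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 5:
        raise ValueError("too few core positions for a domain frame")
    centroid = coords.mean(axis=0)
    X = coords - centroid
    C = X.T @ X / coords.shape[0]
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[0] < 1e-6 or (evals[0] - evals[1]) / evals[0] < 1e-4:
        raise ValueError("degenerate principal axes: near-spherical or flat core")
    # Covariant sign references: chain-direction and first-point vectors.
    u1 = coords[-1] - coords[0]
    u2 = coords[0] - centroid
    a1 = evecs[:, 0]
    if abs(np.dot(a1, u1)) < 1e-6:
        raise ValueError("degenerate sign reference for principal axis 1")
    if np.dot(a1, u1) < 0:
        a1 = -a1
    a2 = evecs[:, 1]
    u2p = u2 - np.dot(u2, a1) * a1
    if np.linalg.norm(u2p) < 1e-6 or abs(np.dot(a2, u2p)) < 1e-6:
        raise ValueError("degenerate sign reference for principal axis 2")
    if np.dot(a2, u2p) < 0:
        a2 = -a2
    a3 = np.cross(a1, a2)
    return np.column_stack([a1, a2, a3])
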