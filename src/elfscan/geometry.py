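"""Idealized peptide geometry built from internal coordinates.

Backbones are grown atom by atom with the natural-extension-reference-frame
(NeRF) construction from standard bond lengths and angles (Engh & Huber
values, to two decimals), with user-supplied phi/psi and trans omega.  Side
chains are available for the residue types the interface fixtures need
(Ala, Asp, Arg, Phe, Leu); rotamers default to common staggered torsions.

No energy model is involved: detectors downstream are purely geometric, so
idealized geometry is sufficient to pose, e.g., a beta-strand at sheet
dihedrals or an Arg-Asp pair at an exact nitrogen-oxygen distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

# backbone internal coordinates (angstroms / degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.2, 116.2, 121.7
A_CA_C_O = 120.8
OMEGA_TRANS = 180.0

BETA_PHI_PSI = (-139.0, 135.0)    # antiparallel beta-sheet dihedrals
ALPHA_PHI_PSI = (-57.0, -47.0)    # alpha-helix dihedrals
EXTENDED_PHI_PSI = (-180.0, 180.0)


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D bonded to C with |CD| = bond, angle(B,C,D), dihedral(A,B,C,D)."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class GeoResidue:
    name: str                       # 3-letter code
    seq: int                        # residue number
    atoms: dict                     # atom name -> np.ndarray(3)
    confidence: float = 90.0        # planted pLDDT


# side-chain topology: atom -> ((grandparent, parent_of_parent, parent), bond, angle, dihedral)
# dihedral entries given as strings "chi1"/"chi2"... are looked up in the rotamer dict
_CB = ("C", "N", "CA")  # improper C-N-CA-CB places CB for an L-amino acid
SIDE_CHAINS: dict[str, list] = {
    "GLY": [],
    "ALA": [("CB", _CB, 1.53, 110.4, -122.6)],
    "ASP": [
        ("CB", _CB, 1.53, 110.4, -122.6),
        ("CG", ("N", "CA", "CB"), 1.52, 112.6, "chi1"),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118.4, "chi2"),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118.4, "chi2+180"),
    ],
    "ARG": [
        ("CB", _CB, 1.53, 110.4, -122.6),
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, "chi1"),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, "chi2"),
        ("NE", ("CB", "CG", "CD"), 1.46, 112.0, "chi3"),
        ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, "chi4"),
        ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0),
    ],
    "PHE": [
        ("CB", _CB, 1.53, 110.4, -122.6),
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, "chi2+180"),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
    "LEU": [
        ("CB", _CB, 1.53, 110.4, -122.6),
        ("CG", ("N", "CA", "CB"), 1.53, 116.3, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.52, 110.7, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.52, 110.7, "chi2+120"),
    ],
}

DEFAULT_ROTAMERS = {"chi1": -65.0, "chi2": 180.0, "chi3": 180.0, "chi4": 180.0}


def build_chain(sequence: Sequence[str], phi_psi: Sequence[tuple[float, float]],
                start_seq: int = 1,
                rotamers: Optional[dict[str, float]] = None) -> list[GeoResidue]:
    """Build a peptide of 3-letter residue names at the given (phi, psi) per residue.

    phi of the first residue and psi of the last are still consumed (psi
    shapes the final carbonyl); omega is trans throughout.
    """
    if len(sequence) != len(phi_psi):
        raise ValueError("need one (phi, psi) pair per residue")
    rot = dict(DEFAULT_ROTAMERS, **(rotamers or {}))

    residues: list[GeoResidue] = []
    # seed first three backbone atoms in a canonical frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([B_N_CA, 0.0, 0.0])
    c0 = nerf(np.array([-1.0, 1.0, 0.0]), n0, ca0, B_CA_C, A_N_CA_C, phi_psi[0][0])
    backbone = [{"N": n0, "CA": ca0, "C": c0}]
    for i in range(1, len(sequence)):
        prev = backbone[-1]
        psi_prev = phi_psi[i - 1][1]
        n = nerf(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psi_prev)
        ca = nerf(prev["CA"], prev["C"], n, B_N_CA, A_C_N_CA, OMEGA_TRANS)
        c = nerf(prev["C"], n, ca, B_CA_C, A_N_CA_C, phi_psi[i][0])
        backbone.append({"N": n, "CA": ca, "C": c})

    for i, (name, bb) in enumerate(zip(sequence, backbone)):
        atoms = dict(bb)
        # carbonyl O: anti to the next amide N (or to a virtual psi continuation)
        if i + 1 < len(backbone):
            next_n = backbone[i + 1]["N"]
            atoms["O"] = nerf(next_n, atoms["CA"], atoms["C"], B_C_O, A_CA_C_O, 180.0)
        else:
            atoms["O"] = nerf(atoms["N"], atoms["CA"], atoms["C"], B_C_O, A_CA_C_O,
                              phi_psi[i][1] + 180.0)
        for entry in SIDE_CHAINS.get(name, []):
            atom_name, (ga, pa, pb), bond, angle, dihedral = entry
            if isinstance(dihedral, str):
                if "+" in dihedral:
                    key, offset = dihedral.split("+")
                    dihedral = rot[key] + float(offset)
                else:
                    dihedral = rot[dihedral]
            atoms[atom_name] = nerf(atoms[ga], atoms[pa], atoms[pb], bond, angle, dihedral)
        residues.append(GeoResidue(name=name, seq=start_seq + i, atoms=atoms))
    return residues


def transform(residues: list[GeoResidue], rotation: np.ndarray,
              translation: np.ndarray) -> list[GeoResidue]:
    """Apply a rigid-body transform (rotation matrix + translation) to a chain."""
    out = []
    for res in residues:
        atoms = {k: rotation @ v + translation for k, v in res.atoms.items()}
        out.append(GeoResidue(res.name, res.seq, atoms, res.confidence))
    return out


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)
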