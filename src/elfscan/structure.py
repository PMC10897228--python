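"""Interface featurization of predicted two-chain complexes.

Miro clients engage the ELF pocket through a small set of recurring
structural features that this module detects from coordinates alone:

* **pocket insertion** — near-complete burial of the client's anchor F/L side
  chain on complex formation, measured as the side-chain solvent-accessible
  surface area (SASA) lost between the client chain alone and the complex,
  relative to a Gly-X-Gly maximal-exposure reference;
* **salt bridges** — Arg/Lys side-chain nitrogens within cutoff of Asp/Glu
  carboxylate oxygens (side-chain kind) or of backbone carbonyl oxygens
  (backbone-oxygen kind), e.g. a client aspartate pairing with a conserved
  arginine beside the pocket;
* **inter-chain antiparallel beta-pairing** — a client strand completing a
  beta-sheet with a strand of the Miro GTPase1 domain, detected by a
  geometric backbone H-bond criterion rather than a DSSP energy;
* **surface annotations** — Kyte-Doolittle hydrophobicity, per-residue model
  confidence (pLDDT read from the B-factor field, AlphaFold convention), and
  an optional conservation overlay.

SASA is computed with a Shrake-Rupley sphere-sampling algorithm implemented
here (packaged van der Waals radii, configurable probe radius and sphere
point count).  All detectors operate on author residue numbering so that
reports read like the structural literature (R263, F2989, ...).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
from matplotlib.path import Path as MplPath
from scipy.spatial import cKDTree

from .geometry import GeoResidue, dihedral

# ---------------------------------------------------------------------------
# packaged tables

#: Bondi van der Waals radii (angstroms) by element symbol.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_RADIUS = 1.70
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

#: Kyte-Doolittle hydropathy scale (1-letter keyed below via 3-letter codes).
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

#: Maximal side-chain solvent accessibility (angstrom^2) of residue X in an
#: extended Gly-X-Gly tripeptide (Miller et al. 1987).  Glycine has no side
#: chain and is handled via a C-alpha proxy.
GXG_SIDECHAIN_MAX = {
    "ALA": 67.0, "ARG": 196.0, "ASN": 113.0, "ASP": 106.0, "CYS": 104.0,
    "GLN": 144.0, "GLU": 138.0, "HIS": 151.0, "ILE": 140.0, "LEU": 137.0,
    "LYS": 167.0, "MET": 160.0, "PHE": 175.0, "PRO": 105.0, "SER": 80.0,
    "THR": 102.0, "TRP": 217.0, "TYR": 187.0, "VAL": 117.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

DEFAULT_SALT_BRIDGE_CUTOFF = 4.0   # angstrom, N-O
DEFAULT_HBOND_CUTOFF = 3.5         # angstrom, backbone N...O
DEFAULT_CA_CUTOFF = 5.5            # angstrom, paired-residue C-alpha separation
DEFAULT_MIN_PAIR_LENGTH = 2
DEFAULT_INSERTION_THRESHOLD = 0.7  # relative side-chain burial => "inserted"
DEFAULT_PLDDT_THRESHOLD = 70.0
DEFAULT_CONTACT_DISTANCE = 5.0     # heavy-atom distance defining interface residues

_BASIC_SIDECHAIN_N = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",)}
_ACIDIC_SIDECHAIN_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


# ---------------------------------------------------------------------------
# model container

@dataclass
class AtomRecord:
    chain: str
    res_seq: int
    res_name: str
    atom_name: str
    element: str
    xyz: np.ndarray
    confidence: float = 0.0
    flagged: bool = False  # e.g. all-zero coordinates

    @property
    def key(self) -> tuple:
        return (self.chain, self.res_seq, self.atom_name)


class Residue:
    """Atoms of one residue, addressable by atom name."""

    def __init__(self, chain: str, res_seq: int, res_name: str):
        self.chain = chain
        self.res_seq = res_seq
        self.res_name = res_name
        self.atoms: dict[str, AtomRecord] = {}

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.res_seq)

    @property
    def confidence(self) -> float:
        return float(np.mean([a.confidence for a in self.atoms.values()]))

    def coord(self, name: str) -> Optional[np.ndarray]:
        a = self.atoms.get(name)
        return None if a is None else a.xyz

    def sidechain_atoms(self) -> list[AtomRecord]:
        side = [a for a in self.atoms.values() if a.atom_name not in BACKBONE_ATOMS
                and a.element != "H"]
        if side:
            return side
        ca = self.atoms.get("CA")  # glycine / C-alpha proxy
        return [ca] if ca is not None else []


class StructureModel:
    """Chains of residues of atoms, author numbering preserved."""

    def __init__(self, atoms: Iterable[AtomRecord]):
        self._residues: dict[tuple[str, int], Residue] = {}
        self._chain_order: list[str] = []
        for atom in atoms:
            key = (atom.chain, atom.res_seq)
            if key not in self._residues:
                self._residues[key] = Residue(atom.chain, atom.res_seq, atom.res_name)
            self._residues[key].atoms[atom.atom_name] = atom
            if atom.chain not in self._chain_order:
                self._chain_order.append(atom.chain)
        if not self._chain_order:
            raise ValueError("structure model has no atoms")

    @property
    def chains(self) -> list[str]:
        return list(self._chain_order)

    def residues(self, chain: Optional[str] = None) -> list[Residue]:
        res = [r for r in self._residues.values() if chain is None or r.chain == chain]
        return sorted(res, key=lambda r: (self._chain_order.index(r.chain), r.res_seq))

    def residue(self, chain: str, res_seq: int) -> Residue:
        try:
            return self._residues[(chain, res_seq)]
        except KeyError:
            raise KeyError(f"no residue {res_seq} in chain {chain!r}") from None

    def atoms(self, chains: Optional[set[str]] = None) -> list[AtomRecord]:
        out = []
        for r in self.residues():
            if chains is None or r.chain in chains:
                out.extend(r.atoms.values())
        return out

    def sequence(self, chain: str) -> str:
        return "".join(THREE_TO_ONE.get(r.res_name, "X") for r in self.residues(chain))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        atoms = []
        for a in self.atoms():
            atoms.append(AtomRecord(a.chain, a.res_seq, a.res_name, a.atom_name,
                                    a.element, rotation @ a.xyz + translation,
                                    a.confidence, a.flagged))
        return StructureModel(atoms)


def parse_structure(path: str | Path) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    Waters and non-polymer hetero compounds are dropped; for alternate
    locations the highest-occupancy conformer is kept.  Per-residue model
    confidence is read from the B-factor column (AlphaFold convention).
    Atoms with all-zero coordinates are kept but flagged.
    """
    path = str(path)
    try:
        st = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path!r}: {exc}") from exc
    st.setup_entities()
    st.remove_alternative_conformations()  # keeps highest occupancy
    if not st:
        raise ValueError(f"no models in structure file {path!r}")
    model = st[0]
    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is not None and not info.is_amino_acid():
                continue
            for atom in res:
                if atom.is_hydrogen():
                    continue
                xyz = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                atoms.append(AtomRecord(
                    chain=chain.name,
                    res_seq=res.seqid.num,
                    res_name=res.name,
                    atom_name=atom.name,
                    element=atom.element.name.upper(),
                    xyz=xyz,
                    confidence=float(atom.b_iso),
                    flagged=bool(np.all(xyz == 0.0)),
                ))
    if not atoms:
        raise ValueError(f"no protein atoms found in {path!r}")
    return StructureModel(atoms)


def model_from_geometry(chains: dict[str, list[GeoResidue]]) -> StructureModel:
    """Assemble a StructureModel directly from idealized geometry chains."""
    atoms = []
    for chain_id, residues in chains.items():
        for res in residues:
            for atom_name, xyz in res.atoms.items():
                atoms.append(AtomRecord(
                    chain=chain_id, res_seq=res.seq, res_name=res.name,
                    atom_name=atom_name, element=atom_name[0],
                    xyz=np.asarray(xyz, dtype=float), confidence=res.confidence,
                ))
    return StructureModel(atoms)


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)

def _sphere_points(n: int) -> np.ndarray:
    """n roughly uniform unit-sphere points (golden-spiral / Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def atom_radius(element: str) -> float:
    r = VDW_RADII.get(element.upper())
    if r is None:
        warnings.warn(f"unknown element {element!r}; using default radius "
                      f"{DEFAULT_RADIUS} A", stacklevel=2)
        return DEFAULT_RADIUS
    return r


def sasa(model: StructureModel, subset: Optional[set[str]] = None,
         probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_N_POINTS,
         ) -> dict[tuple, float]:
    """Per-atom solvent-accessible surface areas (angstrom^2).

    Shrake-Rupley sphere sampling: each atom's solvent-expanded sphere
    (vdW radius + probe) is sampled at ``n_points`` quasi-uniform points and
    the accessible fraction is the fraction of points outside every other
    atom's expanded sphere.  ``subset`` restricts the computation to the
    named chains (atoms outside the subset do not occlude).
    """
    atoms = model.atoms(subset)
    if not atoms:
        raise ValueError("no atoms selected for SASA")
    coords = np.array([a.xyz for a in atoms])
    radii = np.array([atom_radius(a.element) + probe for a in atoms])
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas: dict[tuple, float] = {}
    for i, atom in enumerate(atoms):
        pts = coords[i] + radii[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        areas[atom.key] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return areas


@dataclass
class BurialResult:
    """Side-chain burial of one client residue on complex formation."""

    chain: str
    res_seq: int
    res_name: str
    sasa_isolated: float
    sasa_complex: float
    relative_burial: float
    inserted: bool
    ca_proxy: bool = False  # glycine (or side-chain-less) residue, C-alpha used


def delta_sasa_insertion(model: StructureModel, client_chain: str,
                         receptor_chain: str, res_seq: int,
                         insertion_threshold: float = DEFAULT_INSERTION_THRESHOLD,
                         probe: float = DEFAULT_PROBE,
                         n_points: int = DEFAULT_N_POINTS) -> BurialResult:
    """Quantify how deeply a client residue's side chain buries into the receptor.

    The side-chain SASA is computed for the client chain alone and for the
    client+receptor complex; the difference, normalized by the residue's
    maximal (Gly-X-Gly extended tripeptide) side-chain exposure, is the
    relative burial.  ``inserted`` is true at or above the insertion
    threshold -- the operational definition of an anchor residue "inserting"
    into the ELF pocket.
    """
    residue = model.residue(client_chain, res_seq)
    side = residue.sidechain_atoms()
    if not side:
        raise ValueError(f"residue {client_chain}/{res_seq} has no usable atoms")
    ca_proxy = all(a.atom_name == "CA" for a in side)
    side_keys = {a.key for a in side}

    iso = sasa(model, subset={client_chain}, probe=probe, n_points=n_points)
    chains_present = set(model.chains)
    both = {client_chain, receptor_chain} & chains_present
    cpx = sasa(model, subset=both, probe=probe, n_points=n_points)

    sasa_iso = sum(iso[k] for k in side_keys)
    sasa_cpx = sum(cpx[k] for k in side_keys)
    if ca_proxy:
        reference = max(sasa_iso, 1e-9)
        warnings.warn(
            f"residue {residue.res_name} {client_chain}/{res_seq} has no side chain; "
            "using C-alpha exposure as proxy", stacklevel=2)
    else:
        reference = GXG_SIDECHAIN_MAX.get(residue.res_name, max(sasa_iso, 1e-9))
    rel = float(np.clip((sasa_iso - sasa_cpx) / reference, 0.0, 1.0))
    return BurialResult(
        chain=client_chain, res_seq=res_seq, res_name=residue.res_name,
        sasa_isolated=sasa_iso, sasa_complex=sasa_cpx, relative_burial=rel,
        inserted=rel >= insertion_threshold, ca_proxy=ca_proxy,
    )


# ---------------------------------------------------------------------------
# salt bridges

@dataclass
class SaltBridge:
    basic: tuple[str, int, str]            # (chain, res_seq, res_name)
    basic_atom: str
    partner: tuple[str, int, str]
    partner_atom: str
    kind: str                              # "side-chain" | "backbone-oxygen"
    min_distance: float


def detect_salt_bridges(model: StructureModel, chain_a: str, chain_b: str,
                        cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
                        include_histidine: bool = False) -> list[SaltBridge]:
    """Inter-chain salt bridges between Arg/Lys nitrogens and acceptor oxygens.

    Side-chain kind: guanidinium/ammonium N within ``cutoff`` of an Asp/Glu
    carboxylate O on the other chain.  Backbone-oxygen kind: the same N
    within cutoff of a backbone carbonyl O -- the "partial" bridges an
    arginine can make with a client's backbone.  One bridge is reported per
    (basic residue, partner residue, kind) with the minimal N-O distance.
    Symmetric in chain order.  Histidine is excluded from the basic set by
    default (protonation state unknown in a predicted model).
    """
    basic_map = dict(_BASIC_SIDECHAIN_N)
    if include_histidine:
        basic_map["HIS"] = ("ND1", "NE2")
    bridges: dict[tuple, SaltBridge] = {}
    for basic_chain, other_chain in ((chain_a, chain_b), (chain_b, chain_a)):
        for res in model.residues(basic_chain):
            n_atoms = [res.atoms[n] for n in basic_map.get(res.res_name, ())
                       if n in res.atoms]
            if not n_atoms:
                continue
            for other in model.residues(other_chain):
                # side-chain carboxylate oxygens
                for kind, names in (
                    ("side-chain", _ACIDIC_SIDECHAIN_O.get(other.res_name, ())),
                    ("backbone-oxygen", ("O",)),
                ):
                    best = None
                    for nm in names:
                        o = other.atoms.get(nm)
                        if o is None:
                            continue
                        for na in n_atoms:
                            d = float(np.linalg.norm(na.xyz - o.xyz))
                            if d <= cutoff and (best is None or d < best[0]):
                                best = (d, na.atom_name, o.atom_name)
                    if best is None:
                        continue
                    key = (res.key, other.key, kind)
                    if key not in bridges or best[0] < bridges[key].min_distance:
                        bridges[key] = SaltBridge(
                            basic=(res.chain, res.res_seq, res.res_name),
                            basic_atom=best[1],
                            partner=(other.chain, other.res_seq, other.res_name),
                            partner_atom=best[2],
                            kind=kind,
                            min_distance=best[0],
                        )
    return sorted(bridges.values(),
                  key=lambda b: (b.basic[0], b.basic[1], b.partner[1], b.kind))


# ---------------------------------------------------------------------------
# inter-chain beta pairing

@dataclass
class BetaPairing:
    strand_a: list[tuple[str, int]]
    strand_b: list[tuple[str, int]]
    orientation: str                        # "antiparallel" | "parallel"
    registry: list[tuple[tuple[str, int], tuple[str, int]]]
    n_hbonds: int


def _hbond(donor_res: Residue, acceptor_res: Residue, cutoff: float) -> bool:
    """Backbone N(donor)...O=C(acceptor) geometric hydrogen bond."""
    n = donor_res.coord("N")
    o = acceptor_res.coord("O")
    c = acceptor_res.coord("C")
    if n is None or o is None or c is None:
        return False
    if np.linalg.norm(n - o) > cutoff:
        return False
    # angular check: N must approach the carbonyl O away from the C=O bond
    v1 = c - o
    v2 = n - o
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 90.0


def detect_interchain_beta_pairs(model: StructureModel, chain_a: str, chain_b: str,
                                 hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
                                 ca_cutoff: float = DEFAULT_CA_CUTOFF,
                                 min_pair_length: int = DEFAULT_MIN_PAIR_LENGTH,
                                 ) -> list[BetaPairing]:
    """Beta-ladder pairings between two chains from backbone geometry.

    Candidate paired residues must have C-alpha atoms within ``ca_cutoff``
    and extend in an uninterrupted register (i+1 pairs with j-1 for
    antiparallel, j+1 for parallel).  Each ladder must be supported by
    backbone N...O hydrogen bonds (distance + angular criterion) on at least
    half of its rungs -- in a beta-ladder H-bonded and non-H-bonded rungs
    alternate.  Residues lacking backbone atoms are skipped with a warning.
    Orientation is confirmed by the strand direction vectors (negative dot
    product => antiparallel).
    """
    if chain_a == chain_b:
        return []  # inter-chain only by contract
    res_a = _with_backbone(model.residues(chain_a))
    res_b = _with_backbone(model.residues(chain_b))
    if not res_a or not res_b:
        return []
    ca_a = np.array([r.coord("CA") for r in res_a])
    ca_b = np.array([r.coord("CA") for r in res_b])
    dist = np.linalg.norm(ca_a[:, None, :] - ca_b[None, :, :], axis=2)
    candidate = {(i, j) for i in range(len(res_a)) for j in range(len(res_b))
                 if dist[i, j] <= ca_cutoff}

    runs: list[tuple[list, str, int, int]] = []  # (run, orientation, n_hb, n_strong)
    for direction, orientation in ((-1, "antiparallel"), (1, "parallel")):
        for (i, j) in sorted(candidate):
            # only start at the beginning of a maximal run along this diagonal
            if (i - 1, j - direction) in candidate:
                continue
            run = []
            k = 0
            while (i + k, j + direction * k) in candidate:
                run.append((i + k, j + direction * k))
                k += 1
            if len(run) < min_pair_length:
                continue
            fwd = [_hbond(res_a[ii], res_b[jj], hbond_cutoff) for ii, jj in run]
            rev = [_hbond(res_b[jj], res_a[ii], hbond_cutoff) for ii, jj in run]
            n_hb = sum(f or r for f, r in zip(fwd, rev))
            # rungs H-bonded in both directions mark directly-opposite pairs;
            # they disambiguate the true registry from its offset diagonals
            n_strong = sum(f and r for f, r in zip(fwd, rev))
            if n_hb < max(1, len(run) // 2):
                continue
            # confirm orientation with strand direction vectors
            ii0, jj0 = run[0]
            ii1, jj1 = run[-1]
            if len(run) > 1:
                # strand direction vectors follow increasing residue index
                va = res_a[ii1].coord("CA") - res_a[ii0].coord("CA")
                vb = res_b[max(jj0, jj1)].coord("CA") - res_b[min(jj0, jj1)].coord("CA")
                dot = float(np.dot(va, vb))
                if (dot < 0) != (orientation == "antiparallel"):
                    continue
            runs.append((run, orientation, n_hb, n_strong))

    # greedy selection: best-supported registry first, overlapping diagonals
    # of the same physical ladder are suppressed
    runs.sort(key=lambda r: (-r[3], -len(r[0]), -r[2], r[0][0]))
    ladders: list[BetaPairing] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for run, orientation, n_hb, _ in runs:
        if any(ii in used_a or jj in used_b for ii, jj in run):
            continue
        used_a.update(ii for ii, _ in run)
        used_b.update(jj for _, jj in run)
        ladders.append(BetaPairing(
            strand_a=[res_a[ii].key for ii, _ in run],
            strand_b=[res_b[jj].key for _, jj in run],
            orientation=orientation,
            registry=[(res_a[ii].key, res_b[jj].key) for ii, jj in run],
            n_hbonds=n_hb,
        ))
    ladders.sort(key=lambda l: l.registry[0])
    return ladders


def _with_backbone(residues: list[Residue]) -> list[Residue]:
    kept = []
    for r in residues:
        if all(n in r.atoms for n in ("N", "CA", "C", "O")):
            kept.append(r)
        else:
            warnings.warn(f"residue {r.chain}/{r.res_seq} lacks backbone atoms; "
                          "skipped in beta-pairing detection", stacklevel=3)
    return kept


# ---------------------------------------------------------------------------
# surface annotations

def hydrophobicity_map(model: StructureModel, chain: str) -> dict[int, float]:
    """Kyte-Doolittle hydropathy per residue of a chain (author numbering)."""
    out = {}
    for res in model.residues(chain):
        value = KYTE_DOOLITTLE.get(res.res_name)
        if value is None:
            warnings.warn(f"non-standard residue {res.res_name} at {chain}/"
                          f"{res.res_seq}; hydropathy set to 0", stacklevel=2)
            value = 0.0
        out[res.res_seq] = value
    return out


# ---------------------------------------------------------------------------
# Ramachandran classification

_RAMA_CLASSES = ("general", "glycine", "proline", "pre-proline")


def _load_rama_regions() -> dict:
    with resources.files("elfscan.data").joinpath("rama_regions.json").open() as fh:
        raw = json.load(fh)
    return {
        cls: {level: [MplPath(np.asarray(poly, dtype=float)) for poly in polys]
              for level, polys in regions.items()}
        for cls, regions in raw.items() if not cls.startswith("_")
    }


_RAMA_REGIONS: Optional[dict] = None


def ramachandran_class(phi: float, psi: float, residue_class: str = "general") -> str:
    """Classify a (phi, psi) pair as favored, allowed or outlier.

    Region boundaries are packaged polygonal approximations of published
    torsion-density contours, with separate maps for general residues,
    glycine (whose missing side chain opens otherwise forbidden regions),
    proline and pre-proline.  Angles are normalized into (-180, 180].
    """
    global _RAMA_REGIONS
    if _RAMA_REGIONS is None:
        _RAMA_REGIONS = _load_rama_regions()
    if residue_class not in _RAMA_CLASSES:
        raise ValueError(f"residue_class must be one of {_RAMA_CLASSES}")
    phi = _wrap_angle(phi)
    psi = _wrap_angle(psi)
    regions = _RAMA_REGIONS[residue_class]
    point = (phi, psi)
    for level in ("favored", "allowed"):
        if any(poly.contains_point(point) for poly in regions[level]):
            return level
    return "outlier"


def _wrap_angle(a: float) -> float:
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def backbone_dihedrals(model: StructureModel, chain: str) -> dict[int, tuple]:
    """(phi, psi) per residue of a chain; None where a neighbour is missing."""
    residues = model.residues(chain)
    out: dict[int, tuple] = {}
    for k, res in enumerate(residues):
        phi = psi = None
        n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
        if k > 0 and residues[k - 1].res_seq == res.res_seq - 1:
            c_prev = residues[k - 1].coord("C")
            if all(v is not None for v in (c_prev, n, ca, c)):
                phi = dihedral(c_prev, n, ca, c)
        if k + 1 < len(residues) and residues[k + 1].res_seq == res.res_seq + 1:
            n_next = residues[k + 1].coord("N")
            if all(v is not None for v in (n, ca, c, n_next)):
                psi = dihedral(n, ca, c, n_next)
        out[res.res_seq] = (phi, psi)
    return out


# ---------------------------------------------------------------------------
# aggregated report

@dataclass
class InterfaceReport:
    client_chain: str
    receptor_chain: str
    burials: list[BurialResult]
    salt_bridges: list[SaltBridge]
    beta_pairings: list[BetaPairing]
    low_confidence_flags: list[tuple[str, int]]
    hydrophobicity: dict[int, float]
    conservation: Optional[dict[int, float]] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        for burial in d["burials"]:
            for k, v in burial.items():
                if isinstance(v, (np.floating, np.bool_)):
                    burial[k] = v.item()
        return d

    def to_json(self, path: Optional[str | Path] = None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=_jsonify, **kwargs)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def interface_report(model: StructureModel, client_chain: str, receptor_chain: str,
                     conservation: Optional[Sequence[float]] = None,
                     contact_distance: float = DEFAULT_CONTACT_DISTANCE,
                     plddt_threshold: float = DEFAULT_PLDDT_THRESHOLD,
                     insertion_threshold: float = DEFAULT_INSERTION_THRESHOLD,
                     salt_bridge_cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
                     n_points: int = DEFAULT_N_POINTS) -> InterfaceReport:
    """Full interface feature report for a client/receptor chain pair.

    Burial is evaluated for every client residue with a heavy atom within
    ``contact_distance`` of the receptor.  ``conservation``, when given, is a
    per-residue score track indexed by the receptor's author residue numbers
    (1-based); receptor interface residues outside the track are left
    unannotated.
    """
    for ch in (client_chain, receptor_chain):
        if ch not in model.chains:
            raise ValueError(f"chain {ch!r} not present in model (has {model.chains})")

    rec_atoms = model.atoms({receptor_chain})
    tree = cKDTree(np.array([a.xyz for a in rec_atoms]))
    contact_res: list[int] = []
    for res in model.residues(client_chain):
        pts = np.array([a.xyz for a in res.atoms.values()])
        if tree.query_ball_point(pts, contact_distance, return_length=True).sum() > 0:
            contact_res.append(res.res_seq)

    burials = [
        delta_sasa_insertion(model, client_chain, receptor_chain, rs,
                             insertion_threshold=insertion_threshold,
                             n_points=n_points)
        for rs in contact_res
    ]
    bridges = detect_salt_bridges(model, client_chain, receptor_chain,
                                  cutoff=salt_bridge_cutoff)
    pairings = detect_interchain_beta_pairs(model, client_chain, receptor_chain)

    low_conf = [
        (res.chain, res.res_seq)
        for ch in (client_chain, receptor_chain)
        for res in model.residues(ch)
        if res.confidence < plddt_threshold
    ]
    cons_map = None
    if conservation is not None:
        cons_map = {}
        for res in model.residues(receptor_chain):
            if 1 <= res.res_seq <= len(conservation):
                cons_map[res.res_seq] = float(conservation[res.res_seq - 1])
    return InterfaceReport(
        client_chain=client_chain,
        receptor_chain=receptor_chain,
        burials=burials,
        salt_bridges=bridges,
        beta_pairings=pairings,
        low_confidence_flags=low_conf,
        hydrophobicity=hydrophobicity_map(model, receptor_chain),
        conservation=cons_map,
    )
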