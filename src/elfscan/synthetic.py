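"""Ground-truthed synthetic inputs for every pipeline stage.

Real inputs to this pipeline are large or non-redistributable: a curated
mitochondrial proteome inventory, MUSCLE alignments of ~1000 homologs,
AlphaFold multimer models, spinning-disk microscopy stacks and plate-reader
tables.  Each generator here emulates the *properties the pipeline consumes*
(planted motifs, controlled per-column conservation, posed interface
features, known enrichment factors and plate effects) while recording the
ground truth, so every detector and statistic can be validated exactly.

All generators are pure functions of their parameters and an explicit seed:
re-running with the same arguments reproduces byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation
import tifffile

from . import geometry as geo
from .conservation import Alignment
from .imaging import ImageChannel, RegionMask
from .motif import ProteinRecord
from .structure import StructureModel, model_from_geometry
from .y2h import PlateTable, Well

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Swiss-Prot-like amino-acid frequencies (optional decoy background).
SWISSPROT_FREQS = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0661, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0687,
}


@dataclass
class GroundTruth:
    """What a generator planted, sufficient to re-derive the expected output."""

    generator: str
    seed: int
    planted: dict

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(asdict(self), indent=2, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# proteomes with planted motifs

def gen_proteome(n_proteins: int = 100, motif_literal: str = "FADI",
                 n_planted: int = 5, seed: int = 0,
                 length_range: tuple[int, int] = (150, 600),
                 background: str = "uniform",
                 ) -> tuple[list[ProteinRecord], GroundTruth]:
    """Decoy proteome with the motif literal planted in a known protein subset.

    Decoy sequences are drawn i.i.d. from the background residue distribution
    and resampled until free of the literal, so a scan's false-positive decoys
    are guaranteed motif-free.  Planted proteins carry the literal at one
    recorded position each.
    """
    if n_planted > n_proteins:
        raise ValueError("cannot plant more motifs than proteins")
    if background == "uniform":
        probs = np.full(20, 1.0 / 20)
    elif background == "swissprot":
        probs = np.array([SWISSPROT_FREQS[a] for a in _ALPHABET])
        probs = probs / probs.sum()
    else:
        raise ValueError(f"unknown background {background!r}")
    if any(a not in _ALPHABET for a in motif_literal):
        raise ValueError("motif literal must use standard residues")

    rng = np.random.default_rng(seed)
    planted_idx = sorted(rng.choice(n_proteins, size=n_planted, replace=False))
    planted_set = set(int(i) for i in planted_idx)
    records: list[ProteinRecord] = []
    positions: dict[str, int] = {}
    for i in range(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        for _ in range(1000):
            seq = "".join(rng.choice(list(_ALPHABET), size=length, p=probs))
            if motif_literal not in seq:
                break
        else:  # pragma: no cover - astronomically unlikely for real literals
            raise RuntimeError("could not sample a motif-free decoy sequence")
        pid = f"SYN{i:04d}"
        if i in planted_set:
            pos = int(rng.integers(0, length - len(motif_literal) + 1))
            seq = seq[:pos] + motif_literal + seq[pos + len(motif_literal):]
            # splice must not create a second occurrence elsewhere
            while seq.count(motif_literal) != 1:
                pos = int(rng.integers(0, length - len(motif_literal) + 1))
                base = "".join(rng.choice(list(_ALPHABET), size=length, p=probs))
                if motif_literal in base:
                    continue
                seq = base[:pos] + motif_literal + base[pos + len(motif_literal):]
            positions[pid] = pos + 1  # 1-based anchor
        records.append(ProteinRecord(pid, seq))
    truth = GroundTruth(
        generator="gen_proteome", seed=seed,
        planted={"motif_literal": motif_literal, "positions": positions,
                 "n_proteins": n_proteins, "background": background},
    )
    return records, truth


def write_fasta(records: Sequence[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for k in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[k:k + width] + "\n")


# ---------------------------------------------------------------------------
# MSAs with controlled conservation

def gen_msa(ref_seq: str, n_rows: int = 50,
            per_column_rate: float | Sequence[float] = 0.1,
            seed: int = 0, reference_id: str = "REF",
            ) -> tuple[Alignment, GroundTruth]:
    """MSA whose rows are the reference with per-column i.i.d. substitutions.

    At a substituted position the residue is redrawn uniformly over all 20
    letters (so a rate-1 column is background-like and scores ~0, and higher
    rates strictly dilute the reference letter).  No indels are introduced.
    """
    ncol = len(ref_seq)
    rates = np.broadcast_to(np.asarray(per_column_rate, dtype=float), (ncol,)).copy()
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("per-column rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    letters = np.array(list(_ALPHABET))
    rows = [(reference_id, ref_seq)]
    ref_arr = np.array(list(ref_seq))
    for r in range(n_rows):
        mutate = rng.random(ncol) < rates
        seq = ref_arr.copy()
        seq[mutate] = letters[rng.integers(0, 20, size=int(mutate.sum()))]
        rows.append((f"HOMOLOG{r:04d}", "".join(seq)))
    truth = GroundTruth(
        generator="gen_msa", seed=seed,
        planted={"per_column_rate": rates.tolist(), "n_rows": n_rows,
                 "reference_id": reference_id},
    )
    return Alignment(rows=rows, reference_id=reference_id), truth


# ---------------------------------------------------------------------------
# complex fixtures with posed interface features

@dataclass
class ComplexFixture:
    model: StructureModel
    truth: GroundTruth
    chains: dict  # chain id -> list[GeoResidue], for re-posing / writing


def _align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking direction a onto direction b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return Rotation.from_rotvec(np.pi * perp / np.linalg.norm(perp)).as_matrix()
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1 / (1 + c))


def _pose_salt_bridge(n_o_distance: float, receptor_start: int, client_start: int,
                      offset: np.ndarray, backbone_kind: bool = False,
                      ) -> tuple[list, list, dict]:
    """Pose an Arg (receptor) against an Asp side chain or a backbone O (client)."""
    rec = geo.build_chain(["GLY", "ARG", "GLY"],
                          [geo.EXTENDED_PHI_PSI] * 3, start_seq=receptor_start)
    arg = rec[1]
    nh1 = arg.atoms["NH1"]
    out_dir = nh1 - arg.atoms["CZ"]
    out_dir /= np.linalg.norm(out_dir)
    target = nh1 + n_o_distance * out_dir

    if backbone_kind:
        cli = geo.build_chain(["GLY", "GLY", "GLY"],
                              [geo.EXTENDED_PHI_PSI] * 3, start_seq=client_start)
        o_atom = "O"
        anchor_res = cli[1]
        # approach along the carbonyl axis: C=O points toward the arginine
        bond_dir = anchor_res.atoms["O"] - anchor_res.atoms["C"]
    else:
        cli = geo.build_chain(["GLY", "ASP", "GLY"],
                              [geo.EXTENDED_PHI_PSI] * 3, start_seq=client_start)
        o_atom = "OD1"
        anchor_res = cli[1]
        bond_dir = anchor_res.atoms["OD1"] - anchor_res.atoms["CG"]
    rot = _align_rotation(bond_dir, -out_dir)
    cli = geo.transform(cli, rot, np.zeros(3))
    anchor_pos = cli[1].atoms[o_atom]
    cli = geo.transform(cli, np.eye(3), target - anchor_pos)
    rec = geo.transform(rec, np.eye(3), offset)
    cli = geo.transform(cli, np.eye(3), offset)
    truth = {
        "basic": receptor_start + 1,
        "partner": client_start + 1,
        "kind": "backbone-oxygen" if backbone_kind else "side-chain",
        "distance": n_o_distance,
    }
    return rec, cli, truth


def _pose_beta_ladder(length: int, receptor_start: int, client_start: int,
                      offset: np.ndarray) -> tuple[list, list, dict]:
    """Two beta-strands posed as an antiparallel ladder with real H-bond geometry.

    The client strand is flipped 180 degrees and its rigid-body placement is
    refined so that the H-bonded rungs reach ~2.9 A N...O distances and all
    paired C-alphas sit near 5 A -- the geometry of a textbook antiparallel
    sheet, not the detector's acceptance thresholds.
    """
    phi_psi = [geo.BETA_PHI_PSI] * length
    names = ["VAL" if k % 2 else "ALA" for k in range(length)]
    names = [n if n in geo.SIDE_CHAINS else "ALA" for n in names]
    rec = geo.build_chain(names, phi_psi, start_seq=receptor_start)
    cli0 = geo.build_chain(names, phi_psi, start_seq=client_start)

    strand_dir = rec[-1].atoms["CA"] - rec[0].atoms["CA"]
    strand_dir /= np.linalg.norm(strand_dir)
    flip = Rotation.from_rotvec(np.pi * np.array([0.0, 0.0, 1.0])).as_matrix()

    registry = [(i, length - 1 - i) for i in range(length)]
    hb_rungs = registry[::2]  # alternate rungs carry the two H-bonds each

    def place(params: np.ndarray) -> list:
        rot = Rotation.from_rotvec(params[:3]).as_matrix() @ flip
        return geo.transform(cli0, rot, params[3:])

    def cost(params: np.ndarray) -> float:
        cli = place(params)
        c = 0.0
        for i, j in hb_rungs:
            c += (np.linalg.norm(rec[i].atoms["N"] - cli[j].atoms["O"]) - 2.9) ** 2
            c += (np.linalg.norm(rec[i].atoms["O"] - cli[j].atoms["N"]) - 2.9) ** 2
        for i, j in registry:
            c += 0.2 * (np.linalg.norm(rec[i].atoms["CA"] - cli[j].atoms["CA"]) - 5.0) ** 2
        return c

    x0 = np.concatenate([np.zeros(3), rec[0].atoms["CA"] - cli0[-1].atoms["CA"]
                         + 4.8 * np.array([0.0, 1.0, 0.0])])
    best = minimize(cost, x0, method="Nelder-Mead",
                    options={"maxiter": 4000, "xatol": 1e-4, "fatol": 1e-6})
    cli = place(best.x)
    rec = geo.transform(rec, np.eye(3), offset)
    cli = geo.transform(cli, np.eye(3), offset)
    truth = {
        "registry": [(receptor_start + i, client_start + j) for i, j in registry],
        "orientation": "antiparallel",
    }
    return rec, cli, truth


def _pose_insertion(receptor_start: int, client_start: int, offset: np.ndarray,
                    cage_radius: float = 5.5, n_cage: int = 140,
                    ) -> tuple[list, list, dict]:
    """A Phe side chain enclosed in a spherical cage of receptor carbon atoms.

    Cage atoms are dropped where they would clash with the client backbone,
    leaving the natural opening through which the side chain "enters".
    """
    cli = geo.build_chain(["GLY", "PHE", "GLY"],
                          [geo.EXTENDED_PHI_PSI] * 3, start_seq=client_start)
    phe = cli[1]
    side_names = [n for n in phe.atoms if n not in ("N", "CA", "C", "O")]
    centroid = np.mean([phe.atoms[n] for n in side_names], axis=0)

    i = np.arange(n_cage) + 0.5
    ang = np.arccos(1 - 2 * i / n_cage)
    theta = np.pi * (1 + 5 ** 0.5) * i
    pts = centroid + cage_radius * np.column_stack(
        [np.cos(theta) * np.sin(ang), np.sin(theta) * np.sin(ang), np.cos(ang)])
    backbone = np.array([phe.atoms[n] for n in ("N", "CA", "C", "O")]
                        + [cli[0].atoms[n] for n in ("N", "CA", "C", "O")]
                        + [cli[2].atoms[n] for n in ("N", "CA", "C", "O")])
    keep = [p for p in pts
            if np.min(np.linalg.norm(backbone - p, axis=1)) > 3.4
            and np.min([np.linalg.norm(phe.atoms[n] - p) for n in side_names]) > 3.2]
    cage = geo.GeoResidue(
        name="UNK", seq=receptor_start,
        atoms={f"C{k:03d}": np.asarray(p) for k, p in enumerate(keep)},
    )
    rec = geo.transform([cage], np.eye(3), offset)
    cli = geo.transform(cli, np.eye(3), offset)
    truth = {"inserted": client_start + 1, "res_name": "PHE"}
    return rec, cli, truth


def gen_complex_fixture(features: Sequence[str] = ("salt_bridge", "beta_ladder", "insertion"),
                        seed: int = 0, n_o_distance: float = 3.0,
                        ladder_length: int = 6, plddt: float = 90.0,
                        ) -> ComplexFixture:
    """Two-chain toy complex with the requested features posed far apart.

    ``features`` may include ``salt_bridge``, ``backbone_bridge``,
    ``beta_ladder``, ``insertion``, ``helix_contact`` (two touching
    alpha-helices: a negative control that must yield no beta-pairing) and
    ``separated`` (client segment 20 A from any receptor atom).  Receptor is
    chain A, client chain B.  The whole complex is then rigidly rotated and
    translated by a seed-dependent isometry, so fixtures from different
    seeds differ in pose but not in planted features.
    """
    chain_a: list[geo.GeoResidue] = []
    chain_b: list[geo.GeoResidue] = []
    planted: dict = {"salt_bridges": [], "beta": [], "insertions": []}
    spacing = 40.0
    for k, feat in enumerate(features):
        offset = np.array([spacing * k, 0.0, 0.0])
        ra, rb = 100 * (k + 1), 100 * (k + 1) + 50
        if feat == "salt_bridge":
            rec, cli, t = _pose_salt_bridge(n_o_distance, ra, rb, offset)
            planted["salt_bridges"].append(t)
        elif feat == "backbone_bridge":
            rec, cli, t = _pose_salt_bridge(n_o_distance, ra, rb, offset,
                                            backbone_kind=True)
            planted["salt_bridges"].append(t)
        elif feat == "beta_ladder":
            rec, cli, t = _pose_beta_ladder(ladder_length, ra, rb, offset)
            planted["beta"].append(t)
        elif feat == "insertion":
            rec, cli, t = _pose_insertion(ra, rb, offset)
            planted["insertions"].append(t)
        elif feat == "helix_contact":
            phi_psi = [geo.ALPHA_PHI_PSI] * 10
            rec = geo.build_chain(["ALA"] * 10, phi_psi, start_seq=ra)
            cli = geo.build_chain(["ALA"] * 10, phi_psi, start_seq=rb)
            cli = geo.transform(cli, np.eye(3), np.array([0.0, 9.0, 0.0]))
            rec = geo.transform(rec, np.eye(3), offset)
            cli = geo.transform(cli, np.eye(3), offset)
        elif feat == "separated":
            rec = geo.build_chain(["ALA"] * 5, [geo.EXTENDED_PHI_PSI] * 5, start_seq=ra)
            cli = geo.build_chain(["ALA"] * 5, [geo.EXTENDED_PHI_PSI] * 5, start_seq=rb)
            cli = geo.transform(cli, np.eye(3), np.array([0.0, 25.0, 0.0]))
            rec = geo.transform(rec, np.eye(3), offset)
            cli = geo.transform(cli, np.eye(3), offset)
        else:
            raise ValueError(f"unknown feature {feat!r}")
        chain_a.extend(rec)
        chain_b.extend(cli)

    for res in chain_a + chain_b:
        res.confidence = plddt
    # seed-dependent global pose: planted features are isometry-invariant
    rng = np.random.default_rng(seed)
    rot = geo.random_rotation(rng)
    trans = rng.uniform(-20, 20, size=3)
    chains = {"A": geo.transform(chain_a, rot, trans),
              "B": geo.transform(chain_b, rot, trans)}
    truth = GroundTruth(generator="gen_complex_fixture", seed=seed, planted=planted)
    return ComplexFixture(model=model_from_geometry(chains), truth=truth, chains=chains)


def to_gemmi(chains: dict[str, list[geo.GeoResidue]]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "synthetic complex fixture"
    model = gemmi.Model("1")
    for chain_id, residues in chains.items():
        chain = gemmi.Chain(chain_id)
        for res in residues:
            r = gemmi.Residue()
            r.name = res.name
            r.seqid = gemmi.SeqId(res.seq, " ")
            for atom_name, xyz in res.atoms.items():
                a = gemmi.Atom()
                a.name = atom_name
                a.element = gemmi.Element(atom_name[0])
                a.pos = gemmi.Position(*map(float, xyz))
                a.b_iso = float(res.confidence)
                a.occ = 1.0
                r.add_atom(a)
            chain.add_residue(r)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_fixture(fixture: ComplexFixture, out_dir: str | Path,
                  stem: str = "fixture", formats: Sequence[str] = ("pdb", "cif"),
                  ) -> dict[str, Path]:
    """Write a fixture as PDB and/or mmCIF plus a ground-truth JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    st = to_gemmi(fixture.chains)
    paths = {}
    if "pdb" in formats:
        p = out_dir / f"{stem}.pdb"
        st.write_pdb(str(p))
        paths["pdb"] = p
    if "cif" in formats:
        p = out_dir / f"{stem}.cif"
        doc = st.make_mmcif_document()
        doc.write_file(str(p))
        paths["cif"] = p
    truth_path = out_dir / f"{stem}.truth.json"
    fixture.truth.to_json(truth_path)
    paths["truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# two-channel cell images

def gen_cell_image(shape: tuple[int, int] = (256, 256), enrichment: float = 3.0,
                   punctate_fraction: Optional[float] = None,
                   noise: str = "poisson", pixel_size: float = 0.1,
                   baseline: float = 200.0, seed: int = 0,
                   n_tubules: int = 6, n_puncta: int = 8,
                   ) -> tuple[dict, GroundTruth]:
    """Synthetic two-channel cell: marker structures and a client channel.

    Tubular mode (``punctate_fraction=None``): mitochondria are dilated
    random-walk curves inside an elliptical cell; the client channel is
    ``baseline * enrichment`` on mitochondria and ``baseline`` elsewhere in
    the cell, with optional Poisson shot noise.  The noiseless mitochondrial
    enrichment ratio is exactly ``enrichment``.

    Punctate mode (``punctate_fraction=f``): marker structures are small
    disks (contact-site foci) and the client intensity is apportioned so the
    integrated density inside the puncta is exactly fraction ``f`` of the
    whole-cell total before noise.

    Returns a dict with 'marker', 'client' (ImageChannel), 'mito_mask' /
    'punctum_mask' and 'cell_mask' (RegionMask) plus the ground truth.
    """
    if noise not in ("poisson", "none"):
        raise ValueError("noise must be 'poisson' or 'none'")
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2, w / 2
    cell = ((yy - cy) / (0.45 * h)) ** 2 + ((xx - cx) / (0.45 * w)) ** 2 <= 1.0

    struct = np.zeros(shape, dtype=bool)
    if punctate_fraction is None:
        for _ in range(n_tubules):
            r = rng.uniform(0.25 * h, 0.75 * h)
            c = rng.uniform(0.25 * w, 0.75 * w)
            ang = rng.uniform(0, 2 * np.pi)
            for _step in range(int(0.4 * max(h, w))):
                ang += rng.normal(0, 0.25)
                r += np.sin(ang)
                c += np.cos(ang)
                ri, ci = int(round(r)), int(round(c))
                if not (1 <= ri < h - 1 and 1 <= ci < w - 1):
                    break
                struct[ri - 1:ri + 2, ci - 1:ci + 2] = True
        kind = "mitochondria"
    else:
        if not 0.0 <= punctate_fraction <= 1.0:
            raise ValueError("punctate_fraction must lie in [0, 1]")
        for _ in range(n_puncta):
            r = rng.uniform(0.3 * h, 0.7 * h)
            c = rng.uniform(0.3 * w, 0.7 * w)
            rad = rng.uniform(2.0, 3.5)
            struct |= (yy - r) ** 2 + (xx - c) ** 2 <= rad ** 2
        kind = "punctum"
    struct &= cell
    if not struct.any():  # pragma: no cover - geometrically implausible
        raise RuntimeError("generator produced an empty structure mask")

    client = np.zeros(shape, dtype=float)
    if punctate_fraction is None:
        client[cell] = baseline
        client[struct] = baseline * enrichment
        truth_value = {"enrichment": enrichment}
    else:
        n_on = int(struct.sum())
        n_cell = int(cell.sum())
        total = baseline * n_cell
        client[cell & ~struct] = total * (1 - punctate_fraction) / (n_cell - n_on)
        client[struct] = total * punctate_fraction / n_on
        truth_value = {"punctate_fraction": punctate_fraction}

    marker = np.zeros(shape, dtype=float)
    marker[cell] = 0.1 * baseline
    marker[struct] = 2.0 * baseline
    if noise == "poisson":
        client = rng.poisson(client).astype(float)
        marker = rng.poisson(marker).astype(float)

    images = {
        "marker": ImageChannel(marker, pixel_size),
        "client": ImageChannel(client, pixel_size),
        ("mito_mask" if kind == "mitochondria" else "punctum_mask"):
            RegionMask(struct, kind=kind),
        "cell_mask": RegionMask(cell, kind="cell"),
    }
    truth = GroundTruth(
        generator="gen_cell_image", seed=seed,
        planted=dict(truth_value, noise=noise, baseline=baseline,
                     pixel_size=pixel_size, shape=list(shape)),
    )
    return images, truth


def write_image(images: dict, path: str | Path) -> None:
    """Write marker+client as a 2-page TIFF with resolution tags (um/pixel)."""
    marker, client = images["marker"], images["client"]
    res = 1.0 / marker.pixel_size  # pixels per micron
    tifffile.imwrite(
        str(path),
        np.stack([marker.pixels, client.pixels]).astype(np.float32),
        resolution=(res, res),
    )


# ---------------------------------------------------------------------------
# f-Y2H plates

#: Qualitative charge-swap design: wild-type pair binds strongly, single
#: charge-reversal mutants weaken binding, the double swap restores it.
CHARGE_SWAP_EFFECTS = {
    "WT+WT": 1000.0,
    "RtoD+WT": 120.0,
    "WT+DtoR": 700.0,
    "RtoD+DtoR": 650.0,
}


def gen_plate(effects: Optional[dict[str, float]] = None,
              empty_signal: float = 200.0, noise_sd: float = 0.0,
              n_clones: int = 3, n_empty: int = 3, seed: int = 0,
              ) -> tuple[PlateTable, GroundTruth]:
    """Plate of raw fluorescence wells: empty_signal + effect + Gaussian noise.

    ``effects`` maps sample name to its interaction signal above background;
    default is the charge-swap design preset.  Each sample gets ``n_clones``
    replicate wells (independent clones).
    """
    if effects is None:
        effects = dict(CHARGE_SWAP_EFFECTS)
    rng = np.random.default_rng(seed)
    wells = []
    for k in range(n_empty):
        wells.append(Well("empty", f"e{k + 1}",
                          empty_signal + rng.normal(0, noise_sd), True))
    for sample, effect in effects.items():
        for k in range(n_clones):
            wells.append(Well(sample, f"c{k + 1}",
                              empty_signal + effect + rng.normal(0, noise_sd), False))
    truth = GroundTruth(
        generator="gen_plate", seed=seed,
        planted={"effects": dict(effects), "empty_signal": empty_signal,
                 "noise_sd": noise_sd, "n_clones": n_clones},
    )
    return PlateTable(wells), truth


def write_plate_csv(plate: PlateTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample,clone,raw,is_empty_vector\n")
        for w in plate.wells:
            fh.write(f"{w.sample},{w.clone},{w.raw!r},{int(w.is_empty_vector)}\n")
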