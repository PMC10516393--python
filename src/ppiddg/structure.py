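"""Residue-centric parsing and surface annotation of protein-protein complexes.

A complex is loaded from a PDB file into a list of :class:`ResidueStructure`
objects, each carrying the four backbone heavy atoms (N, CA, C, O) and the
side-chain heavy atoms. Hydrogens are always stripped, alternate locations
are resolved to the highest-occupancy conformer, and glycine (or any residue
arriving without side-chain atoms) receives a virtual C-beta so that every
side-chain-derived feature is defined.

Solvent-accessible surface area uses a deterministic Shrake-Rupley scheme
with a golden-spiral sphere point set and Bondi van der Waals radii, so
results are bit-reproducible across platforms. Interface residues are those
whose per-residue SASA drops by more than a cutoff when their chain is
evaluated inside the complex instead of in isolation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

# common modified residues with an unambiguous standard parent
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO", "SEP": "SER",
    "TPO": "THR", "PTR": "TYR", "CSO": "CYS", "MLY": "LYS", "M3L": "LYS",
}

# Bondi (1964) van der Waals radii, Angstrom
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}
DEFAULT_VDW = 1.70

ATOMIC_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974, "SE": 78.971}
DEFAULT_MASS = 12.011

# Theoretical maximum SASA per residue (Tien et al. 2013), Angstrom^2;
# used to express per-residue SASA on a relative 0-1 scale.
MAX_SASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

CB_BOND_LENGTH = 1.522  # Angstrom, ideal C-alpha to C-beta


class PDBInputError(ValueError):
    """Raised for unusable PDB input (missing chains, unreadable file...)."""


class GeometryError(ValueError):
    """Raised for degenerate geometry (e.g. collinear backbone)."""


@dataclass
class ResidueStructure:
    aa_type: str                 # one-letter code, one of the 20 standard AAs
    chain_id: str
    author_number: str           # PDB residue number incl. insertion code
    backbone_coords: np.ndarray  # (4, 3) in N, CA, C, O order
    sidechain_coords: np.ndarray  # (M, 3), M >= 1
    sidechain_masses: np.ndarray  # (M,)
    sidechain_names: list = field(default_factory=list)

    @property
    def ca(self) -> np.ndarray:
        return self.backbone_coords[1]

    @property
    def cb(self) -> np.ndarray:
        """Real C-beta when present among side-chain atoms, else the first
        side-chain atom (which is the virtual C-beta for glycine)."""
        if "CB" in self.sidechain_names:
            return self.sidechain_coords[self.sidechain_names.index("CB")]
        return self.sidechain_coords[0]


@dataclass
class ComplexStructure:
    residues: list
    chains: list
    name: str = ""
    per_residue_sasa: np.ndarray | None = None
    interface_set: set | None = None

    def __len__(self):
        return len(self.residues)

    def chain_residue_indices(self, chain_id: str) -> list:
        return [i for i, r in enumerate(self.residues) if r.chain_id == chain_id]

    def all_atoms(self):
        """(coords (A,3), radii (A,), residue index (A,)) over every heavy atom."""
        coords, radii, owner = [], [], []
        for i, res in enumerate(self.residues):
            for name, xyz in zip(["N", "CA", "C", "O"], res.backbone_coords):
                coords.append(xyz)
                radii.append(VDW_RADII.get(_element_of(name), DEFAULT_VDW))
                owner.append(i)
            for name, xyz in zip(res.sidechain_names, res.sidechain_coords):
                coords.append(xyz)
                radii.append(VDW_RADII.get(_element_of(name), DEFAULT_VDW))
                owner.append(i)
        return np.asarray(coords), np.asarray(radii), np.asarray(owner, dtype=int)

    def translated(self, shift) -> "ComplexStructure":
        shift = np.asarray(shift, dtype=float)
        return self.transformed(np.eye(3), shift)

    def transformed(self, rotation, shift=(0.0, 0.0, 0.0)) -> "ComplexStructure":
        """Rigidly moved copy: x -> R x + t. Surface annotation is dropped."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(shift, dtype=float)
        new = []
        for r in self.residues:
            new.append(ResidueStructure(
                r.aa_type, r.chain_id, r.author_number,
                r.backbone_coords @ R.T + t,
                r.sidechain_coords @ R.T + t,
                r.sidechain_masses.copy(), list(r.sidechain_names)))
        return ComplexStructure(new, list(self.chains), name=self.name)


def _element_of(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:2].upper() in ("SE",):
        return "SE"
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def place_virtual_cb(backbone_coords: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral C-beta from the N, CA, C backbone frame.

    The C-beta is placed 1.522 A from C-alpha along the tetrahedral direction
    that bisects away from N and C, out of the N-CA-C plane on the side that
    gives standard L-amino-acid chirality. The construction uses only the
    local frame, so it is exactly covariant under rigid motions and follows
    the chirality of the input (a mirrored backbone yields a mirrored CB).
    """
    n, ca, c = (np.asarray(backbone_coords[i], dtype=float) for i in range(3))
    u1 = n - ca
    u2 = c - ca
    n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
    if n1 < 1e-6 or n2 < 1e-6:
        raise GeometryError("backbone atoms coincide; cannot place virtual CB")
    u1, u2 = u1 / n1, u2 / n2
    perp = np.cross(u2, u1)
    p = np.linalg.norm(perp)
    if p < 1e-6:
        raise GeometryError("collinear N-CA-C backbone; cannot place virtual CB")
    bis = u1 + u2
    bis /= np.linalg.norm(bis)
    direction = -np.sqrt(1.0 / 3.0) * bis + np.sqrt(2.0 / 3.0) * perp / p
    return ca + CB_BOND_LENGTH * direction


def read_pdb_complex(path, strict: bool = False, name: str | None = None) -> ComplexStructure:
    """Parse a PDB file into a :class:`ComplexStructure`.

    First MODEL only. Hydrogens (and deuterium) are removed unconditionally.
    Alternate locations resolve to the highest-occupancy atom (ties keep the
    first in file order). Residues missing any of N/CA/C/O are dropped with
    a warning (an error in strict mode); non-standard residues are mapped to
    their parent amino acid when one is defined, otherwise skipped.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("complex", str(path))
    except Exception as exc:  # noqa: BLE001 - surface as a typed parse error
        raise PDBInputError(f"cannot parse PDB file {path}: {exc}") from exc
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise PDBInputError(f"no models in {path}") from None

    residues, chains = [], []
    for chain in model:
        chain_added = False
        for res in chain:
            resname = res.get_resname().strip()
            if resname in NONSTANDARD_PARENT:
                resname = NONSTANDARD_PARENT[resname]
            if resname not in AA3_TO_1:
                if res.id[0].strip() and resname in ("HOH", "WAT"):
                    continue
                if strict and res.id[0] == " ":
                    raise PDBInputError(
                        f"non-standard residue {res.get_resname()} at "
                        f"{chain.id}{res.id[1]} (strict mode)")
                if res.id[0] == " ":
                    logger.warning("skipping non-standard residue %s %s%s",
                                   resname, chain.id, res.id[1])
                continue
            atoms = {}
            for atom in res.get_unpacked_list():
                elem = (atom.element or _element_of(atom.get_name())).upper()
                if elem in ("H", "D"):
                    continue
                key = atom.get_name()
                occ = atom.get_occupancy() or 0.0
                if key not in atoms or occ > atoms[key][1]:
                    if key in atoms and occ == atoms[key][1]:
                        continue  # tie: keep first in file
                    atoms[key] = (atom, occ)
            if not all(k in atoms for k in ("N", "CA", "C", "O")):
                msg = (f"residue {resname} {chain.id}{res.id[1]} lacks a "
                       f"complete N/CA/C/O backbone")
                if strict:
                    raise PDBInputError(msg)
                logger.warning("%s; dropped", msg)
                continue
            backbone = np.array([atoms[k][0].get_coord() for k in ("N", "CA", "C", "O")],
                                dtype=float)
            if not np.isfinite(backbone).all():
                raise PDBInputError(f"non-finite coordinates in {path}")
            sc_names = [k for k in atoms if k not in ("N", "CA", "C", "O", "OXT")]
            if sc_names:
                sc = np.array([atoms[k][0].get_coord() for k in sc_names], dtype=float)
                masses = np.array([ATOMIC_MASS.get(_element_of(k), DEFAULT_MASS)
                                   for k in sc_names])
            else:
                sc = place_virtual_cb(backbone)[None, :]
                masses = np.array([ATOMIC_MASS["C"]])
                sc_names = ["CB"]
            icode = res.id[2].strip()
            residues.append(ResidueStructure(
                AA3_TO_1[resname], chain.id, f"{res.id[1]}{icode}",
                backbone, sc, masses, sc_names))
            chain_added = True
        if chain_added and chain.id not in chains:
            chains.append(chain.id)

    if strict and len(chains) < 2:
        raise PDBInputError(f"{path}: strict mode requires at least 2 chains "
                            f"with standard residues, found {len(chains)}")
    if not residues:
        raise PDBInputError(f"{path}: no standard residues found")
    return ComplexStructure(residues, chains, name=name or str(path))


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + 5.0**0.5) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Right-handed frame tied to the atom cloud (principal axes, signs fixed
    by coordinate skewness). The quadrature sphere is expressed in this
    frame, so a rigid motion of the input rotates the sphere points with it
    and the computed areas are exactly invariant, not merely within
    quadrature jitter."""
    if len(coords) < 2:
        return np.eye(3)
    x = coords - coords.mean(axis=0)
    _, vecs = np.linalg.eigh(x.T @ x)
    proj = x @ vecs
    skew = (proj**3).sum(axis=0)
    signs = np.where(np.abs(skew) > 1e-9, np.sign(skew), 1.0)
    vecs = vecs * signs
    if np.linalg.det(vecs) < 0:
        vecs[:, 0] = -vecs[:, 0]
    return vecs


def _atom_sasa(coords: np.ndarray, radii: np.ndarray, probe: float,
               n_points: int, frame: np.ndarray | None = None) -> np.ndarray:
    """Shrake-Rupley SASA per atom over an arbitrary heavy-atom set.

    A sphere point of atom a is buried iff it lies inside the
    probe-extended sphere of any neighbour (resolved through one large
    point-plane test per neighbour pair). The quadrature sphere is oriented
    in `frame` (default: the canonical frame of the atom cloud), so the
    result is exactly invariant under rigid motions of the input.
    """
    if probe < 0:
        raise ValueError(f"probe radius must be non-negative, got {probe}")
    A = len(coords)
    if frame is None:
        frame = _canonical_frame(coords)
    sphere = golden_spiral_points(n_points) @ frame.T
    ext = radii + probe
    out = 4.0 * np.pi * ext**2
    if A == 1:
        return out
    tree = cKDTree(coords)
    pairs = tree.query_pairs(2.0 * ext.max(), output_type="ndarray")
    if len(pairs) == 0:
        return out
    # both directions: b occludes a's sphere and vice versa
    pairs = np.concatenate([pairs, pairs[:, ::-1]])
    a_idx, b_idx = pairs[:, 0], pairs[:, 1]
    diff = coords[b_idx] - coords[a_idx]
    d = np.linalg.norm(diff, axis=1)
    keep = d < ext[a_idx] + ext[b_idx]
    swallowed = (d < 1e-9) & (ext[b_idx] >= ext[a_idx]) & (a_idx < b_idx)
    out[a_idx[swallowed]] = 0.0  # coincident centre, larger sphere wins
    keep &= d >= 1e-9
    a_idx, b_idx, diff, d = a_idx[keep], b_idx[keep], diff[keep], d[keep]
    if len(a_idx) == 0:
        return out
    # point s of a's probe sphere is inside b's iff s . u_ab > t_ab
    order = np.argsort(a_idx, kind="stable")
    a_idx, b_idx, diff, d = a_idx[order], b_idx[order], diff[order], d[order]
    u = diff / d[:, None]
    t = (d**2 + ext[a_idx] ** 2 - ext[b_idx] ** 2) / (2.0 * ext[a_idx] * d)
    groups, starts = np.unique(a_idx, return_index=True)
    batch = max(1, int(2e7 // n_points))
    for lo_g in range(0, len(groups), batch):
        hi_g = min(len(groups), lo_g + batch)
        lo = starts[lo_g]
        hi = starts[hi_g] if hi_g < len(groups) else len(a_idx)
        buried = (sphere @ u[lo:hi].T) > t[None, lo:hi]   # (n_points, pairs)
        per_group = np.logical_or.reduceat(buried, starts[lo_g:hi_g] - lo,
                                           axis=1)
        acc = n_points - per_group.sum(axis=0)
        out[groups[lo_g:hi_g]] *= acc / n_points
    return out


def compute_sasa(complex_: ComplexStructure, probe: float = 1.4,
                 n_points: int = 960,
                 frame: np.ndarray | None = None) -> np.ndarray:
    """Per-residue SASA (A^2): atom SASA summed over each residue's atoms."""
    if len(complex_) == 0:
        raise ValueError("empty complex")
    coords, radii, owner = complex_.all_atoms()
    atom_area = _atom_sasa(coords, radii, probe, n_points, frame=frame)
    per_res = np.zeros(len(complex_))
    np.add.at(per_res, owner, atom_area)
    return per_res


def detect_interface_residues(complex_: ComplexStructure, cutoff: float = 1.0,
                              probe: float = 1.4, n_points: int = 960) -> set:
    """Residues burying more than `cutoff` A^2 of SASA upon complexation.

    Each chain is evaluated in isolation and inside the full complex; residue
    i is an interface residue iff SASA_isolated(i) - SASA_complex(i) > cutoff.
    Symmetric in the chains by construction.
    """
    if len(complex_.chains) < 2:
        logger.warning("interface detection on a single-chain complex; empty set")
        return set()
    # one shared quadrature frame (the full complex's canonical frame) for
    # both states, so isolated-vs-complex differences carry no jitter
    frame = _canonical_frame(complex_.all_atoms()[0])
    complex_sasa = (complex_.per_residue_sasa
                    if complex_.per_residue_sasa is not None
                    else compute_sasa(complex_, probe, n_points, frame=frame))
    interface = set()
    for chain_id in complex_.chains:
        idx = complex_.chain_residue_indices(chain_id)
        sub = ComplexStructure([complex_.residues[i] for i in idx], [chain_id])
        iso = compute_sasa(sub, probe, n_points, frame=frame)
        for local, global_i in enumerate(idx):
            if iso[local] - complex_sasa[global_i] > cutoff:
                interface.add(global_i)
    return interface


def annotate_surface(complex_: ComplexStructure, cutoff: float = 1.0,
                     probe: float = 1.4, n_points: int = 960) -> ComplexStructure:
    """Fill per_residue_sasa and interface_set in place; returns the complex.

    An already-present SASA array is kept (it was computed with the same
    deterministic quadrature); pass a complex with per_residue_sasa=None to
    force recomputation.
    """
    if complex_.per_residue_sasa is None:
        complex_.per_residue_sasa = compute_sasa(complex_, probe, n_points)
    if len(complex_.chains) >= 2:
        complex_.interface_set = detect_interface_residues(
            complex_, cutoff, probe, n_points)
    else:
        complex_.interface_set = set()
    return complex_


def write_surface_sidecar(complex_: ComplexStructure, path) -> None:
    """JSON sidecar: per-residue SASA, interface membership and chain map."""
    if complex_.per_residue_sasa is None or complex_.interface_set is None:
        raise ValueError("complex lacks surface annotation; call annotate_surface")
    payload = {
        "name": complex_.name,
        "chains": complex_.chains,
        "residues": [
            {"index": i, "chain": r.chain_id, "number": r.author_number,
             "aa": r.aa_type, "sasa": float(complex_.per_residue_sasa[i]),
             "interface": i in complex_.interface_set}
            for i, r in enumerate(complex_.residues)
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
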