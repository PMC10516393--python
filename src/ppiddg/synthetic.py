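"""Deterministic synthetic complexes and labelled WT/MT mutation pairs.

The generator emulates exactly the structural properties the pipeline
consumes: multi-chain complexes with 4-atom backbones (ideal alpha-helices,
1.5 A rise, 100 degrees per residue, 2.3 A helix radius), side chains as
pseudo-atom clusters whose atom count and reach are a deterministic,
invertible function of the assigned amino-acid class (so identity is
recoverable from geometry alone), and chain placement that creates a
genuine buried-SASA interface.

A mutant complex differs from its wild type only in the mutated residue's
side-chain cluster, mimicking side-chain-repacking mutant generators. The
ground-truth binding-affinity change is a fixed deterministic functional of
the structural perturbation:

    ddG = W_VOLUME * (vol_WT(site) - vol_MT(site))
        + W_BURIED * (buriedSASA_WT(site) - buriedSASA_MT(site))

with the wild-type-minus-mutant sign convention; optional Gaussian noise
can be added on top. The weights are fixed constants of the generator, not
tunable knobs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure import (AA_ORDER, ATOMIC_MASS, ComplexStructure,
                        ResidueStructure, annotate_surface, compute_sasa)

logger = logging.getLogger(__name__)

HELIX_RISE = 1.5          # A per residue
HELIX_TWIST = np.deg2rad(100.0)
HELIX_RADIUS = 2.3        # A, C-alpha distance from helix axis

# label-function weights: fixed constants, kcal/mol per proxy unit
W_VOLUME = 0.1
W_BURIED = 0.05

_SIDECHAIN_ATOM_NAMES = ["CB", "CG", "CD", "CE", "CZ", "CH", "CT", "CU",
                         "CV", "CW", "CX"]


SIDECHAIN_SPACING = 0.7  # A between consecutive pseudo-atoms of a cluster


def aa_class_geometry(aa: str):
    """(n_atoms, base_distance) for an amino-acid class.

    The 20 classes map bijectively onto atom counts 3/5/7/9/11 crossed with
    base C-alpha distances 1.5/3.9/6.3/8.7 A. Both steps are large relative
    to the sub-Angstrom corruption noise of pre-training, and larger
    clusters average the noise down, so class identity stays recoverable
    from noisy side-chain geometry: the centroid distance locates the
    base-distance bin and the cluster extent (0.7 A atom spacing) encodes
    the atom count.
    """
    c = AA_ORDER.index(aa)
    n_atoms = 3 + 2 * (c % 5)
    base_dist = 1.5 + 2.4 * (c // 5)
    return n_atoms, base_dist


def volume_proxy(aa: str) -> float:
    """Scalar side-chain size proxy used by the label function."""
    n_atoms, base_dist = aa_class_geometry(aa)
    return n_atoms * base_dist


@dataclass
class SyntheticSpec:
    n_residues: int = 24        # per chain
    n_chains: int = 2
    separation: float | None = None  # A between helix axes; None = contact
    contact_gap: float = 2.5    # A closest inter-chain approach when adaptive
    helix_rise: float = HELIX_RISE
    helix_twist: float = HELIX_TWIST
    helix_radius: float = HELIX_RADIUS
    seed: int = 0


class GenerationError(RuntimeError):
    pass


def _sidechain_cluster(aa: str, ca: np.ndarray, outward: np.ndarray,
                       tangent: np.ndarray):
    """Deterministic pseudo-atom cluster for a residue's side chain.

    Atoms march outward from the C-alpha along the radial direction with a
    small alternating tangential offset; spacing and count encode the class.
    """
    n_atoms, base_dist = aa_class_geometry(aa)
    binormal = np.cross(outward, tangent)
    coords = []
    for k in range(n_atoms):
        wiggle = 0.45 * ((-1) ** k) * tangent + 0.25 * np.sin(1.0 + k) * binormal
        coords.append(ca + (base_dist + SIDECHAIN_SPACING * k) * outward
                      + wiggle * min(k, 1))
    names = _SIDECHAIN_ATOM_NAMES[:n_atoms]
    masses = np.full(n_atoms, ATOMIC_MASS["C"])
    return np.array(coords), masses, names


def make_toy_complex(spec: SyntheticSpec,
                     aa_sequence: list | None = None) -> ComplexStructure:
    """Ideal multi-helix complex; same spec and seed give identical output.

    Chains are parallel helices with axes spaced ``spec.separation`` apart
    along x, each chain facing its neighbour so that radially pointing side
    chains create inter-chain contacts.
    """
    if spec.n_residues < 3:
        raise ValueError("need at least 3 residues per chain")
    rng = np.random.default_rng(spec.seed)
    if aa_sequence is None:
        aa_sequence = ["".join(rng.choice(list(AA_ORDER), size=spec.n_residues))
                       for _ in range(spec.n_chains)]
    chains = [chr(ord("A") + c) for c in range(spec.n_chains)]
    per_chain = []
    for c in range(spec.n_chains):
        # build each chain on a local axis through the origin, place later
        phase = np.pi if c % 2 else 0.0  # neighbours face each other
        z0 = 0.35 * c  # slight stagger so chains are not mirror-degenerate
        chain_res = []
        for i in range(spec.n_residues):
            theta = phase + i * spec.helix_twist

            def ring(angle, z, radius=spec.helix_radius):
                return np.array([radius * np.cos(angle),
                                 radius * np.sin(angle), z])

            ca = ring(theta, z0 + i * spec.helix_rise)
            n = ring(theta - 0.55, z0 + i * spec.helix_rise - 0.9,
                     spec.helix_radius * 0.88)
            cc = ring(theta + 0.55, z0 + i * spec.helix_rise + 0.85,
                      spec.helix_radius * 0.92)
            o = cc + np.array([0.7 * np.cos(theta + 1.2),
                               0.7 * np.sin(theta + 1.2), 0.95])
            outward = np.array([np.cos(theta), np.sin(theta), 0.0])
            tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
            aa = aa_sequence[c][i]
            sc, masses, names = _sidechain_cluster(aa, ca, outward, tangent)
            chain_res.append(ResidueStructure(
                aa, chains[c], str(i + 1),
                np.array([n, ca, cc, o]), sc, masses, list(names)))
        per_chain.append(chain_res)

    # chain placement along +x: either the requested axis separation, or the
    # smallest shift putting the chain `contact_gap` away from its neighbour
    shift = 0.0
    placed_atoms = None
    residues = []
    for c, chain_res in enumerate(per_chain):
        local = np.concatenate([np.vstack([r.backbone_coords,
                                           r.sidechain_coords])
                                for r in chain_res])
        if c > 0:
            if spec.separation is not None:
                shift += spec.separation
            else:
                # only pairs closer than the gap in the yz-plane constrain
                # the x-shift; the binding pair ends exactly gap away
                dyz2 = ((placed_atoms[:, None, 1:] - local[None, :, 1:]) ** 2
                        ).sum(-1)
                tight = dyz2 < spec.contact_gap**2
                need = np.sqrt(spec.contact_gap**2 - dyz2[tight])
                dx = (placed_atoms[:, None, 0] - local[None, :, 0])[tight]
                shift = float((dx + need).max()) if need.size else shift + 10.0
        offset = np.array([shift, 0.0, 0.0])
        for r in chain_res:
            residues.append(ResidueStructure(
                r.aa_type, r.chain_id, r.author_number,
                r.backbone_coords + offset, r.sidechain_coords + offset,
                r.sidechain_masses, r.sidechain_names))
        moved = local + offset
        placed_atoms = (moved if placed_atoms is None
                        else np.concatenate([placed_atoms, moved]))

    cx = ComplexStructure(residues, chains, name=f"synthetic-{spec.seed}")
    if spec.n_chains > 1:
        for a in range(len(chains) - 1):
            pa = np.concatenate([np.vstack([r.backbone_coords,
                                            r.sidechain_coords])
                                 for r in cx.residues
                                 if r.chain_id == chains[a]])
            pb = np.concatenate([np.vstack([r.backbone_coords,
                                            r.sidechain_coords])
                                 for r in cx.residues
                                 if r.chain_id == chains[a + 1]])
            dmin = np.sqrt((((pa[:, None, :] - pb[None, :, :]) ** 2)
                            .sum(-1)).min())
            if dmin < 1.0:
                raise GenerationError(
                    f"chains {chains[a]}/{chains[a+1]} overlap "
                    f"(min atom distance {dmin:.2f} A); increase separation")
    return cx


def write_pdb(complex_: ComplexStructure, path) -> None:
    """Write a valid single-model PDB file via Biopython."""
    from Bio.PDB import PDBIO, StructureBuilder
    from .structure import AA3_TO_1

    one_to_three = {v: k for k, v in AA3_TO_1.items()}
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("synthetic")
    builder.init_model(0)
    current_chain = None
    serial = 1
    for res in complex_.residues:
        if res.chain_id != current_chain:
            builder.init_chain(res.chain_id)
            builder.init_seg("    ")
            current_chain = res.chain_id
        builder.init_residue(one_to_three[res.aa_type], " ",
                             int("".join(ch for ch in res.author_number
                                         if ch.isdigit() or ch == "-")),
                             res.author_number[-1]
                             if res.author_number[-1].isalpha() else " ")
        for name, coord in zip(["N", "CA", "C", "O"], res.backbone_coords):
            builder.init_atom(name, np.asarray(coord, dtype=np.float32), 0.0,
                              1.0, " ", name.center(4)[:4], serial,
                              element=name[0])
            serial += 1
        for name, coord in zip(res.sidechain_names, res.sidechain_coords):
            builder.init_atom(name, np.asarray(coord, dtype=np.float32), 0.0,
                              1.0, " ", name.center(4)[:4], serial,
                              element="C")
            serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def _site_buried_sasa(cx: ComplexStructure, site: int,
                      n_points: int = 960) -> float:
    """Buried SASA of one residue: isolated-chain SASA minus complex SASA.

    Both states share the complex's quadrature frame, matching the
    interface-detection convention.
    """
    from ppiddg.structure import _canonical_frame

    frame = _canonical_frame(cx.all_atoms()[0])
    if cx.per_residue_sasa is None:
        cx.per_residue_sasa = compute_sasa(cx, n_points=n_points, frame=frame)
    chain_idx = cx.chain_residue_indices(cx.residues[site].chain_id)
    sub = ComplexStructure([cx.residues[i] for i in chain_idx],
                           [cx.residues[site].chain_id])
    iso = compute_sasa(sub, n_points=n_points, frame=frame)
    return float(iso[chain_idx.index(site)] - cx.per_residue_sasa[site])


def make_wt_mt_pair(spec: SyntheticSpec, site: int, new_aa: str,
                    noise_sd: float = 0.0, rng=None):
    """One labelled mutation: (WT complex, MT complex, true ddG).

    The mutant keeps every backbone atom and every other residue untouched;
    only the mutated site's side-chain cluster is regenerated under the new
    class law. The label is the fixed functional of side-chain volume change
    and site buried-SASA change described in the module docstring.
    """
    wt = make_toy_complex(spec)
    if not 0 <= site < len(wt):
        raise ValueError(f"site {site} out of range")
    wt_res = wt.residues[site]
    if new_aa == wt_res.aa_type:
        raise ValueError(f"mutation to identical residue {new_aa} at site {site}")

    i_in_chain = int(wt_res.author_number) - 1
    chain_no = wt.chains.index(wt_res.chain_id)
    phase = np.pi if chain_no % 2 else 0.0
    theta = phase + i_in_chain * spec.helix_twist
    outward = np.array([np.cos(theta), np.sin(theta), 0.0])
    tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
    sc, masses, names = _sidechain_cluster(new_aa, wt_res.ca, outward, tangent)

    mt_residues = list(wt.residues)
    mt_residues[site] = ResidueStructure(
        new_aa, wt_res.chain_id, wt_res.author_number,
        wt_res.backbone_coords.copy(), sc, masses, list(names))
    mt = ComplexStructure(mt_residues, list(wt.chains),
                          name=wt.name + f"-m{site}{new_aa}")

    d_vol = volume_proxy(wt_res.aa_type) - volume_proxy(new_aa)
    d_buried = _site_buried_sasa(wt, site) - _site_buried_sasa(mt, site)
    ddg = W_VOLUME * d_vol + W_BURIED * d_buried
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        ddg += float(rng.normal(0.0, noise_sd))
    return wt, mt, float(ddg)


def interface_adjacent_sites(cx: ComplexStructure, margin: int = 1) -> list:
    """Interface residues plus their within-chain sequence neighbours."""
    if cx.interface_set is None:
        annotate_surface(cx)
    sites = set()
    for i in sorted(cx.interface_set):
        for j in range(i - margin, i + margin + 1):
            if 0 <= j < len(cx) and cx.residues[j].chain_id == cx.residues[i].chain_id:
                sites.add(j)
    return sorted(sites)


def make_pair_corpus(n_pairs: int, spec: SyntheticSpec | None = None,
                     n_complex_types: int = 20, noise_sd: float = 0.0,
                     seed: int = 0):
    """A corpus of labelled WT/MT pairs spread over distinct WT complexes.

    Returns a list of dicts with keys wt, mt, site, wt_aa, mt_aa, ddg and
    complex_type. Mutation sites are drawn from the interface-adjacent
    region of each WT complex.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng([seed, 99])
    samples = []
    type_specs = []
    for t in range(n_complex_types):
        s = SyntheticSpec(**{**spec.__dict__, "seed": spec.seed + 1000 + t})
        type_specs.append(s)
    candidate_sites = {}
    for k in range(n_pairs):
        t = int(rng.integers(n_complex_types))
        s = type_specs[t]
        if t not in candidate_sites:
            wt_probe = make_toy_complex(s)
            annotate_surface(wt_probe)
            sites = interface_adjacent_sites(wt_probe)
            if not sites:
                sites = list(range(len(wt_probe)))
            candidate_sites[t] = sites
        site = int(rng.choice(candidate_sites[t]))
        wt_aa_probe = make_toy_complex(s).residues[site].aa_type
        new_aa = wt_aa_probe
        while new_aa == wt_aa_probe:
            new_aa = AA_ORDER[int(rng.integers(20))]
        wt, mt, ddg = make_wt_mt_pair(s, site, new_aa, noise_sd=noise_sd,
                                      rng=rng)
        samples.append({
            "sample_id": f"s{k:04d}", "wt": wt, "mt": mt, "site": site,
            "wt_aa": wt_aa_probe, "mt_aa": new_aa, "ddg": ddg,
            "complex_type": f"type{t:02d}"})
    return samples


def make_pretraining_corpus(n_complexes: int, spec: SyntheticSpec | None = None,
                            seed: int = 0):
    """Annotated toy complexes with varied sequences for pre-training."""
    spec = spec or SyntheticSpec()
    out = []
    for k in range(n_complexes):
        s = SyntheticSpec(**{**spec.__dict__, "seed": spec.seed + 7000 + k})
        cx = make_toy_complex(s)
        annotate_surface(cx)
        out.append(cx)
    return out
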