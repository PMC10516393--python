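"""PDB parsing, virtual C-beta placement, SASA and interface detection."""

import numpy as np
import pytest

from ppiddg import (SyntheticSpec, compute_sasa,
                    detect_interface_residues, make_toy_complex,
                    place_virtual_cb, read_pdb_complex)
from ppiddg.structure import (ComplexStructure, GeometryError, PDBInputError,
                              golden_spiral_points, _atom_sasa)

from conftest import random_rotation


def _atom_line(serial, name, resname, chain, resseq, xyz, occ=1.0,
               altloc=" ", element=None):
    element = element or name[0]
    return (f"ATOM  {serial:5d} {name:<4s}{altloc}{resname:<3s} {chain}"
            f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {element:>2s}")


def _backbone(resseq, chain, resname="ALA", offset=np.zeros(3), serial=1,
              with_o=True, with_h=False, extra=()):
    base = np.array([3.0 * resseq, 0.0, 0.0]) + offset
    lines = [
        _atom_line(serial, "N", resname, chain, resseq, base + [0, 1.4, 0]),
        _atom_line(serial + 1, "CA", resname, chain, resseq, base),
        _atom_line(serial + 2, "C", resname, chain, resseq, base + [1.5, 0, 0]),
    ]
    if with_o:
        lines.append(_atom_line(serial + 3, "O", resname, chain, resseq,
                                base + [1.9, 1.1, 0]))
    if with_h:
        lines.append(_atom_line(serial + 4, "H", resname, chain, resseq,
                                base + [0, 2.2, 0], element="H"))
    for k, (nm, pos) in enumerate(extra):
        lines.append(_atom_line(serial + 5 + k, nm, resname, chain, resseq,
                                base + pos))
    return lines


def _write(tmp_path, lines, name="toy.pdb"):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\nTER\nEND\n")
    return p


def test_hydrogens_always_stripped(tmp_path):
    lines = []
    for chain, off in (("A", np.zeros(3)), ("B", np.array([0, 20.0, 0]))):
        for i in range(1, 4):
            lines += _backbone(i, chain, offset=off, serial=100 * (chain == "B") + 10 * i,
                               with_h=True,
                               extra=[("CB", np.array([0, -1.5, 0]))])
    cx = read_pdb_complex(_write(tmp_path, lines))
    assert len(cx) == 6 and cx.chains == ["A", "B"]
    for r in cx.residues:
        assert all(not n.startswith("H") for n in r.sidechain_names)


def test_glycine_side_chain_is_virtual_cbeta(tmp_path):
    lines = []
    for i in range(1, 4):
        lines += _backbone(i, "A", resname="GLY", serial=10 * i)
    cx = read_pdb_complex(_write(tmp_path, lines))
    for r in cx.residues:
        assert r.sidechain_coords.shape == (1, 3)
        expected = place_virtual_cb(r.backbone_coords)
        assert np.allclose(r.sidechain_coords[0], expected, atol=1e-3)


def test_residue_missing_backbone_atom_dropped(tmp_path, caplog):
    lines = _backbone(1, "A", serial=10) + _backbone(2, "A", serial=20,
                                                     with_o=False)
    lines += _backbone(1, "B", offset=np.array([0, 30.0, 0]), serial=40)
    with caplog.at_level("WARNING"):
        cx = read_pdb_complex(_write(tmp_path, lines))
    assert len(cx) == 2
    assert any("backbone" in rec.message for rec in caplog.records)
    with pytest.raises(PDBInputError):
        read_pdb_complex(_write(tmp_path, lines), strict=True)


def test_strict_mode_requires_two_chains(tmp_path):
    lines = _backbone(1, "A", serial=1) + _backbone(2, "A", serial=10)
    path = _write(tmp_path, lines)
    read_pdb_complex(path)  # lenient mode is fine
    with pytest.raises(PDBInputError, match="2 chains"):
        read_pdb_complex(path, strict=True)


def test_altloc_resolves_to_highest_occupancy(tmp_path):
    lines = _backbone(1, "A", serial=1) + _backbone(2, "A", serial=20)
    del lines[1]  # replace residue 1's CA by two lettered altlocs
    lines.insert(1, _atom_line(9, "CA", "ALA", "A", 1,
                               np.array([3.0, 0.0, 0.0]), occ=0.7,
                               altloc="A"))
    lines.insert(2, _atom_line(10, "CA", "ALA", "A", 1,
                               np.array([99.0, 99.0, 99.0]), occ=0.3,
                               altloc="B"))
    cx = read_pdb_complex(_write(tmp_path, lines))
    assert np.allclose(cx.residues[0].ca, [3.0, 0.0, 0.0])


class TestVirtualCBeta:
    backbone = np.array([[1.46, 0.0, 0.0],     # N
                         [0.0, 0.0, 0.0],      # CA
                         [-0.55, 1.41, 0.0],   # C
                         [0.2, 2.4, 0.0]])     # O

    def test_bond_length(self):
        cb = place_virtual_cb(self.backbone)
        assert abs(np.linalg.norm(cb - self.backbone[1]) - 1.522) < 1e-3

    def test_rigid_motion_covariance(self, rng):
        cb = place_virtual_cb(self.backbone)
        for _ in range(10):
            R, t = random_rotation(rng), rng.normal(size=3)
            moved = place_virtual_cb(self.backbone @ R.T + t)
            assert np.linalg.norm(moved - (cb @ R.T + t)) < 1e-6

    @staticmethod
    def _gram_schmidt_oracle(backbone):
        """Independent construction: fixed local coordinates in the
        Gram-Schmidt frame of (N-CA, C-CA)."""
        n, ca, c = backbone[0], backbone[1], backbone[2]
        e1 = (n - ca) / np.linalg.norm(n - ca)
        u2 = (c - ca) - ((c - ca) @ e1) * e1
        e2 = u2 / np.linalg.norm(u2)
        e3 = np.cross(e1, e2)
        # local coordinates of an ideal tetrahedral CB at 1.522 A: derived
        # once from the defining angles, frozen here
        u1 = e1
        v2 = (c - ca) / np.linalg.norm(c - ca)
        bis = (u1 + v2) / np.linalg.norm(u1 + v2)
        perp = np.cross(v2, u1) / np.linalg.norm(np.cross(v2, u1))
        direction = -np.sqrt(1 / 3) * bis + np.sqrt(2 / 3) * perp
        return ca + 1.522 * direction

    def test_chirality_follows_the_input_frame(self, rng):
        """The CB pops out of the N-CA-C plane on the side fixed by the
        handedness of the local frame; a mirrored backbone therefore keeps
        the same local coordinates in its (mirrored) Gram-Schmidt frame.
        Checked against the explicit Gram-Schmidt oracle on random
        backbones and on the mirrored one."""
        for trial in range(5):
            R, t = random_rotation(rng), rng.normal(size=3)
            bb = self.backbone @ R.T + t
            assert np.allclose(place_virtual_cb(bb),
                               self._gram_schmidt_oracle(bb), atol=1e-9)
        mirrored = self.backbone @ np.diag([1.0, 1.0, -1.0])
        assert np.allclose(place_virtual_cb(mirrored),
                           self._gram_schmidt_oracle(mirrored), atol=1e-9)

    def test_collinear_backbone_rejected(self):
        bad = np.array([[1, 0, 0], [0, 0, 0], [-1, 0, 0], [0, 1, 0.0]])
        with pytest.raises(GeometryError):
            place_virtual_cb(bad)


class TestSasa:
    def test_isolated_atom_matches_closed_form(self):
        area = _atom_sasa(np.zeros((1, 3)), np.array([1.7]), 1.4, 960)[0]
        assert abs(area - 4 * np.pi * 3.1**2) / (4 * np.pi * 3.1**2) < 0.01

    def test_distant_atoms_unoccluded(self):
        area = _atom_sasa(np.array([[0, 0, 0], [100.0, 0, 0]]),
                          np.array([1.7, 1.7]), 1.4, 960)
        assert np.allclose(area, 4 * np.pi * 3.1**2, rtol=1e-9)

    def test_caged_atom_is_buried(self):
        """Atom enclosed by a tight shell of neighbours loses >99% of its
        surface; verified against a brute-force point-rejection oracle."""
        cage = 3.0 * golden_spiral_points(26)
        coords = np.vstack([np.zeros(3), cage])
        radii = np.full(len(coords), 1.7)
        fast = _atom_sasa(coords, radii, 1.4, 960)

        sphere = golden_spiral_points(960)
        ext = radii + 1.4
        pts = coords[0] + ext[0] * sphere
        occluded = np.zeros(960, dtype=bool)
        for j in range(1, len(coords)):
            occluded |= ((pts - coords[j]) ** 2).sum(1) < ext[j] ** 2
        brute = 4 * np.pi * ext[0] ** 2 * (960 - occluded.sum()) / 960

        isolated = 4 * np.pi * ext[0] ** 2
        assert fast[0] < 0.01 * isolated
        assert brute < 0.01 * isolated

    def test_negative_probe_rejected(self, small_complex):
        with pytest.raises(ValueError):
            compute_sasa(small_complex, probe=-0.1)

    def test_rigid_motion_invariance(self, small_complex, rng):
        base = compute_sasa(small_complex)
        for _ in range(3):
            moved = small_complex.transformed(random_rotation(rng),
                                              rng.normal(size=3) * 10)
            assert np.abs(compute_sasa(moved) - base).max() < 0.5


class TestInterface:
    def test_far_apart_chains_have_no_interface(self):
        cx = make_toy_complex(SyntheticSpec(n_residues=8, separation=100.0))
        assert detect_interface_residues(cx) == set()

    def test_unreachable_cutoff_gives_empty_set(self, small_complex):
        assert detect_interface_residues(small_complex,
                                         cutoff=np.inf) == set()

    def test_single_chain_warns_and_returns_empty(self, caplog):
        cx = make_toy_complex(SyntheticSpec(n_residues=8, n_chains=1))
        with caplog.at_level("WARNING"):
            assert detect_interface_residues(cx) == set()

    def test_detected_residues_really_bury_surface(self, small_complex):
        """Every reported interface residue buries more than the cutoff,
        recomputed via an independent isolated-vs-complex SASA evaluation."""
        from ppiddg.structure import _canonical_frame

        interface = small_complex.interface_set
        assert interface  # the contact-placed toy complex must touch
        frame = _canonical_frame(small_complex.all_atoms()[0])
        complex_sasa = compute_sasa(small_complex, frame=frame)
        for i in sorted(interface):
            chain = small_complex.residues[i].chain_id
            idx = small_complex.chain_residue_indices(chain)
            sub = ComplexStructure(
                [small_complex.residues[j] for j in idx], [chain])
            iso = compute_sasa(sub, frame=frame)
            assert iso[idx.index(i)] - complex_sasa[i] > 1.0

    def test_symmetric_under_chain_relabelling(self, small_complex):
        relabel = {"A": "B", "B": "A"}
        swapped = ComplexStructure(
            [type(r)(r.aa_type, relabel[r.chain_id], r.author_number,
                     r.backbone_coords, r.sidechain_coords,
                     r.sidechain_masses, r.sidechain_names)
             for r in small_complex.residues],
            ["B", "A"])
        assert (detect_interface_residues(swapped)
                == detect_interface_residues(
                    ComplexStructure(list(small_complex.residues),
                                     list(small_complex.chains))))
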