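"""Contact-graph construction and featurization at the fixed layout."""

import numpy as np
import pytest

from ppiddg import (SyntheticSpec, assemble_contact_graphs, build_knn_graph,
                    build_radius_graph, edge_features, load_graph_archive,
                    make_toy_complex, node_features, normalize_coordinates,
                    save_graph_archive, annotate_surface)
from ppiddg.graphs import (_positional_encoding, _rbf, GraphFeaturizer,
                           NormalizedComplex)

from conftest import random_rotation


def _point_cloud(ca):
    """Wrap bare C-alpha positions into a NormalizedComplex."""
    ca = np.asarray(ca, dtype=float)
    return NormalizedComplex(
        ca=ca, cb=ca + [0.0, 0.0, 1.0],
        backbone=[np.vstack([c + [0, 1, 0], c, c + [1, 0, 0], c + [1, 1, 0]])
                  for c in ca],
        sidechain=[c[None, :] + [0.0, 0.0, 1.0] for c in ca],
        sidechain_masses=[np.array([12.0])] * len(ca),
        chain_ids=["A"] * len(ca), centroid=np.zeros(3))


class TestNormalization:
    def test_backbone_centroid_moves_to_origin(self, small_complex):
        norm = normalize_coordinates(small_complex)
        bb = np.concatenate(norm.backbone)
        assert np.abs(bb.mean(axis=0)).max() < 1e-6

    def test_centered_input_is_unchanged(self, small_complex):
        norm1 = normalize_coordinates(small_complex)
        centered = small_complex.translated(-norm1.centroid)
        norm2 = normalize_coordinates(centered)
        assert np.abs(norm2.centroid).max() < 1e-9
        assert np.allclose(norm2.ca, norm1.ca)

    def test_translation_cancels(self, small_complex):
        norm1 = normalize_coordinates(small_complex)
        norm2 = normalize_coordinates(small_complex.translated([13.0, -7.0, 2.0]))
        assert np.allclose(norm1.ca, norm2.ca, atol=1e-9)
        assert np.allclose(np.concatenate(norm1.sidechain),
                           np.concatenate(norm2.sidechain), atol=1e-9)


class TestKnnGraph:
    def test_unit_square_adjacency(self):
        """Brute-force oracle: at the corners of a unit square with K=2 the
        two adjacent corners win over the diagonal."""
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.0]])
        edges = build_knn_graph(_point_cloud(pts), K=2)
        nbrs = {i: set(edges[edges[:, 0] == i, 1]) for i in range(4)}
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        for i in range(4):
            brute = set(np.argsort(np.where(np.arange(4) == i, np.inf, d[i]),
                                   kind="stable")[:2])
            assert nbrs[i] == brute
            assert (i + 2) % 4 not in nbrs[i]  # diagonal excluded

    def test_small_complex_caps_at_n_minus_1(self):
        edges = build_knn_graph(_point_cloud(np.diag([1.0, 2.0, 3.0])), K=20)
        deg = np.bincount(edges[:, 0], minlength=3)
        assert (deg == 2).all()

    def test_indegree_is_exactly_k_on_60_residues(self):
        cx = make_toy_complex(SyntheticSpec(n_residues=30, seed=3))
        edges = build_knn_graph(normalize_coordinates(cx), K=20)
        deg = np.bincount(edges[:, 0], minlength=60)
        assert (deg == 20).all()
        assert (edges[:, 0] != edges[:, 1]).all()

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            build_knn_graph(_point_cloud(np.eye(3)), K=0)


class TestRadiusGraph:
    def test_collinear_chain_degrees(self):
        """5 collinear points 6 A apart: only <=10 A pairs connect, so the
        termini have degree 1... brute-forced over all 10 pairs."""
        pts = np.array([[6.0 * i, 0, 0] for i in range(5)])
        edges = build_radius_graph(_point_cloud(pts), R=10.0)
        deg = np.bincount(edges[:, 0], minlength=5)
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        brute = ((d <= 10.0) & (d > 0)).sum(axis=1)
        assert (deg == brute).all()
        assert deg.tolist() == [1, 2, 2, 2, 1]

    def test_symmetry_and_cutoff(self, small_complex):
        norm = normalize_coordinates(small_complex)
        edges = build_radius_graph(norm, R=10.0)
        pair_set = set(map(tuple, edges))
        assert all((j, i) in pair_set for i, j in pair_set)
        dist = np.linalg.norm(norm.ca[edges[:, 1]] - norm.ca[edges[:, 0]],
                              axis=1)
        assert (dist <= 10.0 + 1e-6).all()

    def test_tiny_radius_isolates_everything(self, caplog):
        with caplog.at_level("WARNING"):
            edges = build_radius_graph(_point_cloud(np.eye(3) * 5), R=0.01)
        assert len(edges) == 0


class TestNodeFeatures:
    def test_scalar_layout(self, small_complex):
        norm = normalize_coordinates(small_complex)
        s, v = node_features(norm, small_complex)
        assert s.shape == (len(small_complex), 29)
        assert v.shape == (len(small_complex), 9, 3)
        onehot = s[:, :20]
        assert ((onehot.sum(axis=1) == 1) & (onehot.max(axis=1) == 1)).all()

    def test_dihedral_encoding_unit_circle_or_pad(self, small_complex):
        s, _ = node_features(normalize_coordinates(small_complex),
                             small_complex)
        for pair in (s[:, 21:23], s[:, 23:25], s[:, 25:27]):
            mag = (pair**2).sum(axis=1)
            assert np.all((np.abs(mag - 1) < 1e-6) | (mag < 1e-12))
        # chain-initial residues have undefined phi/omega -> exact zero pads
        first = [min(small_complex.chain_residue_indices(c))
                 for c in small_complex.chains]
        assert np.allclose(s[first][:, [21, 22, 25, 26]], 0.0)

    def test_single_point_side_chain_collapses_channels(self, tmp_path):
        """A one-atom side chain (the glycine virtual CB case) makes the
        centroid, COM and max-coordinate channels coincide, and the two
        CA-anchored unit vectors coincide."""
        from ppiddg import read_pdb_complex
        from ppiddg.structure import place_virtual_cb
        from test_structure import _backbone, _write

        lines = []
        for i in range(1, 4):
            lines += _backbone(i, "A", resname="GLY", serial=10 * i)
        for i in range(1, 4):
            lines += _backbone(i, "B", resname="GLY", serial=200 + 10 * i,
                               offset=np.array([0, 8.0, 0]))
        cx = read_pdb_complex(_write(tmp_path, lines))
        annotate_surface(cx)
        norm = normalize_coordinates(cx)
        _, v = node_features(norm, cx)
        assert np.allclose(v[:, 0], v[:, 1]) and np.allclose(v[:, 0], v[:, 2])
        assert np.allclose(v[:, 3], v[:, 4]) and np.allclose(v[:, 3], v[:, 8])


class TestEdgeFeatures:
    def test_rbf_peaks_at_its_centre(self):
        centers = np.linspace(0, 20, 16)
        vals = _rbf(np.array([centers[5]]))
        assert np.isclose(vals[0, 5], 1.0)
        assert (np.delete(vals[0], 5) < 1.0).all()

    def test_zero_offset_encoding_pattern(self):
        enc = _positional_encoding(np.array([0.0]))
        assert np.allclose(enc[0, :8], 1.0)   # cos block
        assert np.allclose(enc[0, 8:], 0.0)   # sin block

    def test_edge_feature_shapes_and_unit_vectors(self, small_complex):
        norm = normalize_coordinates(small_complex)
        edges = build_knn_graph(norm)
        s, v = edge_features(norm, edges)
        assert s.shape == (len(edges), 32)
        assert v.shape == (len(edges), 1, 3)
        norms = np.linalg.norm(v[:, 0], axis=1)
        assert np.all((np.abs(norms - 1) < 1e-6) | (norms == 0))

    def test_coincident_pair_warns_and_zeroes(self, caplog):
        pts = np.array([[0, 0, 0], [0, 0, 0], [5.0, 0, 0]])
        cloud = _point_cloud(pts)
        with caplog.at_level("WARNING"):
            _, v = edge_features(cloud, np.array([[0, 1]]))
        assert np.allclose(v, 0)


class TestAssembly:
    def test_feature_shapes_on_60_residues(self):
        cx = make_toy_complex(SyntheticSpec(n_residues=30, seed=3))
        pair = assemble_contact_graphs(cx)
        assert pair.node_scalar.shape == (60, 29)
        assert pair.node_vector.shape == (60, 9, 3)
        assert pair.knn_edge_scalar.shape[1] == 32
        assert pair.knn_edge_vector.shape[1:] == (1, 3)

    def test_two_residue_complex(self):
        pts = np.array([[0, 0, 0], [4.0, 0, 0]])
        cloud = _point_cloud(pts)
        assert len(build_knn_graph(cloud, K=20)) == 2
        assert len(build_radius_graph(cloud, R=10.0)) == 2

    def test_archive_round_trip_bit_identical(self, small_pair, tmp_path):
        p1, p2 = tmp_path / "a.npz", tmp_path / "b.npz"
        save_graph_archive(small_pair, p1)
        save_graph_archive(small_pair, p2)
        assert p1.read_bytes() == p2.read_bytes()
        loaded = load_graph_archive(p1)
        assert np.array_equal(loaded.node_scalar, small_pair.node_scalar)
        assert np.array_equal(loaded.knn_edges, small_pair.knn_edges)


class TestRigidMotionBehaviour:
    def test_translation_leaves_all_features_identical(self, small_complex):
        feat = GraphFeaturizer()
        base = feat.transform([small_complex])[0]
        moved_cx = small_complex.translated([11.0, -4.0, 9.0])
        moved_cx.per_residue_sasa = small_complex.per_residue_sasa
        moved_cx.interface_set = set(small_complex.interface_set)
        moved = feat.transform([moved_cx])[0]
        assert np.allclose(base.node_scalar, moved.node_scalar, atol=1e-9)
        assert np.allclose(base.node_vector, moved.node_vector, atol=1e-9)
        assert np.array_equal(base.knn_edges, moved.knn_edges)

    @pytest.mark.parametrize("equivariant_max", [False, True])
    def test_rotation_covariance_of_vector_channels(self, small_complex, rng,
                                                    equivariant_max):
        feat = GraphFeaturizer(equivariant_max=equivariant_max)
        base = feat.transform([small_complex])[0]
        R = random_rotation(rng)
        moved_cx = small_complex.transformed(R, rng.normal(size=3))
        moved_cx.per_residue_sasa = small_complex.per_residue_sasa
        moved_cx.interface_set = set(small_complex.interface_set)
        moved = feat.transform([moved_cx])[0]
        assert np.allclose(base.node_scalar, moved.node_scalar, atol=1e-9)
        assert np.array_equal(base.knn_edges, moved.knn_edges)
        assert np.array_equal(base.radius_edges, moved.radius_edges)
        rotated = base.node_vector @ R.T
        if equivariant_max:
            assert np.allclose(moved.node_vector, rotated, atol=1e-8)
        else:
            # every channel except the literal componentwise max rotates
            keep = [0, 1, 3, 4, 5, 6, 7, 8]
            assert np.allclose(moved.node_vector[:, keep],
                               rotated[:, keep], atol=1e-8)
        assert np.allclose(moved.knn_edge_vector,
                           base.knn_edge_vector @ R.T, atol=1e-8)
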