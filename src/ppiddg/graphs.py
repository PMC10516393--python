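"""Residue contact-graph construction and featurization.

Every complex is represented twice over the same residue nodes: a directed
K-nearest-neighbour graph (each residue receives edges from its K nearest
residues by C-alpha distance, K=20) and a symmetric radius graph (all pairs
within R=10 A). Node features are shared between the two graphs; edge
features are computed per relation.

Feature layout (version 1):
  node scalars, 29 = AA one-hot (20) + chain index (1) + sin/cos of
      phi/psi/omega (6) + relative SASA (1) + interface flag (1)
  node vectors, 9x3 = side-chain centroid, side-chain centre of mass,
      side-chain max-coordinate, unit CA->centroid, unit CA->COM,
      centred CA position, unit to preceding CA, unit to following CA,
      unit CA->CB
  edge scalars, 32 = 16 Gaussian RBFs of the CA-CA distance (centres
      0..20 A, width = centre spacing) + 16-dim sinusoidal encoding of the
      signed residue index offset j - i
  edge vectors, 1x3 = unit vector from CA_i to CA_j

All coordinates are first centred on the centroid of the backbone atoms, so
every feature is exactly translation-invariant. The side-chain
max-coordinate channel is the componentwise maximum as defined, which is not
rotation-covariant; ``equivariant_max=True`` substitutes the coordinate of
the side-chain atom farthest from C-alpha, which is.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

from .structure import AA_INDEX, MAX_SASA, ComplexStructure, annotate_surface

logger = logging.getLogger(__name__)

FEATURE_LAYOUT_VERSION = 1
NODE_SCALAR_DIM = 29
NODE_VECTOR_DIM = 9
EDGE_SCALAR_DIM = 32
EDGE_VECTOR_DIM = 1

RBF_COUNT = 16
RBF_MAX = 20.0
POS_ENC_DIM = 16


@dataclass
class NormalizedComplex:
    """Centred coordinates: backbone centroid moved to the origin."""
    ca: np.ndarray            # (N, 3)
    cb: np.ndarray            # (N, 3)
    backbone: list            # N arrays (4, 3)
    sidechain: list           # N arrays (M_i, 3)
    sidechain_masses: list    # N arrays (M_i,)
    chain_ids: list
    centroid: np.ndarray      # the subtracted centroid, original frame


@dataclass
class ContactGraphPair:
    n_nodes: int
    knn_edges: np.ndarray       # (E_K, 2) int, row (i, j): edge from j to i
    radius_edges: np.ndarray    # (E_R, 2) int, same convention, symmetric
    node_scalar: np.ndarray     # (N, 29)
    node_vector: np.ndarray     # (N, 9, 3)
    knn_edge_scalar: np.ndarray     # (E_K, 32)
    knn_edge_vector: np.ndarray     # (E_K, 1, 3)
    radius_edge_scalar: np.ndarray  # (E_R, 32)
    radius_edge_vector: np.ndarray  # (E_R, 1, 3)
    K: int = 20
    R: float = 10.0
    layout_version: int = FEATURE_LAYOUT_VERSION


def normalize_coordinates(complex_: ComplexStructure) -> NormalizedComplex:
    """Subtract the centroid of all backbone (N, CA, C, O) atoms."""
    if len(complex_) == 0:
        raise ValueError("empty complex")
    backbone_all = np.concatenate([r.backbone_coords for r in complex_.residues])
    centroid = backbone_all.mean(axis=0)
    return NormalizedComplex(
        ca=np.array([r.ca for r in complex_.residues]) - centroid,
        cb=np.array([r.cb for r in complex_.residues]) - centroid,
        backbone=[r.backbone_coords - centroid for r in complex_.residues],
        sidechain=[r.sidechain_coords - centroid for r in complex_.residues],
        sidechain_masses=[r.sidechain_masses for r in complex_.residues],
        chain_ids=[r.chain_id for r in complex_.residues],
        centroid=centroid,
    )


def build_knn_graph(norm: NormalizedComplex, K: int = 20) -> np.ndarray:
    """Directed edges (i, j): j is one of i's min(K, N-1) nearest residues.

    Distance is Euclidean between centred C-alpha positions; ties break by
    lower residue index.
    """
    if K <= 0:
        raise ValueError(f"K must be positive, got {K}")
    N = len(norm.ca)
    if N < 2:
        raise ValueError("need at least 2 residues for a contact graph")
    k_eff = min(K, N - 1)
    d = np.linalg.norm(norm.ca[:, None, :] - norm.ca[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    # round to 1e-6 A so rigid-motion float jitter cannot reorder ties;
    # stable argsort then resolves equal distances to the lower index
    order = np.argsort(np.round(d, 6), axis=1, kind="stable")[:, :k_eff]
    edges = np.column_stack([
        np.repeat(np.arange(N), k_eff), order.ravel()]).astype(np.intp)
    return edges


def build_radius_graph(norm: NormalizedComplex, R: float = 10.0) -> np.ndarray:
    """Symmetric edges: both (i, j) and (j, i) for every pair with
    ||CA_i - CA_j|| <= R."""
    if R <= 0:
        raise ValueError(f"R must be positive, got {R}")
    N = len(norm.ca)
    if N < 2:
        raise ValueError("need at least 2 residues for a contact graph")
    tree = cKDTree(norm.ca)
    pairs = tree.query_pairs(R + 1e-6, output_type="ndarray")
    if len(pairs) > 0:
        # tie-robust threshold: exactly-at-R pairs stay in under float jitter
        d = np.linalg.norm(norm.ca[pairs[:, 0]] - norm.ca[pairs[:, 1]], axis=1)
        pairs = pairs[np.round(d, 6) <= R]
    if len(pairs) == 0:
        logger.warning("radius graph has no edges at R=%.2f A", R)
        return np.empty((0, 2), dtype=np.intp)
    edges = np.concatenate([pairs, pairs[:, ::-1]])
    edges = edges[np.lexsort((edges[:, 1], edges[:, 0]))]  # canonical order
    degree = np.bincount(edges[:, 0], minlength=N)
    if (degree == 0).any():
        logger.warning("%d residues isolated in the radius graph",
                       int((degree == 0).sum()))
    return edges.astype(np.intp)


def _safe_unit(v: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return np.where(n > eps, v / np.where(n > eps, n, 1.0), 0.0)


def _cross3(a, b):
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = _cross3(b0, b1), _cross3(b1, b2)
    m1 = _cross3(n1, b1 / np.linalg.norm(b1))
    x, y = n1 @ n2, m1 @ n2
    return float(np.arctan2(y, x))


def _backbone_dihedrals(norm: NormalizedComplex) -> np.ndarray:
    """(N, 6): sin/cos of phi, psi, omega, computed within chains; undefined
    angles at chain termini are zero-padded (both sin and cos are 0)."""
    N = len(norm.ca)
    out = np.zeros((N, 6))
    for i in range(N):
        bb = norm.backbone[i]
        same_prev = i > 0 and norm.chain_ids[i - 1] == norm.chain_ids[i]
        same_next = i + 1 < N and norm.chain_ids[i + 1] == norm.chain_ids[i]
        if same_prev:
            prev = norm.backbone[i - 1]
            phi = _dihedral(prev[2], bb[0], bb[1], bb[2])
            omega = _dihedral(prev[1], prev[2], bb[0], bb[1])
            out[i, 0], out[i, 1] = np.sin(phi), np.cos(phi)
            out[i, 4], out[i, 5] = np.sin(omega), np.cos(omega)
        if same_next:
            nxt = norm.backbone[i + 1]
            psi = _dihedral(bb[0], bb[1], bb[2], nxt[0])
            out[i, 2], out[i, 3] = np.sin(psi), np.cos(psi)
    return out


def node_features(norm: NormalizedComplex, complex_: ComplexStructure,
                  equivariant_max: bool = False):
    """Per-residue scalar (N, 29) and vector (N, 9, 3) features.

    Requires SASA and the interface set to be present on the complex.
    """
    if complex_.per_residue_sasa is None or complex_.interface_set is None:
        raise ValueError("complex lacks surface annotation; call annotate_surface")
    N = len(norm.ca)
    scalars = np.zeros((N, NODE_SCALAR_DIM))
    vectors = np.zeros((N, NODE_VECTOR_DIM, 3))

    chain_order = {c: k for k, c in enumerate(complex_.chains)}
    n_chains = len(complex_.chains)
    dihedrals = _backbone_dihedrals(norm)

    for i, res in enumerate(complex_.residues):
        sc = norm.sidechain[i]
        masses = norm.sidechain_masses[i]
        ca = norm.ca[i]
        centroid = sc.mean(axis=0)
        com = (sc * masses[:, None]).sum(axis=0) / masses.sum()
        if equivariant_max:
            far = int(np.argmax(np.linalg.norm(sc - ca, axis=1)))
            max_coord = sc[far]
        else:
            max_coord = sc.max(axis=0)

        scalars[i, AA_INDEX[res.aa_type]] = 1.0
        scalars[i, 20] = chain_order[res.chain_id] / max(1, n_chains - 1)
        scalars[i, 21:27] = dihedrals[i]
        scalars[i, 27] = min(
            1.5, complex_.per_residue_sasa[i] / MAX_SASA[res.aa_type])
        scalars[i, 28] = 1.0 if i in complex_.interface_set else 0.0

        vectors[i, 0] = centroid
        vectors[i, 1] = com
        vectors[i, 2] = max_coord
        vectors[i, 3] = _safe_unit(centroid - ca)
        vectors[i, 4] = _safe_unit(com - ca)
        vectors[i, 5] = ca
        same_prev = i > 0 and norm.chain_ids[i - 1] == res.chain_id
        same_next = i + 1 < N and norm.chain_ids[i + 1] == res.chain_id
        if same_prev:
            vectors[i, 6] = _safe_unit(norm.ca[i - 1] - ca)
        if same_next:
            vectors[i, 7] = _safe_unit(norm.ca[i + 1] - ca)
        vectors[i, 8] = _safe_unit(norm.cb[i] - ca)
    return scalars, vectors


def _rbf(d: np.ndarray) -> np.ndarray:
    centers = np.linspace(0.0, RBF_MAX, RBF_COUNT)
    width = centers[1] - centers[0]
    return np.exp(-((d[:, None] - centers[None, :]) / width) ** 2)


def _positional_encoding(offset: np.ndarray) -> np.ndarray:
    """16-dim sinusoidal encoding of the signed residue index offset."""
    k = np.arange(0, POS_ENC_DIM, 2, dtype=float)
    freq = np.exp(-k * np.log(10000.0) / POS_ENC_DIM)
    ang = offset[:, None] * freq[None, :]
    return np.concatenate([np.cos(ang), np.sin(ang)], axis=1)


def edge_features(norm: NormalizedComplex, edges: np.ndarray):
    """Per-edge scalar (E, 32) and vector (E, 1, 3) features for edges (i, j)
    carrying information from node j to node i."""
    if len(edges) == 0:
        return (np.zeros((0, EDGE_SCALAR_DIM)), np.zeros((0, EDGE_VECTOR_DIM, 3)))
    i, j = edges[:, 0], edges[:, 1]
    diff = norm.ca[j] - norm.ca[i]
    dist = np.linalg.norm(diff, axis=1)
    if (dist < 1e-8).any():
        logger.warning("%d coincident CA pairs; zero edge vectors emitted",
                       int((dist < 1e-8).sum()))
    vec = _safe_unit(diff)[:, None, :]
    scal = np.concatenate([_rbf(dist), _positional_encoding((j - i).astype(float))],
                          axis=1)
    return scal, vec


def assemble_contact_graphs(complex_: ComplexStructure, K: int = 20,
                            R: float = 10.0, equivariant_max: bool = False,
                            sasa_points: int = 960) -> ContactGraphPair:
    """Full featurization: centre, build both graphs, compute all features."""
    if complex_.per_residue_sasa is None or complex_.interface_set is None:
        annotate_surface(complex_, n_points=sasa_points)
    norm = normalize_coordinates(complex_)
    knn = build_knn_graph(norm, K)
    rad = build_radius_graph(norm, R)
    ns, nv = node_features(norm, complex_, equivariant_max)
    ks, kv = edge_features(norm, knn)
    rs, rv = edge_features(norm, rad)
    return ContactGraphPair(
        n_nodes=len(complex_), knn_edges=knn, radius_edges=rad,
        node_scalar=ns, node_vector=nv,
        knn_edge_scalar=ks, knn_edge_vector=kv,
        radius_edge_scalar=rs, radius_edge_vector=rv,
        K=K, R=R)


def save_graph_archive(pair: ContactGraphPair, path) -> None:
    """Self-describing compressed archive (npz + JSON manifest)."""
    manifest = json.dumps({
        "layout_version": pair.layout_version, "K": pair.K, "R": pair.R,
        "n_nodes": pair.n_nodes})
    np.savez_compressed(
        path, manifest=np.array(manifest),
        knn_edges=pair.knn_edges, radius_edges=pair.radius_edges,
        node_scalar=pair.node_scalar, node_vector=pair.node_vector,
        knn_edge_scalar=pair.knn_edge_scalar, knn_edge_vector=pair.knn_edge_vector,
        radius_edge_scalar=pair.radius_edge_scalar,
        radius_edge_vector=pair.radius_edge_vector)


def load_graph_archive(path) -> ContactGraphPair:
    with np.load(path, allow_pickle=False) as z:
        manifest = json.loads(str(z["manifest"]))
        if manifest["layout_version"] != FEATURE_LAYOUT_VERSION:
            raise ValueError(
                f"feature layout version mismatch: archive has "
                f"{manifest['layout_version']}, library expects "
                f"{FEATURE_LAYOUT_VERSION}")
        return ContactGraphPair(
            n_nodes=manifest["n_nodes"],
            knn_edges=z["knn_edges"], radius_edges=z["radius_edges"],
            node_scalar=z["node_scalar"], node_vector=z["node_vector"],
            knn_edge_scalar=z["knn_edge_scalar"],
            knn_edge_vector=z["knn_edge_vector"],
            radius_edge_scalar=z["radius_edge_scalar"],
            radius_edge_vector=z["radius_edge_vector"],
            K=manifest["K"], R=manifest["R"])


class GraphFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer from parsed complexes to featurized contact-graph pairs.

    Stateless (fit is a no-op); exists so featurization composes with
    scikit-learn pipelines and carries its parameters explicitly.
    """

    def __init__(self, K: int = 20, R: float = 10.0,
                 equivariant_max: bool = False, sasa_points: int = 960,
                 interface_cutoff: float = 1.0):
        self.K = K
        self.R = R
        self.equivariant_max = equivariant_max
        self.sasa_points = sasa_points
        self.interface_cutoff = interface_cutoff

    def fit(self, X, y=None):
        self.n_features_in_ = NODE_SCALAR_DIM
        return self

    def transform(self, X):
        out = []
        for cx in X:
            if cx.per_residue_sasa is None or cx.interface_set is None:
                annotate_surface(cx, cutoff=self.interface_cutoff,
                                 n_points=self.sasa_points)
            out.append(assemble_contact_graphs(
                cx, K=self.K, R=self.R, equivariant_max=self.equivariant_max,
                sasa_points=self.sasa_points))
        return out
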