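"""Masked-corruption pre-training of the GEE encoder.

Each epoch, every complex is corrupted afresh ("on-the-fly"): 15% of its
residues (at least one) are masked, a per-complex noise scale sigma is drawn
uniformly from [0.1, 1.0] A, and i.i.d. zero-mean Gaussian noise of that
scale is added to every backbone and side-chain coordinate of the masked
residues. The masked residues' amino-acid one-hot and SASA input channels
are zeroed so identity and surface recovery are non-trivial. Contact graphs
are rebuilt from the corrupted coordinates.

Four heads read the masked residues' embeddings and recover clean
properties: the C-alpha displacement and the side-chain centroid
displacement (vector-valued, equivariant GVP heads), the clean relative
SASA, and the amino-acid type (invariant scalar MLPs). The training
objective is the unweighted sum MSE_Ca + MSE_Sidec + MSE_SASA + BCE_AA,
minimized with Adam (lr 1e-3) for at most 100 epochs with early stopping
after 30 epochs without validation improvement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor
from .graphs import (ContactGraphPair, assemble_contact_graphs, edge_features,
                     node_features, normalize_coordinates)
from .gvp import GVP, MLP, SV, Module
from .structure import AA_INDEX, ComplexStructure, ResidueStructure

logger = logging.getLogger(__name__)

BCE_EPS = 1e-7


@dataclass
class CorruptionRecord:
    mask: np.ndarray              # (N,) bool
    mask_indices: np.ndarray      # (m,) int
    sigma: float                  # noise scale drawn for this complex/epoch
    d_ca: np.ndarray              # (m, 3) clean CA minus corrupted CA
    d_sidechain: np.ndarray       # (m, 3) clean minus corrupted side-chain centroid
    rel_sasa: np.ndarray          # (m,) clean relative SASA targets
    aa_onehot: np.ndarray         # (m, 20)


@dataclass
class LossReport:
    mse_ca: float
    mse_sidechain: float
    mse_sasa: float
    bce_aa: float
    overall: float

    def as_dict(self):
        return {"mse_ca": self.mse_ca, "mse_sidechain": self.mse_sidechain,
                "mse_sasa": self.mse_sasa, "bce_aa": self.bce_aa,
                "overall": self.overall}


def _relative_sasa(complex_: ComplexStructure) -> np.ndarray:
    from .structure import MAX_SASA

    return np.minimum(1.5, np.array([
        complex_.per_residue_sasa[i] / MAX_SASA[r.aa_type]
        for i, r in enumerate(complex_.residues)]))


def corrupt_complex(complex_: ComplexStructure, p: float = 0.15,
                    sigma_range=(0.1, 1.0), rng=None):
    """Corrupt a surface-annotated complex; returns (corrupted, record).

    Unmasked residues are bit-identical. The corrupted complex carries the
    clean SASA/interface annotation (sub-Angstrom noise does not change it
    appreciably, and the SASA head's target is the clean value).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"mask fraction must lie in (0, 1], got {p}")
    if complex_.per_residue_sasa is None or complex_.interface_set is None:
        raise ValueError("corrupt_complex needs a surface-annotated complex")
    rng = rng or np.random.default_rng()
    N = len(complex_)
    n_mask = max(1, int(round(p * N)))
    mask_indices = np.sort(rng.choice(N, size=n_mask, replace=False))
    mask = np.zeros(N, dtype=bool)
    mask[mask_indices] = True
    sigma = float(rng.uniform(*sigma_range))

    residues, d_ca, d_sc = [], [], []
    for i, res in enumerate(complex_.residues):
        if not mask[i]:
            residues.append(res)
            continue
        bb_noise = rng.normal(0.0, sigma, size=res.backbone_coords.shape) \
            if sigma > 0 else np.zeros_like(res.backbone_coords)
        sc_noise = rng.normal(0.0, sigma, size=res.sidechain_coords.shape) \
            if sigma > 0 else np.zeros_like(res.sidechain_coords)
        residues.append(ResidueStructure(
            res.aa_type, res.chain_id, res.author_number,
            res.backbone_coords + bb_noise, res.sidechain_coords + sc_noise,
            res.sidechain_masses.copy(), list(res.sidechain_names)))
        d_ca.append(-bb_noise[1])
        d_sc.append(-sc_noise.mean(axis=0))

    corrupted = ComplexStructure(
        residues, list(complex_.chains), name=complex_.name,
        per_residue_sasa=complex_.per_residue_sasa.copy(),
        interface_set=set(complex_.interface_set))
    aa = np.zeros((n_mask, 20))
    for row, i in enumerate(mask_indices):
        aa[row, AA_INDEX[complex_.residues[i].aa_type]] = 1.0
    record = CorruptionRecord(
        mask=mask, mask_indices=mask_indices, sigma=sigma,
        d_ca=np.array(d_ca), d_sidechain=np.array(d_sc),
        rel_sasa=_relative_sasa(complex_)[mask_indices], aa_onehot=aa)
    return corrupted, record


def apply_input_masking(pair: ContactGraphPair, mask_indices) -> ContactGraphPair:
    """Zero the AA one-hot (0..19) and relative-SASA (27) input channels of
    masked residues so the identity/SASA tasks cannot leak their targets."""
    pair.node_scalar = pair.node_scalar.copy()
    pair.node_scalar[mask_indices, 0:20] = 0.0
    pair.node_scalar[mask_indices, 27] = 0.0
    return pair


class PretrainHeads(Module):
    """Four task heads over the masked residues.

    Vector heads (backbone, side chain) are two-GVP stacks over the final
    embedding tuple, ending in a linear, ungated GVP with a single vector
    channel, so their 3-vector outputs rotate with the input. The SASA and
    identity heads additionally receive the masked residue's raw input
    feature tuple (whose identity/SASA scalar channels the anti-leak rule
    has zeroed) through a GVP whose vector-norm pathway exposes the
    corrupted side-chain geometry invariantly: recovering identity and
    surface area is a property of the residue's own geometry, and routing
    it only through the denoising-shaped embedding buries that signal.
    """

    def __init__(self, seed=1234, node_dims=(256, 16), in_dims=(29 + 45, 9)):
        rng = np.random.default_rng([seed, 77])
        ns, nv = node_dims
        ins, inv = in_dims
        self.bb1 = GVP(rng, node_dims, (ns // 2, nv // 2))
        self.bb2 = GVP(rng, (ns // 2, nv // 2), (1, 1), activations=False,
                       vector_gate=False)
        self.sc1 = GVP(rng, node_dims, (ns // 2, nv // 2))
        self.sc2 = GVP(rng, (ns // 2, nv // 2), (1, 1), activations=False,
                       vector_gate=False)
        skip_dims = (ns + ins, nv + inv)
        self.sasa_gvp = GVP(rng, skip_dims, (ns // 2, 4), h_dim=24)
        self.sasa = MLP(rng, [ns // 2, 1])
        self.aa_gvp = GVP(rng, skip_dims, (ns // 2, 4), h_dim=24)
        self.aa = MLP(rng, [ns // 2, ns // 2, 20])

    def __call__(self, embeddings: SV, mask_indices, aa_mode="bce",
                 inputs: SV | None = None):
        idx = np.asarray(mask_indices, dtype=np.intp)
        sub = SV(embeddings.s[idx], embeddings.v[idx])
        ca_pred = self.bb2(self.bb1(sub)).v[:, 0, :]
        sc_pred = self.sc2(self.sc1(sub)).v[:, 0, :]
        if inputs is None:
            raise ValueError("SASA/AA heads need the masked residues' input "
                             "feature tuple")
        skip = SV([sub.s, inputs.s], [sub.v, inputs.v])
        sasa_pred = self.sasa(self.sasa_gvp(skip).s)[:, 0]
        aa_logits = self.aa(self.aa_gvp(skip).s)
        if aa_mode == "bce":
            aa_pred = aa_logits.sigmoid()
        elif aa_mode == "softmax":
            shifted = aa_logits - Tensor(aa_logits.data.max(axis=1, keepdims=True))
            e = shifted.exp()
            aa_pred = e / e.sum(axis=1, keepdims=True)
        else:
            raise ValueError(f"unknown aa_mode {aa_mode!r}")
        return {"ca": ca_pred, "sidechain": sc_pred, "sasa": sasa_pred,
                "aa": aa_pred}


def invariant_expansion(v: np.ndarray) -> np.ndarray:
    """Rotation-invariant summary of a vector-channel stack (m, nv, 3):
    per-channel norms plus all pairwise difference norms. Differences of
    position-valued channels recover relative magnitudes (e.g. the
    side-chain centroid to C-alpha distance) that plain channel norms mix
    with the global position."""
    norms = np.linalg.norm(v, axis=-1)
    iu, ju = np.triu_indices(v.shape[1], k=1)
    diffs = np.linalg.norm(v[:, iu, :] - v[:, ju, :], axis=-1)
    return np.concatenate([norms, diffs], axis=1)


def head_forward(encoder, heads: PretrainHeads, pair: ContactGraphPair,
                 record: CorruptionRecord, rng=None, training=False,
                 aa_mode="bce"):
    embeddings = encoder.core_(pair, rng=rng, training=training)
    idx = np.asarray(record.mask_indices, dtype=np.intp)
    vin = pair.node_vector[idx]
    s_in = np.concatenate([pair.node_scalar[idx], invariant_expansion(vin)],
                          axis=1)
    inputs = SV(Tensor(s_in), Tensor(vin))
    return heads(embeddings, record.mask_indices, aa_mode=aa_mode,
                 inputs=inputs)


def compute_multitask_loss(predictions, record: CorruptionRecord,
                           aa_mode="bce"):
    """(loss Tensor for backprop, LossReport of its four components).

    MSE terms average the squared error over masked residues and vector
    components; the AA term is the mean per-channel binary cross-entropy of
    the 20-dim prediction against the one-hot truth (or the categorical
    cross-entropy in softmax mode).
    """
    for key, t in predictions.items():
        if not np.isfinite(t.data).all():
            raise FloatingPointError(
                f"non-finite values in {key} head predictions "
                f"(sigma={record.sigma:.3f}, |mask|={len(record.mask_indices)})")
    d_ca = predictions["ca"] - Tensor(record.d_ca)
    mse_ca = (d_ca * d_ca).mean()
    d_sc = predictions["sidechain"] - Tensor(record.d_sidechain)
    mse_sc = (d_sc * d_sc).mean()
    d_sasa = predictions["sasa"] - Tensor(record.rel_sasa)
    mse_sasa = (d_sasa * d_sasa).mean()
    t = Tensor(record.aa_onehot)
    p = predictions["aa"].clip(BCE_EPS, 1.0 - BCE_EPS)
    if aa_mode == "bce":
        bce = -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()
    else:
        bce = -(t * p.log()).sum(axis=1).mean()
    overall = mse_ca + mse_sc + mse_sasa + bce
    report = LossReport(float(mse_ca.data), float(mse_sc.data),
                        float(mse_sasa.data), float(bce.data),
                        float(overall.data))
    return overall, report


def _featurize_corrupted(corrupted, record, encoder, clean_pair=None):
    """Rebuild graphs/features from corrupted coordinates, then apply the
    anti-leak input masking. With freeze_topology the clean edge lists are
    kept and only features are recomputed."""
    if encoder.freeze_topology and clean_pair is not None:
        norm = normalize_coordinates(corrupted)
        ns, nv = node_features(norm, corrupted, encoder.equivariant_max)
        ks, kv = edge_features(norm, clean_pair.knn_edges)
        rs, rv = edge_features(norm, clean_pair.radius_edges)
        pair = ContactGraphPair(
            n_nodes=len(corrupted), knn_edges=clean_pair.knn_edges,
            radius_edges=clean_pair.radius_edges, node_scalar=ns,
            node_vector=nv, knn_edge_scalar=ks, knn_edge_vector=kv,
            radius_edge_scalar=rs, radius_edge_vector=rv,
            K=encoder.K, R=encoder.R)
    else:
        pair = assemble_contact_graphs(
            corrupted, K=encoder.K, R=encoder.R,
            equivariant_max=encoder.equivariant_max)
    return apply_input_masking(pair, record.mask_indices)


@dataclass
class EpochRecord:
    epoch: int
    train: dict
    val_overall: float
    sigmas: list = field(default_factory=list)


def pretrain(encoder, corpus, heads: PretrainHeads | None = None):
    """Run the multi-task pre-training loop; mutates encoder.core_ in place.

    Returns (heads, history). Complexes that fail featurization are skipped
    with a warning; per-epoch records go to ``encoder.history_`` and, when
    ``encoder.log_path`` is set, to a JSON-lines file.
    """
    from .structure import annotate_surface

    usable, clean_pairs = [], []
    for cx in corpus:
        try:
            if cx.per_residue_sasa is None or cx.interface_set is None:
                annotate_surface(cx)
            clean_pairs.append(assemble_contact_graphs(
                cx, K=encoder.K, R=encoder.R,
                equivariant_max=encoder.equivariant_max))
            usable.append(cx)
        except Exception as exc:  # noqa: BLE001
            logger.warning("skipping complex %s: %s", cx.name, exc)
    if not usable:
        raise ValueError("no complex in the corpus could be featurized")

    if not hasattr(encoder, "core_"):
        encoder.initialize()
    heads = heads or PretrainHeads(seed=encoder.seed,
                                   node_dims=(encoder.node_scalar,
                                              encoder.node_vector))
    params = encoder.core_.parameters() + heads.parameters()
    opt = Adam(params, lr=encoder.lr)

    split_rng = np.random.default_rng([encoder.seed, 11])
    n_val = max(1, int(round(encoder.val_fraction * len(usable)))) \
        if len(usable) > 1 else 0
    order = split_rng.permutation(len(usable))
    val_ids, train_ids = order[:n_val], order[n_val:]
    if len(train_ids) == 0:
        train_ids, val_ids = order, np.array([], dtype=int)

    best_val = np.inf
    best_state = None
    stale = 0
    history = []
    log_fh = open(encoder.log_path, "w") if encoder.log_path else None
    try:
        for epoch in range(encoder.epochs):
            ep_rng = np.random.default_rng([encoder.seed, 1000 + epoch])
            terms = []
            sigmas = []
            for k in ep_rng.permutation(train_ids):
                cx, pair0 = usable[k], clean_pairs[k]
                corrupted, record = corrupt_complex(
                    cx, p=encoder.mask_fraction,
                    sigma_range=encoder.sigma_range, rng=ep_rng)
                sigmas.append(record.sigma)
                pair = _featurize_corrupted(corrupted, record, encoder, pair0)
                preds = head_forward(encoder, heads, pair, record,
                                     rng=ep_rng, training=True,
                                     aa_mode=encoder.aa_loss)
                loss, report = compute_multitask_loss(preds, record,
                                                      encoder.aa_loss)
                opt.zero_grad()
                loss.backward()
                clip = getattr(encoder, "grad_clip", 0.0)
                if clip:
                    # global-norm clipping: single-complex steps occasionally
                    # spike (large sigma draws) and can derail the trajectory
                    g2 = sum(float((p.grad**2).sum()) for p in params
                             if p.grad is not None)
                    scale = min(1.0, clip / (np.sqrt(g2) + 1e-12))
                    if scale < 1.0:
                        for p in params:
                            if p.grad is not None:
                                p.grad *= scale
                opt.step()
                terms.append(report.as_dict())
            train_mean = {k: float(np.mean([t[k] for t in terms]))
                          for k in terms[0]}

            if len(val_ids) > 0:
                val_losses = []
                for k in val_ids:
                    # fixed validation corruption (same masks and noise every
                    # epoch) so the early-stopping signal tracks the model,
                    # not the luck of the epoch's sigma draw
                    val_rng = np.random.default_rng([encoder.seed, 500 + int(k)])
                    corrupted, record = corrupt_complex(
                        usable[k], p=encoder.mask_fraction,
                        sigma_range=encoder.sigma_range, rng=val_rng)
                    pair = _featurize_corrupted(corrupted, record, encoder,
                                                clean_pairs[k])
                    preds = head_forward(encoder, heads, pair, record,
                                         training=False,
                                         aa_mode=encoder.aa_loss)
                    _, report = compute_multitask_loss(preds, record,
                                                       encoder.aa_loss)
                    val_losses.append(report.overall)
                val_overall = float(np.mean(val_losses))
            else:
                val_overall = train_mean["overall"]

            rec = EpochRecord(epoch=epoch, train=train_mean,
                              val_overall=val_overall, sigmas=sigmas)
            history.append(rec)
            if log_fh:
                log_fh.write(json.dumps({
                    "epoch": epoch, **{f"train_{k}": v
                                       for k, v in train_mean.items()},
                    "val_overall": val_overall, "sigmas": sigmas}) + "\n")
                log_fh.flush()

            if val_overall < best_val - 1e-9:
                best_val = val_overall
                best_state = {**encoder.core_.state_arrays("core."),
                              **heads.state_arrays("heads.")}
                best_state = {k: v.copy() for k, v in best_state.items()}
                stale = 0
            else:
                stale += 1
                if stale >= encoder.patience:
                    logger.info("early stopping at epoch %d", epoch)
                    break
    finally:
        if log_fh:
            log_fh.close()

    if best_state is not None:
        encoder.core_.load_state_arrays(
            {k[len("core."):]: v for k, v in best_state.items()
             if k.startswith("core.")})
        heads.load_state_arrays(
            {k[len("heads."):]: v for k, v in best_state.items()
             if k.startswith("heads.")})
    encoder.history_ = history
    encoder.heads_ = heads
    return heads, history


def masked_aa_accuracy(encoder, heads, complexes, seed=0, repeats=1):
    """Fraction of masked residues whose AA class is recovered (argmax)."""
    rng = np.random.default_rng([seed, 4242])
    hits = total = 0
    for _ in range(repeats):
        for cx in complexes:
            corrupted, record = corrupt_complex(
                cx, p=encoder.mask_fraction, sigma_range=encoder.sigma_range,
                rng=rng)
            pair = _featurize_corrupted(corrupted, record, encoder)
            preds = head_forward(encoder, heads, pair, record,
                                 training=False, aa_mode=encoder.aa_loss)
            pred_class = preds["aa"].data.argmax(axis=1)
            true_class = record.aa_onehot.argmax(axis=1)
            hits += int((pred_class == true_class).sum())
            total += len(true_class)
    return hits / max(1, total)


def backbone_denoising_rmse(encoder, heads, complexes, seed=0):
    """(model RMSE, injected-noise RMS) over the masked C-alpha displacements."""
    rng = np.random.default_rng([seed, 515])
    se_model, se_noise, n = 0.0, 0.0, 0
    for cx in complexes:
        corrupted, record = corrupt_complex(
            cx, p=encoder.mask_fraction, sigma_range=encoder.sigma_range,
            rng=rng)
        pair = _featurize_corrupted(corrupted, record, encoder)
        preds = head_forward(encoder, heads, pair, record, training=False,
                             aa_mode=encoder.aa_loss)
        se_model += float(((preds["ca"].data - record.d_ca) ** 2).sum())
        se_noise += float((record.d_ca ** 2).sum())
        n += record.d_ca.size
    return np.sqrt(se_model / n), np.sqrt(se_noise / n)
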