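"""The GEE encoder as a scikit-learn style transformer.

`GEEEncoder.fit(corpus)` runs the four-task masked-corruption pre-training
(see :mod:`ppiddg.pretrain`); `transform` maps featurized contact-graph
pairs to per-residue embeddings. An encoder can also be used unfitted after
`initialize()` — the random GVP stack is already a rotation-robust feature
map, and the downstream decoder can be trained on top of it.

Checkpoints are versioned npz containers holding a JSON config manifest and
all parameter arrays; loading refuses a mismatched feature-layout version.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .graphs import FEATURE_LAYOUT_VERSION, ContactGraphPair
from .gvp import SV, GEEEncoderCore

CHECKPOINT_VERSION = 1


class GEEEncoder(BaseEstimator, TransformerMixin):
    """Five-layer multi-relational geometric-equivariant encoder.

    Parameters mirror the published architecture: node feature widths
    (256 scalar, 16 vector), edge widths (32, 1), five layers, dropout 0.1,
    seed 1234. Pre-training hyperparameters (Adam lr 1e-3, up to 100 epochs,
    early stopping after 30 stale epochs, 15% masking, per-epoch corruption)
    are estimator parameters so that `fit` is self-contained.
    """

    def __init__(self, n_layers: int = 5, node_scalar: int = 256,
                 node_vector: int = 16, edge_scalar: int = 32,
                 edge_vector: int = 1, drop_rate: float = 0.1,
                 seed: int = 1234, lr: float = 1e-3, epochs: int = 100,
                 patience: int = 30, mask_fraction: float = 0.15,
                 grad_clip: float = 1.0,
                 sigma_range: tuple = (0.1, 1.0), K: int = 20, R: float = 10.0,
                 equivariant_max: bool = False, freeze_topology: bool = False,
                 aa_loss: str = "bce", val_fraction: float = 0.1,
                 log_path=None):
        self.n_layers = n_layers
        self.node_scalar = node_scalar
        self.node_vector = node_vector
        self.edge_scalar = edge_scalar
        self.edge_vector = edge_vector
        self.drop_rate = drop_rate
        self.seed = seed
        self.lr = lr
        self.epochs = epochs
        self.patience = patience
        self.mask_fraction = mask_fraction
        self.grad_clip = grad_clip
        self.sigma_range = sigma_range
        self.K = K
        self.R = R
        self.equivariant_max = equivariant_max
        self.freeze_topology = freeze_topology
        self.aa_loss = aa_loss
        self.val_fraction = val_fraction
        self.log_path = log_path

    # ------------------------------------------------------------------
    def initialize(self) -> "GEEEncoder":
        """Build the (randomly initialized) encoder core without training."""
        self.core_ = GEEEncoderCore(
            seed=self.seed, n_layers=self.n_layers,
            node_dims=(self.node_scalar, self.node_vector),
            edge_dims=(self.edge_scalar, self.edge_vector),
            drop_rate=self.drop_rate)
        self.history_ = []
        return self

    def fit(self, X, y=None):
        """Pre-train on a corpus of :class:`ComplexStructure` objects."""
        from .pretrain import pretrain

        self.initialize()
        if self.epochs > 0:
            pretrain(self, X)
        return self

    # ------------------------------------------------------------------
    def encode(self, pair: ContactGraphPair) -> SV:
        """Residue-level (scalar, vector) embeddings, eval mode."""
        self._check_core()
        if pair.layout_version != FEATURE_LAYOUT_VERSION:
            raise ValueError("feature layout version mismatch")
        return self.core_(pair, training=False)

    def transform(self, X):
        """List of contact-graph pairs -> list of (N_i, 256) scalar arrays."""
        return [self.encode(p).s.data.copy() for p in X]

    def _check_core(self):
        if not hasattr(self, "core_"):
            raise RuntimeError("encoder not initialized; call fit or initialize")

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        self._check_core()
        manifest = json.dumps({
            "checkpoint_version": CHECKPOINT_VERSION,
            "feature_layout_version": FEATURE_LAYOUT_VERSION,
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()
                       if k != "log_path"},
        })
        arrays = self.core_.state_arrays("core.")
        np.savez_compressed(path, manifest=np.array(manifest), **arrays)

    @classmethod
    def load(cls, path) -> "GEEEncoder":
        with np.load(path, allow_pickle=False) as z:
            manifest = json.loads(str(z["manifest"]))
            if manifest["feature_layout_version"] != FEATURE_LAYOUT_VERSION:
                raise ValueError(
                    "checkpoint was written for feature layout "
                    f"{manifest['feature_layout_version']}; this library uses "
                    f"{FEATURE_LAYOUT_VERSION}")
            params = manifest["params"]
            params["sigma_range"] = tuple(params["sigma_range"])
            enc = cls(**params)
            enc.initialize()
            arrays = {k[len("core."):]: z[k] for k in z.files if k.startswith("core.")}
            enc.core_.load_state_arrays(arrays)
        return enc

    def checkpoint_hash(self) -> str:
        """Stable digest of the parameter arrays, for model manifests."""
        import hashlib

        self._check_core()
        h = hashlib.sha256()
        for key, arr in sorted(self.core_.state_arrays().items()):
            h.update(key.encode())
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]


def encode_complex(pair: ContactGraphPair, encoder: GEEEncoder) -> np.ndarray:
    """Functional form: featurized pair -> (N, 256) scalar embedding matrix."""
    return encoder.encode(pair).s.data.copy()
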