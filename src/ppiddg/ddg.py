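"""Pooled WT/MT comparison representations and the gradient-boosted
binding-affinity-change decoder.

For one mutation sample the wild-type (WT) and mutant (MT) complexes are
featurized and encoded; the per-residue scalar embeddings are then pooled
into eleven named 256-dim blocks: channel-wise max and mean over the
mutation sites and over the WT interface sites, in both structures, the two
WT-minus-MT differences over the mutation sites, and the global mean of the
MT complex. Their concatenation (2816-dim) is the input of a
gradient-boosted-trees regressor whose output is the predicted ddG with the
wild-type-minus-mutant sign convention (ddG = dG_WT - dG_MT).

Only scalar embedding channels are pooled: ddG is a physical scalar and
must not depend on the global orientation of either structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import GradientBoostingRegressor

from .encoder import GEEEncoder
from .graphs import GraphFeaturizer
from .structure import ComplexStructure, annotate_surface, read_pdb_complex

logger = logging.getLogger(__name__)

POOL_BLOCKS = ["wt_mut_max", "wt_mut_mean", "wt_int_max", "wt_int_mean",
               "mt_mut_max", "mt_mut_mean", "mt_int_max", "mt_int_mean",
               "diff_mut_max", "diff_mut_mean", "mt_global_mean"]

SIGN_CONVENTION = "ddG = dG_WT - dG_MT"


class AlignmentError(ValueError):
    """WT and MT structures cannot be put in residue correspondence."""


@dataclass
class MutationSample:
    sample_id: str
    mutations: list                     # (chain, author_number, wt_aa, mt_aa)
    wt_path: str | None = None
    mt_path: str | None = None
    wt_structure: ComplexStructure | None = None
    mt_structure: ComplexStructure | None = None
    ddg_label: float | None = None
    complex_type: str | None = None
    mutation_indices: np.ndarray | None = None   # resolved S^mutation
    interface_indices: np.ndarray | None = None  # resolved WT S^interface

    def load(self, strict: bool = False) -> "MutationSample":
        if self.wt_structure is None:
            self.wt_structure = read_pdb_complex(self.wt_path, strict=strict)
        if self.mt_structure is None:
            self.mt_structure = read_pdb_complex(self.mt_path, strict=strict)
        return self


def parse_mutation_string(text: str) -> list:
    """Parse "A:23:K>R" (comma-separated for multi-point mutations)."""
    out = []
    for part in str(text).split(","):
        part = part.strip()
        try:
            chain, pos, swap = part.split(":")
            wt_aa, mt_aa = swap.split(">")
        except ValueError:
            raise ValueError(
                f"malformed mutation {part!r}; expected chain:pos:wt>mt") from None
        out.append((chain.strip(), pos.strip(), wt_aa.strip().upper(),
                    mt_aa.strip().upper()))
    if not out:
        raise ValueError("empty mutation list")
    return out


def resolve_sample(sample: MutationSample) -> MutationSample:
    """Resolve mutation sites to global indices and validate WT/MT alignment.

    WT and MT must have equal residue counts and align position-by-position
    on (chain, author number); insertions or deletions are rejected.
    """
    sample.load()
    wt, mt = sample.wt_structure, sample.mt_structure
    if len(wt) != len(mt):
        raise AlignmentError(
            f"{sample.sample_id}: WT has {len(wt)} residues, MT {len(mt)}")
    for i, (rw, rm) in enumerate(zip(wt.residues, mt.residues)):
        if (rw.chain_id, rw.author_number) != (rm.chain_id, rm.author_number):
            raise AlignmentError(
                f"{sample.sample_id}: residue {i} is {rw.chain_id}"
                f"{rw.author_number} in WT but {rm.chain_id}{rm.author_number} "
                f"in MT")
    lookup = {(r.chain_id, r.author_number): i for i, r in enumerate(wt.residues)}
    indices = []
    for chain, pos, wt_aa, mt_aa in sample.mutations:
        key = (chain, pos)
        if key not in lookup:
            raise AlignmentError(
                f"{sample.sample_id}: no residue {chain}:{pos} in WT structure")
        i = lookup[key]
        if wt.residues[i].aa_type != wt_aa:
            raise AlignmentError(
                f"{sample.sample_id}: WT structure has "
                f"{wt.residues[i].aa_type} at {chain}:{pos}, table says {wt_aa}")
        indices.append(i)
    sample.mutation_indices = np.array(sorted(set(indices)), dtype=np.intp)
    if wt.interface_set is None:
        annotate_surface(wt)
    sample.interface_indices = np.array(sorted(wt.interface_set), dtype=np.intp)
    return sample


def pool_representations(r_wt: np.ndarray, r_mt: np.ndarray,
                         mutation_indices, interface_indices) -> dict:
    """The eleven named 256-dim pooling blocks (see module docstring).

    An empty interface yields zero interface blocks with a warning.
    """
    mut = np.asarray(mutation_indices, dtype=np.intp)
    inter = np.asarray(interface_indices, dtype=np.intp)
    if len(mut) == 0:
        raise ValueError("empty mutation set")
    for idx, r in ((mut, r_wt), (mut, r_mt), (inter, r_wt)):
        if len(idx) and (idx.min() < 0 or idx.max() >= len(r)):
            raise IndexError("pooling index out of range")
    d = r_wt.shape[1]

    def pools(r, idx):
        if len(idx) == 0:
            return np.zeros(d), np.zeros(d)
        return r[idx].max(axis=0), r[idx].mean(axis=0)

    if len(inter) == 0:
        logger.warning("empty interface set; interface blocks are zero")
    blocks = {}
    blocks["wt_mut_max"], blocks["wt_mut_mean"] = pools(r_wt, mut)
    blocks["wt_int_max"], blocks["wt_int_mean"] = pools(r_wt, inter)
    blocks["mt_mut_max"], blocks["mt_mut_mean"] = pools(r_mt, mut)
    blocks["mt_int_max"], blocks["mt_int_mean"] = pools(r_mt, inter)
    blocks["diff_mut_max"] = blocks["wt_mut_max"] - blocks["mt_mut_max"]
    blocks["diff_mut_mean"] = blocks["wt_mut_mean"] - blocks["mt_mut_mean"]
    blocks["mt_global_mean"] = r_mt.mean(axis=0)
    return blocks


def concat_blocks(blocks: dict) -> np.ndarray:
    return np.concatenate([blocks[k] for k in POOL_BLOCKS])


class DdgRegressor(BaseEstimator, RegressorMixin):
    """End-to-end ddG predictor: featurize, encode, pool, boost.

    Parameters
    ----------
    encoder : GEEEncoder or None
        A (pre-trained or freshly initialized) encoder; None builds a
        default encoder with random weights, which is already a usable
        rotation-robust feature map.
    gbt_lr, gbt_estimators, gbt_depth : float, int, int
        Gradient-boosting hyperparameters; defaults follow the published
        setting (0.001, 50000, 6). Tests and desk-scale runs pass smaller
        estimator counts.
    """

    def __init__(self, encoder: GEEEncoder | None = None,
                 gbt_lr: float = 0.001, gbt_estimators: int = 50_000,
                 gbt_depth: int = 6, gbt_max_features=None,
                 gbt_subsample: float = 1.0, seed: int = 1234,
                 K: int = 20, R: float = 10.0,
                 equivariant_max: bool = False):
        self.encoder = encoder
        self.gbt_lr = gbt_lr
        self.gbt_estimators = gbt_estimators
        self.gbt_depth = gbt_depth
        self.gbt_max_features = gbt_max_features
        self.gbt_subsample = gbt_subsample
        self.seed = seed
        self.K = K
        self.R = R
        self.equivariant_max = equivariant_max

    # ------------------------------------------------------------------
    def _encoder(self) -> GEEEncoder:
        if not hasattr(self, "encoder_"):
            enc = self.encoder
            if enc is None:
                enc = GEEEncoder(seed=self.seed, K=self.K, R=self.R,
                                 equivariant_max=self.equivariant_max)
            if not hasattr(enc, "core_"):
                enc.initialize()
            self.encoder_ = enc
        return self.encoder_

    def _featurizer(self) -> GraphFeaturizer:
        return GraphFeaturizer(K=self.K, R=self.R,
                               equivariant_max=self.equivariant_max)

    def sample_features(self, sample: MutationSample) -> np.ndarray:
        """2816-dim pooled comparison representation for one sample."""
        if sample.mutation_indices is None:
            resolve_sample(sample)
        feat = self._featurizer()
        enc = self._encoder()
        wt, mt = sample.wt_structure, sample.mt_structure
        if mt.interface_set is None:
            # interface is defined under the WT status and index-transferred;
            # the mutant still gets its own SASA feature
            if mt.per_residue_sasa is None:
                from .structure import compute_sasa

                mt.per_residue_sasa = compute_sasa(mt)
            mt.interface_set = set(wt.interface_set)
        pair_wt, pair_mt = feat.transform([wt, mt])
        r_wt, r_mt = enc.transform([pair_wt, pair_mt])
        blocks = pool_representations(r_wt, r_mt, sample.mutation_indices,
                                      sample.interface_indices)
        return concat_blocks(blocks)

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        """X: list of MutationSample (or precomputed (n, 2816) matrix)."""
        if y is None:
            y = [s.ddg_label for s in X]
            if any(v is None for v in y):
                raise ValueError("fit requires ddg labels on every sample")
        y = np.asarray(y, dtype=float)
        if len(y) < 10:
            raise ValueError(f"need at least 10 labelled samples, got {len(y)}")
        F = (np.asarray(X, dtype=float) if isinstance(X, np.ndarray)
             else np.vstack([self.sample_features(s) for s in X]))
        if np.allclose(y.var(), 0.0):
            logger.warning("zero-variance labels; decoder degenerates to a "
                           "constant model")
        self.gbt_ = GradientBoostingRegressor(
            learning_rate=self.gbt_lr, n_estimators=self.gbt_estimators,
            max_depth=self.gbt_depth, max_features=self.gbt_max_features,
            subsample=self.gbt_subsample,
            random_state=self.seed % (2**31))
        self.gbt_.fit(F, y)
        self.n_features_in_ = F.shape[1]
        self.sign_convention_ = SIGN_CONVENTION
        self.encoder_hash_ = self._encoder().checkpoint_hash()
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "gbt_"):
            raise RuntimeError("regressor not fitted")
        F = (np.asarray(X, dtype=float) if isinstance(X, np.ndarray)
             else np.vstack([self.sample_features(s) for s in X]))
        return self.gbt_.predict(F)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        import joblib

        joblib.dump({"manifest": {
            "sign_convention": self.sign_convention_,
            "encoder_hash": self.encoder_hash_,
            "feature_layout_version": 1,
            "params": {k: v for k, v in self.get_params(deep=False).items()
                       if k != "encoder"}},
            "gbt": self.gbt_}, path)

    @classmethod
    def load(cls, path, encoder: GEEEncoder | None = None) -> "DdgRegressor":
        import joblib

        blob = joblib.load(path)
        model = cls(encoder=encoder, **blob["manifest"]["params"])
        model.gbt_ = blob["gbt"]
        model.sign_convention_ = blob["manifest"]["sign_convention"]
        model.encoder_hash_ = blob["manifest"]["encoder_hash"]
        if encoder is not None and hasattr(encoder, "core_"):
            if encoder.checkpoint_hash() != model.encoder_hash_:
                raise ValueError(
                    "model was trained with a different encoder checkpoint "
                    f"(expected hash {model.encoder_hash_})")
        return model


def fit_gbt(features: np.ndarray, labels, gbt_lr=0.001, gbt_estimators=50_000,
            gbt_depth=6, gbt_max_features=None,
            seed=1234) -> GradientBoostingRegressor:
    """Thin functional wrapper: fit the GBT decoder on pooled features."""
    reg = DdgRegressor(gbt_lr=gbt_lr, gbt_estimators=gbt_estimators,
                       gbt_depth=gbt_depth, gbt_max_features=gbt_max_features,
                       seed=seed)
    reg.fit(np.asarray(features), np.asarray(labels))
    return reg.gbt_


def predict_ddg(model: DdgRegressor, sample: MutationSample) -> float:
    """End-to-end prediction for one sample (sign: dG_WT - dG_MT)."""
    return float(model.predict([sample])[0])


def split_by_complex_type(samples, n_folds: int = 5, rng=None) -> np.ndarray:
    """Greedy balanced fold assignment with disjoint complex types.

    Types are sorted by sample count (descending; ties shuffled by `rng`)
    and each type is assigned wholly to the currently smallest fold, so no
    two folds share a WT complex type. Returns the fold index per sample.
    """
    types = [getattr(s, "complex_type", None) if not isinstance(s, dict)
             else s.get("complex_type") for s in samples]
    if any(t is None for t in types):
        raise ValueError("every sample needs a complex_type")
    uniq, counts = np.unique(types, return_counts=True)
    if len(uniq) < n_folds:
        raise ValueError(
            f"{len(uniq)} complex types cannot fill {n_folds} disjoint folds")
    rng = rng or np.random.default_rng(0)
    perm = rng.permutation(len(uniq))
    order = perm[np.argsort(-counts[perm], kind="stable")]
    fold_of_type = {}
    fold_sizes = np.zeros(n_folds, dtype=int)
    for t in order:
        f = int(np.argmin(fold_sizes))
        fold_of_type[uniq[t]] = f
        fold_sizes[f] += counts[t]
    logger.info("fold sizes after greedy assignment: %s", fold_sizes.tolist())
    return np.array([fold_of_type[t] for t in types], dtype=int)


# ---------------------------------------------------------------------------
# mutation-table and prediction CSV dialects

def read_mutation_table(path, base_dir=None) -> list:
    """CSV with header sample_id,wt_pdb,mt_pdb,mutations[,ddg[,complex_type]]."""
    from pathlib import Path

    df = pd.read_csv(path)
    required = ["sample_id", "wt_pdb", "mt_pdb", "mutations"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table is missing columns: {missing}")
    base = Path(base_dir) if base_dir else Path(path).parent
    samples = []
    for _, row in df.iterrows():
        wt = Path(row["wt_pdb"])
        mt = Path(row["mt_pdb"])
        samples.append(MutationSample(
            sample_id=str(row["sample_id"]),
            mutations=parse_mutation_string(row["mutations"]),
            wt_path=str(wt if wt.is_absolute() else base / wt),
            mt_path=str(mt if mt.is_absolute() else base / mt),
            ddg_label=(float(row["ddg"]) if "ddg" in df.columns
                       and pd.notna(row["ddg"]) else None),
            complex_type=(str(row["complex_type"])
                          if "complex_type" in df.columns
                          and pd.notna(row["complex_type"])
                          else str(row["wt_pdb"]))))
    return samples


def write_predictions(samples, predictions, path) -> None:
    pd.DataFrame({
        "sample_id": [s.sample_id for s in samples],
        "ddg_pred": np.asarray(predictions, dtype=float),
        "sign_convention": SIGN_CONVENTION,
    }).to_csv(path, index=False)
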