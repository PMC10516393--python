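# Methods

`ppiddg` predicts the change in binding free energy (ΔΔG, kcal/mol, sign
convention ΔΔG = ΔG<sup>WT</sup> − ΔG<sup>MT</sup>) caused by amino-acid
mutations in a protein–protein complex, from the wild-type (WT) and mutant
(MT) 3-D structures alone. This note documents the model, its assumptions,
the numerical conventions, and what the synthetic test bed does and does
not demonstrate.

## Dual contact-graph featurization

A complex is reduced to one residue node per standard amino acid, located
at its Cα. Two relations are built over the same nodes:

* **KNN graph** — each node receives directed edges from its K = 20 nearest
  residues (Euclidean Cα distance). Ties are broken by lower residue index
  after rounding distances to 10⁻⁶ Å, so the topology is stable under
  rigid motions of the input. For N ≤ K the in-degree caps at N − 1.
* **Radius graph** — symmetric edges between all pairs within R = 10 Å,
  with the same rounding convention. Isolated nodes are permitted.

All coordinates are first centred on the centroid of the backbone (N, Cα,
C, O) atoms, which makes every feature exactly translation-invariant.

Node features (29 scalars, 9 vector channels): amino-acid one-hot (20);
chain index (ordinal position ÷ max(1, n_chains−1)); sin/cos of φ, ψ, ω
computed within chains with exact-zero pads at termini; relative SASA
(per-residue Shrake–Rupley SASA divided by the residue type's theoretical
maximum, clipped at 1.5); interface flag. The vector channels are the
side-chain centroid, centre of mass, and componentwise maximum coordinate;
unit vectors from Cα to the side-chain centroid and centre of mass; the
centred Cα position; unit vectors to the preceding and following Cα of the
same chain (zero at termini); and the unit Cα→Cβ vector. Glycine (or any
residue arriving without side-chain heavy atoms) receives a virtual Cβ
placed 1.522 Å from Cα along the ideal tetrahedral direction, so every
side-chain feature is always defined.

The componentwise max-coordinate channel is not rotation-covariant as
defined; `equivariant_max=True` substitutes the coordinate of the
side-chain atom farthest from Cα (ties to the lower atom index), which is.
The default stays literal; the equivariant surrogate is used where exact
end-to-end equivariance is asserted.

Edge features (32 scalars, 1 vector channel): 16 Gaussian radial basis
functions of the Cα–Cα distance (centres linearly spaced on 0–20 Å, width
equal to the spacing), a 16-dim sinusoidal encoding of the signed residue
index offset j − i, and the unit vector from Cα_i to Cα_j (zero with a
warning for coincident positions).

## SASA and interface residues

SASA uses Shrake–Rupley quadrature with a deterministic golden-spiral
point set (960 points/atom by default, probe 1.4 Å, Bondi van der Waals
radii). The sphere point set is oriented in a canonical frame of the atom
cloud (principal axes with skewness-fixed signs), so computed areas are
exactly invariant under rigid motions rather than invariant only up to
quadrature jitter. A residue is an interface residue when its SASA drops
by more than 1 Å² (configurable) between its chain evaluated in isolation
and in the complex; both states share the complex's quadrature frame so
the difference carries no discretization noise. The interface is defined
on the WT structure and transferred to the MT by residue correspondence.

## The encoder

Features flow through geometric vector perceptrons (GVPs): vector channels
are linearly mixed, their norms join the scalar channels, scalars pass
through a ReLU dense layer, and output vectors are gated by a sigmoid of
the output scalars. Scalars are therefore rotation-invariant and vectors
rotation-covariant by construction.

One encoder layer runs an independent GVP message function per relation on
the concatenation of the source-node tuple and the edge tuple, averages
incoming messages per relation (empty neighbourhoods contribute zeros),
concatenates the two half-width (128 scalar, 8 vector) aggregates back to
node width, and applies two residual stages with layer normalization — the
second around a pointwise feed-forward GVP. Layer normalization on vector
channels rescales all channels of a node by the RMS of their norms,
preserving directions (a per-component affine would break equivariance).
Dropout (rate 0.1, configurable) drops scalar units and whole vector
channels. Node/edge widths are 256/16 and 32/1; inputs are lifted by
linear GVPs; five layers are stacked. Weight initialization is Glorot
uniform from a seeded generator (default seed 1234); all computation is
float64 numpy with an in-repo reverse-mode autodiff core, so results are
bit-reproducible on any platform.

## Masked-corruption pre-training

Per epoch and per complex: 15% of residues (at least one) are masked, a
noise scale σ ~ U[0.1, 1.0] Å is drawn per complex, and i.i.d. zero-mean
Gaussian noise of scale σ is added to every backbone and side-chain
coordinate of the masked residues. The masked residues' amino-acid one-hot
and relative-SASA input channels are zeroed so that identity and surface
recovery are not trivially readable from the inputs. Contact graphs and
all geometric features are rebuilt from the corrupted coordinates
(`freeze_topology=True` keeps the clean edge lists and only recomputes
features); SASA/interface scalars of unmasked residues reuse the clean
values, since sub-Å noise changes them marginally and the SASA task
targets the clean value.

Four heads read the masked residues. Two equivariant GVP stacks over the
final embeddings predict the Cα displacement and the side-chain centroid
displacement (the displacement formulation carries the same information as
the clean centroid given the corrupted input, and is translation-invariant
and rotation-covariant). The SASA and identity heads receive, in addition
to the embedding, the masked residue's own anti-leaked input feature tuple
together with a fixed rotation-invariant expansion of its vector channels
(channel norms and all pairwise difference norms, which contain e.g. the
side-chain-centroid-to-Cα distance). This skip path matters: the three
denoising MSE tasks dominate the shared encoder and, at desk scale,
reshape the embeddings away from identity information, while identity and
surface recovery are properties of the residue's own corrupted geometry.

The loss is the unweighted sum MSE(Cα) + MSE(side chain) + MSE(SASA) +
BCE(AA), with the MSE terms averaged over masked residues and components.
The identity term defaults to a mean per-channel binary cross-entropy
against the one-hot truth; `aa_loss="softmax"` substitutes the categorical
cross-entropy, the natural likelihood for a 20-way identification, which
learns far faster at small step budgets (per-channel BCE spends most of
its gradient on the 19 cold channels and tends to sit at the class
marginal). The synthetic learnability study in the acceptance suite runs
with the softmax option for this reason. Adam with learning rate 10⁻³
runs for up to 100 epochs with early stopping after 30 epochs without
improvement on a seeded 10% validation split whose corruptions are fixed
across epochs (so the early-stopping signal tracks the model rather than
the epoch's σ draw); the best checkpoint is restored. Every epoch is
logged as a JSON-lines record. Each optimization step processes one
complex; gradients are clipped to a global norm of 1.0 (configurable) —
without clipping, occasional large-σ steps can derail the whole
trajectory on an unlucky seed.

## ΔΔG decoding

WT and MT are featurized and encoded in eval mode; only the 256 scalar
channels are pooled, because ΔΔG is a physical scalar and pooling vector
channels would make the prediction depend on the global orientation of
either structure. Eleven 256-dim blocks are concatenated (2816-dim):
max/mean over the mutation sites and over the WT interface sites in both
structures, the two WT−MT differences over the mutation sites, and the
global mean of the MT complex. A gradient-boosted-trees regressor
(scikit-learn; defaults learning rate 0.001, 50 000 estimators, depth 6,
seeded) maps this to ΔΔG. Multi-point mutations pool over the union of
mutated sites. With few training samples and thousands of correlated
channels, full-feature greedy boosting generalizes poorly (the signal is
spread near-linearly over many channels); `gbt_max_features` enables
per-split feature subsampling ("sqrt" in the desk-scale configuration),
which decorrelates the trees and markedly improves held-out correlation. WT/MT structures must align one-to-one on (chain, author
residue number); insertions or deletions are rejected with an error naming
the mismatch. Desk-scale runs and the test suite use reduced estimator
counts with a correspondingly larger learning rate and stochastic
subsampling (e.g. 2000–5000 trees at 0.05, `gbt_subsample=0.7`), which is
a capacity/runtime trade-off, not a change of model.

For evaluation under unseen-complex conditions, `split_by_complex_type`
assigns whole WT complex types to folds greedily (largest type count
first, ties shuffled by the supplied generator, each type to the currently
smallest fold), so no two folds share a complex type.

## The synthetic test bed

The generator emulates exactly the structural properties the pipeline
consumes, not protein physics. Chains are ideal α-helices (rise 1.5
Å/residue, 100°/residue, radius 2.3 Å) with plausible N/C/O placements so
dihedrals are well-defined. Side chains are pseudo-atom clusters marching
radially outward from the Cα; the 20 amino-acid classes map bijectively to
atom counts {3, 5, 7, 9, 11} × base distances {1.5, 3.9, 6.3, 8.7} Å
(0.7 Å spacing within a cluster). The steps are deliberately large so
class identity remains recoverable under the corruption noise of
pre-training *within the one-pass training budget of the desk-scale
study* — the design requirement is solvability of the identity task, not
realistic side-chain dimensions. By default, chains are placed so the closest
inter-chain atom pair sits exactly 2.5 Å apart, guaranteeing a buried-SASA
interface for every seed; explicit axis separations (e.g. 100 Å for a
contact-free control) remain available.

A mutant pair keeps every backbone atom and every other residue untouched
and resamples the mutated site's cluster under the new class law, which
mimics side-chain-repacking mutant generators. The ground-truth label is

    ΔΔG = 0.1 · (vol_WT − vol_MT) + 0.05 · (buriedSASA_WT − buriedSASA_MT)

where vol is atom count × base distance and buriedSASA is the site's
isolated-chain-minus-complex SASA; the weights are fixed constants of the
generator. Optional Gaussian noise can be added; the default corpora are
noiseless.

What passing tests show: the featurization, equivariance, corruption,
optimization and pooling/decoding machinery is correct, the pre-training
tasks are learnable, and the pooled representation carries enough local
structural signal for a GBT to recover a deterministic structural label.
What they do not show: predictive accuracy on real mutations — real side
chains are smaller and chemically diverse, real ΔΔG labels are noisy and
not a simple functional of two structural proxies, and real complexes
have far richer contact topology.

## Numerical conventions and degenerate inputs

* Unit vectors of zero-length differences (chain termini, coincident
  atoms) are exact zero vectors; undefined dihedrals are zero-padded.
* Altlocs resolve to the highest occupancy (ties: first in file);
  hydrogens and deuterium are always stripped; MSE and a small set of
  modified residues map to their parent amino acid, others are skipped
  (strict mode: error). Residues missing any backbone atom are dropped
  with a warning (strict mode: error).
* BCE probabilities are clamped to [10⁻⁷, 1 − 10⁻⁷]; NaN predictions
  raise immediately with the offending head named.
* Checkpoints and graph caches are versioned; loading a mismatched
  feature-layout version is refused.
* Desk-scale study sizes: pre-training learnability uses 50 two-chain
  complexes of 24 residues each for 30 epochs; the end-to-end recovery
  experiment uses 250 labelled pairs (200 train / 50 held out) spread over
  25 WT complex types, also of 24-residue complexes.

## Known limitations

* No mmCIF input, no side-chain rebuilding, no protonation; callers supply
  complete side chains (upstream repair tools) or accept the drop/virtual
  Cβ rules.
* The encoder runs on CPU in float64; it is sized for desk-scale corpora,
  not for large-scale pre-training.
* The literal componentwise-max side-chain feature breaks exact rotation
  covariance of one vector channel (see above); downstream scalar
  embeddings are unaffected in practice, and the equivariant surrogate is
  available where exactness matters.
* WT/MT pairs differing in residue count are rejected rather than aligned.
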