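# Methods

## Model

Drugs and proteins are embedded by two independent two-layer fully
connected towers into a shared d_s-dimensional space.  Each tower is
`Tanh(W¹ · ReLU(BN(W⁰ x + b⁰)) + b¹)`; batch normalization keeps running
mean/variance (momentum 0.1) so that inference is single-sample
well-defined and batch-size independent.  A pair's interaction likelihood
is the cosine similarity of its embeddings, Î = 1 − Φ with Φ the cosine
distance; Tanh bounds every coordinate in (−1, 1) and near-zero-norm
embeddings are treated as an error (they indicate broken training and
would silently corrupt rankings if mapped to a score).

Scoring is embed-once/score-many: all entities are encoded once (m + n
encoder passes), rows are L2-normalized, and the full score matrix is one
matrix product.  This is the linear-time property that makes
catalogue-scale screening feasible.

### Default hyperparameters

| parameter | default | meaning |
|---|---|---|
| d_m | 1024 | Morgan fingerprint bits (radius 2, ECFP4-equivalent) |
| d_t | 1280 | protein feature length |
| d_h | 2048 | tower hidden width |
| d_s | 512 | shared embedding dimension |
| λ | 1/3 | weight of the interaction loss term |
| t | 3 | root of the rank-reciprocal similarity transform |
| learning rate | 1e-5 | Adam, fixed (no schedule, no weight decay, no dropout) |
| max iterations | 2000 | mini-batch optimization steps |
| batch size | 256 | labeled pairs per step |
| negative ratio | 1 | sampled negatives per training positive |

The full-scale defaults suit benchmark-sized corpora.  Synthetic
desk-scale studies use `RunConfig.small()`: d_m=64, d_t=32, d_h=32,
d_s=16, learning rate 1e-3, 600 steps — dimensions small enough that a
study (generate, featurize, train, evaluate) runs in a couple of seconds
on one CPU, with the learning rate raised accordingly since the reduced
problem is far better conditioned than the full-scale one.

## Relative distances

The training target geometry comes from three sources.  Drug–drug:
1 − Dice(fingerprints).  Protein–protein: raw Smith–Waterman scores
(BLOSUM62, affine gaps open 10 / extend 1 — a gap of length L costs
10 + (L−1)) are replaced row-wise by (1/rank)^(1/t), descending dense
ranks with the self-entry excluded and set to similarity 1.  Only the
within-row rank order of the raw scores survives this transform, so the
alignment parameter choice affects ties only; any strictly monotone
per-row rescaling of the raw matrix leaves the output unchanged (tested).
Ties share a dense rank so that equal inputs get equal outputs.  The
transform is row-wise and therefore asymmetric; the loss sums over ordered
pairs, which is equivalent to regressing the symmetric cosine distance on
the mean of the two directed targets.  Drug–protein: 1 − y over *labeled*
pairs only — unlabeled pairs are absent, not assumed negative, consistent
with the negative-sampling protocol.

## Loss and training

GBA loss = mean over ordered in-batch drug pairs of (Φ − RD)² + the same
over protein pairs + λ · mean over the batch's labeled pairs.  The
loss is defined as full sums over all m²/n² pairs, which is
infeasible beyond toy sizes; evaluating all three terms within each
mini-batch with means (rather than sums) is the standard pair-sampling
estimator and keeps λ's effect stable under batch-size changes.  Batches
are shuffled labeled pairs; a trailing short chunk is merged into the
previous batch so every batch retains at least two distinct drugs and
proteins (the prior terms need pairs).  Gradients of the whole pipeline —
cosine terms, row normalization, Tanh, ReLU, batch-norm with batch
statistics — are derived by hand and verified against central-difference
numerical gradients to ~1e-10 in the test suite.  Optimization is Adam
with default moments; "iterations" means optimizer steps.  When a
validation set is supplied, the checkpoint with the best validation AUPR
is restored at the end (AUPR being the imbalance-robust headline metric).
Negative training pairs are sampled uniformly without replacement from the
unlabeled drug × protein universe, once per run, seeded.

The interaction-only (OI) ablation drops the two prior terms and is
exposed as `loss_kind="oi"` / `--loss oi`.

## Evaluation protocol

Random splits are 7:1:2 over labeled pairs.  Cold-start splits hold out
20% of drugs (or proteins) entity-wise and route all their pairs to
test/validation at 70/30; held-out entities never contribute a training
pair.  Imbalanced test sets keep the test positives and add uniformly
sampled negatives from pairs unseen in *any* split until the
positive:negative ratio is exactly 1:r (existing test negatives count
toward r).  AUROC uses the rank-sum half-credit-for-ties convention; AUPR
is the uninterpolated precision–recall step sum (interpolation inflates
AUPR precisely in the imbalanced regime of interest); both are
cross-checked in tests against brute-force all-pairs / step-sum oracles.
Accuracy and F1 need a threshold: the F1-maximizing validation score when
a validation set exists, else 0.5; F1 is defined as 0 when nothing is
predicted positive.  Top-k counts break score ties deterministically by
entity id.

## Synthetic data

The generator plants the one statistical property the GBA prior exploits:
similar drugs interact with similar proteins.  K drug clusters each get a
random binary fingerprint template (density 0.25) copied with independent
per-bit flips (default rate 0.02); L protein clusters are Gaussian centers
(spread 1.0) plus within-cluster noise (std 0.1); a binary K×L block
matrix B (default: identity) decides which blocks interact, and individual
labels follow B with a flip probability (default 0.01).  The default study
size is 200 drugs × 100 proteins in 4×4 clusters — large enough for
meaningful held-out evaluation, small enough that a three-seed study with
both loss variants runs in well under a minute.  A sequence variant emits
proteins as point-mutated copies of per-cluster ancestor sequences, which
exercises the Smith–Waterman + rank-transform path end to end.  For
feature-vector proteins (no sequences) the raw prior similarity is the
cosine similarity of feature vectors; only its within-row order matters
after the rank transform.

What the fixtures do *not* emulate: real chemical space, graded binding
affinities, the degree heterogeneity of curated interaction networks, or
homology structure beyond single-ancestor families.  Tests passing on
them demonstrate that the machinery recovers planted block structure
under noise — not benchmark-level performance.

A note on the ablation at desk scale: on these fixtures the cluster
identity of every entity is fully determined by its input features, and
the similarity networks are computed from those same features, so the
prior terms carry no information that the label-alignment term cannot
already extract; measured held-out AUPR of the full loss and the
interaction-only ablation are equal within seed noise here (the prior is
neutral, with the sign of the tiny difference seed-dependent).  The
prior's advantage is expected to require complementary channels — e.g.
alignment-based protein similarity versus learned sequence features — and
negatives far from the training distribution, neither of which a clean
block model provides.

At the 200×100 study size the pair universe (20,000) cannot supply
r × |test positives| unseen negatives for r = 100, so the imbalanced
evaluation subsamples test positives (seeded) to the largest count the
unseen-pair pool supports and augments around them to the exact ratio.

## Numerical choices and edge cases

* Dice of two all-zero fingerprints is defined as 0 with a warning (an
  empty molecule shares nothing with anything; usually a featurization
  problem upstream).
* Cosine scoring floors norms at 1e-12 — far below any trained Tanh
  embedding, above float rounding — and errors below it.
* Batch-norm epsilon 1e-5; running statistics initialized to (0, 1).
* Weight initialization: Kaiming-normal for the ReLU layer,
  Xavier-uniform for the Tanh layer, from the run's seeded generator.
* Rank ties: dense ranks (ties share a rank); self-similarity excluded
  from ranking and set to 1 (so an entity is never its own rank-1 slot).
* Non-finite training loss aborts with the iteration, learning rate and
  offending batch in the message rather than continuing silently.
* A protein language model adapter (mean-pooled 1280-dim residue
  embeddings) is declared but requires external weights and a deep
  learning runtime; constructing it without them raises an error pointing
  to the hashed k-mer featurizer (k=3, L1-normalized, deterministic) or
  precomputed feature vectors, which are the self-contained paths.

## Known limitations

Binary labels only (graded affinities are out of scope); no structure- or
conformer-based features; single-threaded CPU training (adequate at the
design scale; the towers are two dense layers); the Smith–Waterman matrix
is O(n²) alignments and is intended for protein sets up to a few thousand.
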