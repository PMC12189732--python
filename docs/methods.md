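# Methods

## Problem and model

`crossdti` predicts binary drug–target interactions (DTI) from a compound's
SMILES and a protein's amino-acid sequence, with all computation on a single
CPU. The model is a two-tower cross-modal attention classifier:

1. **Featurization.** Compounds become Morgan (ECFP-style) circular-substructure
   bit vectors after RDKit canonicalization; defaults radius 2, 2048 bits
   (512 in the scaled-down pipeline configuration). Proteins are decomposed
   into non-overlapping k-mers along three reading frames (offsets 0, 1, 2 —
   their union covers every k-mer start position); a skip-gram
   negative-sampling embedder is trained on that k-mer corpus (k = 3, dim 100
   by default; dim 32 in the pipeline configuration) and the protein vector
   is the mean of its k-mer vectors. Out-of-vocabulary k-mers contribute a
   zero vector and are counted in a logged miss counter.
2. **Projection stacks.** Each modality passes through its own three-layer
   affine + ReLU stack into a shared latent space of width p
   (library default p = 1024, pipeline default p = 64):
   `L1 = ReLU(W1ᵀE + b1)`, `L2 = ReLU(W2ᵀL1 + b2)`, `L3 = ReLU(W3ᵀL2 + b3)`.
3. **Dual-headed cross-modal attention.** Head 1 queries with the target
   latent and attends over the compound's keys/values; head 2 mirrors this.
   With `token_count = t` each latent is reshaped into t tokens of width p/t;
   per-head output width is p/(2t) so the two concatenated heads have width p,
   mixed by a global matrix WG (p × p). The softmax scores are scaled by
   √(p/(2t)), which is the √(p/2) scaling at t = 1.
4. **Classifier.** Residual sum `Â = L3_target + L3_compound + A`, layer
   normalisation (gain α, bias β, ε = 1e-5) and a single linear layer emit one
   logit. The sigmoid lives inside a numerically fused BCE loss
   (`max(z,0) − zy + log(1+e^{−|z|})`).
5. **Contrastive fine-tuning.** Triplet hinge on the *projected latents*:
   for an anchor target, an active compound and decoys,
   `mean_k max(0, d(a,p) − d(a,n_k) + m)` with Euclidean d and margin m = 1.
   Per (target, active) pair, 50 decoys are sampled randomly without
   replacement (the whole pool with a logged shortfall when it is smaller).
   Fine-tuning alternates BCE mini-batches with triplet steps weighted by
   `contrastive_weight` (default 1.0); at weight 0 triplet steps are skipped
   entirely so the run is bit-identical to continued pre-training.

All tensors are float64 NumPy; gradients are derived by hand and verified
against central finite differences in the test suite (tolerance 1e-4 on random
parameter subsets). The optimiser is Adam (lr 1e-4 library default, 1e-3 in
the pipeline; batch 64). Mini-batch shuffling and triplet sampling draw from
per-epoch seeded generators, so every training run is bit-reproducible on a
single thread. The retained checkpoint is the epoch with the best validation
PR AUC.

### Design choices where the architecture was open

- **Residual dimensionality.** A residual of raw embeddings (2048- and
  100-dimensional) cannot be added to a p-wide fused vector; the residual
  therefore uses the projected latents L3.
- **Head combination.** The two head outputs (each p/2) are concatenated
  before WG, which gives the "global mixing" matrix a real job; summation
  would reduce WG to a per-head average.
- **Token count.** With one token per modality, the attention softmax is over
  a single key and the weight is exactly 1, so the fused vector is a linear
  (additive) function of the two latents; the classifier then cannot express
  conjunctive interactions between modalities. The library supports this
  faithful single-token form (`token_count=1`, the default of `ModelConfig`)
  and a two-token reshape (`token_count=2`, the pipeline default) in which
  the attention weights genuinely depend on both modalities. Both variants
  are oracle-tested.
- **Triplet latents.** Fine-tuning updates all parameters; the hinge itself
  only touches the projection stacks because distances are computed on L3.

## Synthetic data generator

The generator emulates a DTI benchmark with planted, recoverable interaction
structure:

- A pool of 6 chemical fragment motifs (valid SMILES units that remain valid
  under linear concatenation) and 6 random peptide motifs (length 7).
- Each target is assigned one required fragment and carries each peptide
  motif independently with probability √positive_rate; its sequence is built
  by interleaving intact planted peptides (5 copies each, plus a tag peptide
  that encodes the required-fragment assignment) with random filler segments,
  so no planted occurrence is clobbered.
- Each compound is assigned one peptide motif (encoded by a tag fragment in
  its SMILES) and carries each fragment motif independently with probability
  √positive_rate; its SMILES is the shuffled concatenation of carried
  fragments, the tag and filler units, and always parses.
- A pair is truly positive iff the compound carries the target's fragment AND
  the target carries the compound's motif, so the expected positive fraction
  equals `positive_rate` (default 0.25). Observed labels flip the truth with
  probability `noise_rate`. Pairs receive a seeded 70/15/15
  train/validation/test split.

The tag encodings matter: without them the two assignments are latent
attributes invisible to the features, the planted rule is not a function of
the observable data, and no learner can recover it from held-out pairs. With
them, recovery is a genuine two-modality composition task: the model must
read the compound's fragment content and tag from the fingerprint, the
target's motif content and tag from the k-mer profile, and conjoin them.

What the generator does **not** emulate: real chemistry (compounds are
synthetic concatenations, not drug-like molecules), homology structure among
proteins, assay noise heterogeneity, and the extreme active/decoy imbalance
of real decoy databases. Passing the synthetic experiments therefore
demonstrates that the implementation can learn planted cross-modal structure
end to end — not that it attains any particular accuracy on real benchmark
corpora.

## Preprocessing and numerical choices

- Mean-pooled k-mer embeddings of different proteins have tiny, nearly
  collinear vectors (norms ~1e-2); `featurize_dataset` therefore z-scores
  target embeddings per dimension across the dataset (on by default).
  `embed_protein` itself stays a pure pooling operation.
- Layer-norm ε = 1e-5 guards zero-variance residual sums; a constant-score
  model is reported with a `degenerate_scores` flag rather than an error.
- PR AUC is the step-wise average-precision estimator (no interpolation);
  with constant scores it equals the positive prevalence. ROC AUC counts ties
  as half. Both reject single-class inputs.
- Group comparisons use Welch's unequal-variance one-sided t-test;
  "interacts more strongly" maps to "smaller latent distance", i.e.
  alternative "less". Group sizes and variances differ wildly in the intended
  use (thousands of catalogue compounds vs a dozen clinical drugs), which is
  why the pooled-variance test is not used.
- Ranking tables sort by full-precision 2-D Euclidean distance with
  lexicographic tie-breaks on the compound name and display two decimals;
  the target heads its own table at 0.00. The target is always projected
  jointly with its compounds in one run — distances across separate
  projections are not comparable.
- The 2-D projection is a seeded neighbor embedding (UMAP, n_neighbors 10,
  single-threaded) chosen to preserve local and global structure of the
  latent cloud before distances are measured; parameters are snapshotted into
  the `Projection2D` for reproducibility.

## Problem sizes

The reference synthetic experiment uses 40 targets × 200 compounds
(8,000 pairs, prevalence ≈ 0.25), fingerprints of 512 bits, k-mer dim 32,
p = 64, 60 pre-training epochs and 10 fine-tuning epochs — sizes chosen so a
full run (including the label-permuted null control) completes in about a
minute on one CPU while leaving the planted structure clearly recoverable
(held-out PR AUC ≈ 0.92–0.97 across seeds). The library defaults (p = 1024,
2048-bit fingerprints, dim-100 k-mer vectors) match the published
configuration of the method and are intended for real corpora.

## Known limitations

- Training is plain NumPy: adequate at desk scale, not for the full
  ~400k-pair decoy corpora of real benchmarks.
- Skip-gram embeddings are retrained per corpus; no pre-trained protein
  vectors ship with the package (a saved table can be loaded instead).
- The 2-D projection step is inherently stochastic-looking across library
  versions even when seeded; published distance tables from real data are
  therefore not bit-reproduced, only the procedure is.
- Decoy sampling assumes decoys are true non-binders; label noise among
  decoys is not modelled.
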