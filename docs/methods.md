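# Methods

## Problem setting

`mtmolgen` studies generative design of multi-target (polypharmacological)
ligands under severe data scarcity. The motivating task is simultaneous
inhibition of several nodes of a cancer signalling axis (dual PIK3CA+AKT1
and triplet PIK3CA+AKT1+MTOR blockade), where curated multi-target actives
are so few — here, 5 dual-target and 16 triplet-target seed molecules —
that a generative model must inherit almost everything from stages trained
on cheaper data. The package implements the full pipeline at desk scale
(one CPU, minutes) on synthetic data, with every numerical component pinned
to an independent oracle in the test suite.

## Model

The generator is a sequence VAE over SMILES strings.

**Input encoding.** A SMILES is tokenized (two-character halogens, bracket
atoms and `%NN` ring closures are single tokens) and laid out as a one-hot
matrix of shape (100, 48): `<bos>` + up to 98 payload tokens + `<eos>`,
padded with `<pad>`. The 48-symbol vocabulary (4 specials + 44 chemistry
tokens) ships as a versioned data file; loading data that produces `<unk>`
tokens logs a warning. Payloads longer than 98 tokens are truncated *before*
`<eos>`, so every decode target terminates.

**Encoder: 1-D bi-level routing attention.** Bi-level routing attention was
formulated for 2-D image patches; the 1-D adaptation here is our
construction. The L = 100 token positions are partitioned into R = L/S
contiguous regions of S tokens. Mean-pooled per-region query/key
descriptors give an R×R affinity matrix; each query region is routed to its
top-k regions (ties to the lowest index; a region always routes to itself),
and token-level scaled-dot-product attention is restricted to the keys of
the routed regions, so each query sees exactly k·S keys instead of L.
Routing is hard — top-k on detached affinities — so gradients flow only
through the token-level attention. Implementation note: the restriction is
applied as an additive −1e9 mask inside a fused softmax, which is
mathematically identical to gathering the routed keys and normalizing over
the gathered set; the instrumentation counter that reports keys-per-query
(= k·S) is derived from the routing mask. Setting k = R recovers dense
attention exactly, and that dense-limit equivalence against an
independently written dense attention (≤ 1e-5) is the correctness anchor
for the whole mechanism.

**Latent bottleneck.** Encoder states are mean-pooled over non-pad
positions (the pooling rule is our choice) and mapped by two linear heads
to the mean and log-variance of a diagonal Gaussian, with the standard
reparameterization `z = mu + exp(logvar/2)·eps` and the closed-form KL to
the standard normal.

**Decoder.** A causal (GPT-style) transformer over token + position
embeddings, conditioned on the latent through a single learned prefix
embedding at position 0 (chosen over per-layer cross-attention for
simplicity and testability). Position t predicts token t from the prefix
plus tokens < t; causality is verified by perturbation at every position.
Sampling is token-by-token from temperature-scaled softmax distributions,
halting at `<eos>` or 100 tokens; temperature ≤ 0 requests greedy argmax.

**Numerics.** The network and its training run on a small reverse-mode
autodiff engine over NumPy (float32), with fused softmax / cross-entropy /
layer-norm ops on the hot path; every op's gradient is checked against
central finite differences. Attention logits use a −1e9 additive mask;
Fréchet-distance covariances floor their eigenvalues at 1e-8; the supervised
contrastive loss rejects projections that are not L2-normalized and returns
0 (with a warning) for batches without a positive pair.

## Training pipeline

**Phase A — pre-training.** Minimizes reconstruction cross-entropy (mean
nats per non-pad token) + β·KL, with β warmed up linearly 0 → 0.05 over 10
epochs (β, λ, τ and learning rates are not established constants for this
architecture; the defaults follow common VAE/SupCon practice and are all
exposed in config). Optimizer: Adam, lr 1e-3.

**Phase B — supervised contrastive stage.** Adds λ·SupCon on the latent
means passed through a 2-layer projection head (output dimension 32,
L2-normalized): for each anchor with at least one same-label positive,
−(1/|P(i)|) Σ_p log[exp(s_ip/τ) / Σ_{a≠i} exp(s_ia/τ)] with dot-product
similarity; defaults λ = 1.0, τ = 0.1. The class scheme is binary
single-target vs multi-target. The total loss decomposes exactly into its
logged components (re-added offline to 1e-6), and with λ = 0 the stage
reproduces the pre-training loss series bit-for-bit — the ablation
identity used in the tests.

**Phase C — curriculum fine-tuning.** Dual-target seeds first, then
triplet-target seeds continuing from the dual-stage weights; the order is
enforced (an override flag exists on the CLI). Each seed set is amplified
by randomized (non-canonical) SMILES enumeration: each seed contributes its
canonical form plus a−1 randomized renderings (default a = 50, so 5 seeds →
250 strings, 16 → 800). Enumeration was chosen over plain repetition so the
decoder sees varied token sequences of the same molecules; whether the
original work amplified its seeds this way is not stated, so the mechanism
is configurable.

All stages draw every random number from the seed in their config; a rerun
with the same config and data reproduces the loss series exactly (pure
NumPy, deterministic kernels).

## Latent probe

Discriminability is measured by freezing the encoder, encoding each
molecule to its latent mean, and fitting an L2-regularized logistic
regression (C = 1.0) on a stratified 80/20 split (the evaluation protocol
of the probe is our choice; a single held-out fold keeps the desk runs
fast). Reported metrics — accuracy, macro precision/recall/F1 — are
recomputed from the confusion matrix in the tests.

## Metric suite

Validity, uniqueness and novelty operate on canonical SMILES. All Tanimoto
computations package-wide use 2048-bit radius-2 circular fingerprints
(ECFP4). Internal diversity is IntDiv1 (1 − arithmetic mean pairwise
Tanimoto; the power-mean IntDiv2 variant is not implemented). Fragment
similarity uses BRICS decomposition counts, scaffold similarity Murcko
scaffold counts, both as cosine over the union key space. The Fréchet
distance fits Gaussians to feature vectors of the two sets,
|μ1−μ2|² + Tr(Σ1+Σ2−2(Σ1Σ2)^{1/2}); the default featurizer is a built-in
block of ten standardized physicochemical descriptors (MW, LogP, TPSA, HBD,
HBA, rotatable bonds, rings, Fsp3, QED, SA), so the package is
self-contained — a neural-embedding featurizer can be registered where such
weights are available locally, and distances from different featurizers are
not comparable. Standardization uses pooled moments assembled
commutatively, and the trace term averages both orderings of the matrix
square root, making the distance exactly symmetric under swapping the sets.

## Screening cascade

Stage 1 removes invalid molecules and those with more than one rule-of-five
violation (MW > 500, LogP > 5, HBD > 5, HBA > 10; the classic rule allows
one violation, configurable). Stage 2 keeps molecules whose Murcko-scaffold
fingerprint reaches Tanimoto ≥ 0.50 (inclusive) to at least one reference
scaffold; acyclic molecules are removed and logged. Stage 3 ranks by
rank(QED, descending) + rank(SA, ascending) — the aggregation rule is our
choice, ties broken by canonical SMILES — and keeps the top 25% (at least
one). Stage 4 clusters by Butina sphere-exclusion on Tanimoto distance
(cutoff 0.6 by default): neighbourhoods at distance ≤ cutoff, candidate
centroids in order of decreasing neighbour count with ties to the lowest
index, each centroid claiming its unassigned neighbours; the best-ranked
member per cluster is the representative. Representatives are categorized
against the references by best whole-molecule Tanimoto: high-fidelity (HF)
at ≥ 0.70, scaffold-hopping (SH) in [0.50, 0.70), other below. The HF
boundary is fixed package-wide at 0.70; stricter per-task bands (e.g. 0.80
for triplet-target analyses) can be applied downstream. Retention
fraction, cutoff and violation allowance are documented defaults, not
published constants.

## Synthetic data

The generator assembles molecules from ring-containing scaffold templates
(1–3 substituent slots) and a library of ~45 motif-free substituents, with
target classes encoded by three pharmacophore motifs: sulfonamide
(`S(=O)(=O)N`), morpholine (`N1CCOCC1`) and urea (`NC(=O)N`) — echoing
linkers recurrent in kinase inhibitors. Single-target molecules carry
exactly one motif, dual-target A+B, triplet-target A+B+C; the mapping of
motifs to protein targets is a fiction for testing. Every emission is
re-verified by substructure matching, so labels hold by construction, and
the combinatorial space (> 10⁴) keeps duplicate rates under 5% at corpus
scale.

What the generator does *not* emulate: real bioactivity landscapes
(activity cliffs, assay noise), the scaffold imbalance of curated inhibitor
sets, stereochemistry, charged species, or molecules near the 98-token
length limit. Because class membership is a deterministic substructure
property, the synthetic discriminability benchmark is *easier* than
separating real single- from multi-target actives; passing it shows the
pipeline's machinery works end-to-end, not that the model would reach the
same accuracy on curated assay data.

## Desk-scale defaults and problem sizes

Model: embed dim 64, 4 heads, 2 encoder + 2 decoder layers, latent dim 32,
region size S = 10, top-k = 3, feed-forward multiplier 2. Full-scale values
belong in config files, not code. The β exponent in the sub-quadratic
complexity claim of routed attention is not meaningful at L = 100; instead
of asserting an asymptotic bound the package exposes (S, k) and asserts the
gathered-key count k·S per query.

The discriminability benchmark (also what `scripts/acceptance.py` runs)
uses 1,000 molecules per class, 4 pre-training epochs + 16 contrastive
epochs at batch size 100 — chosen once as the point where the probe
saturates at desk scale. Tests use smaller instances of the same recipe
(40/class, 2 + 6 epochs, a narrower model) for the paired before/after and
ablation comparisons over 5 seeds.

## Known limitations

- Training is single-process NumPy: adequate for the desk-scale study, not
  for corpus-scale pre-training.
- Hard routing passes no gradient to the region-affinity descriptors;
  at desk scale this is compensated by the token-level gradients, but a
  soft-routing variant may train differently.
- The supervised contrastive stage assumes class labels are trustworthy;
  label noise is not modelled.
- Checkpoints store weights + config + vocabulary hash and refuse to load
  under a different vocabulary; there is no migration path between
  vocabulary versions.
- Exact neural-embedding Fréchet distances (and hence comparisons against
  published tables using them) require external weights and are out of
  scope for the built-in featurizer.
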