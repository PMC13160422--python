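# mtmolgen

Multi-target de novo molecular generation for low-data drug discovery: a
sparse-attention SMILES variational autoencoder with supervised contrastive
latent shaping and curriculum fine-tuning, plus the generative metric suite,
scaffold analytics and a four-stage virtual-screening cascade.

## Who this is for

Designing one molecule that inhibits several proteins at once
(polypharmacology — e.g. dual PIK3CA+AKT1 or triplet PIK3CA+AKT1+MTOR
blockade of a cancer signalling axis) is starved of training data: curated
multi-target actives number in the tens, not thousands. `mtmolgen` is a
desk-scale toolkit for studying how a generative chemical language model can
be adapted to that regime:

1. **Pre-training** — a VAE learns general SMILES syntax from an unlabeled
   corpus. Each molecule is a one-hot tensor of shape (100, 48): 100 token
   positions over a 48-symbol vocabulary.
2. **Contrastive latent shaping** — a hybrid loss (reconstruction + KL +
   supervised contrastive on projected latent means) pulls same-profile
   molecules together in latent space, so single- and multi-target profiles
   become linearly separable.
3. **Curriculum fine-tuning** — the decoder is specialised first on 5
   dual-target seed molecules, then on 16 triplet-target seeds, each tiny
   set amplified by randomized SMILES enumeration.

The encoder uses **bi-level routing attention**: the 100-token sequence is
split into regions of S tokens, each query region is routed to its top-k
most relevant regions by a region-affinity matrix, and token-level attention
is restricted to the routed keys — so each query attends to k·S keys instead
of all N, while k = N/S recovers exact dense attention. The model and its
training are implemented on a small reverse-mode autodiff engine over NumPy
(`mtmolgen.autodiff`), verified against finite differences.

A fragment-grammar generator (`mtmolgen.synthdata`) emits valid, labeled
molecules whose target classes are encoded by pharmacophore motifs
(sulfonamide, morpholine, urea), so the entire pipeline is testable without
downloads.

## Worked example

```python
from mtmolgen.benchmark import contrastive_discriminability

result = contrastive_discriminability(seed=1, n_per_class=100,
                                      pretrain_epochs=3, contrastive_epochs=8,
                                      batch_size=50)
print("probe accuracy before contrastive stage:", result.probe_before.accuracy)
print("probe accuracy after contrastive stage: ", result.probe_after.accuracy)
```

prints (seed 1, 100 molecules per class, about a minute on one CPU):

```
probe accuracy before contrastive stage: 0.7
probe accuracy after contrastive stage:  0.9
```

The probe is a logistic regression fitted on frozen latent mean vectors with
a stratified 80/20 split; its holdout accuracy measures how cleanly the
contrastive stage separated single-target from dual-target profiles. After
pre-training alone the latent space is organised only by reconstruction and
the probe sits near chance; the contrastive stage pulls the two profiles
apart. At the full benchmark scale (1,000 molecules per class, 4 + 16
epochs) the probe saturates — that run is what `scripts/acceptance.py`
reports.

The same workflow is available from the shell:

```bash
mtmolgen synth --kind corpus --n 2000 --seed 7 -o corpus.smi
mtmolgen pretrain --corpus corpus.smi --epochs 4 --seed 1 -o runs/pre
mtmolgen synth --kind labeled --n 1000 --seed 7 -o labeled.csv
mtmolgen contrast --data labeled.csv --checkpoint runs/pre/pretrain.npz \
         --epochs 16 --seed 1 -o runs/con
mtmolgen probe --checkpoint runs/con/contrastive.npz --data labeled.csv \
         --seed 1 -o probe.json
mtmolgen generate --checkpoint runs/con/contrastive.npz --n 100 -o gen.smi
mtmolgen evaluate --gen gen.smi --ref corpus.smi --train corpus.smi -o report.json
mtmolgen screen --gen gen.smi --refs corpus.smi -o runs/screen
```

`evaluate` writes a JSON report with validity, uniqueness, novelty, internal
diversity (1 − mean pairwise ECFP4 Tanimoto), similarity-to-nearest-
neighbour, BRICS-fragment and Murcko-scaffold cosine similarities, a
descriptor-Gaussian Fréchet distance, and QED/LogP/SA/MW summaries. `screen`
runs the cascade: rule-of-five filter → scaffold similarity ≥ 0.50 to a
reference inhibitor → QED/SA rank → Butina cluster representatives, each
categorized against the references as high-fidelity (Tanimoto ≥ 0.70),
scaffold-hopping (0.50–0.70) or other.

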