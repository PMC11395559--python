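# Methods

## What the toolkit measures

DNA language models trained on *overlapping* k-mer tokens face an unusual
masked-prediction problem: when a single token is masked, its sequence is
almost entirely recoverable from the unmasked neighbours, because adjacent
tokens share k−1 nucleotides.  The toolkit implements the probing protocol
that separates this **token-identity learning** from genuine **sequence-context
learning**, together with the datasets, reference model and analyses needed
to run the whole protocol at desk scale on synthetic genomes.

Three readouts carry the contrast:

1. **Masked-token prediction.** k tokens around a randomly chosen token are
   masked with the per-k offset patterns (4-mer: −1,0,1,2; 5-mer: −2..2;
   6-mer: −2..3).  By construction the union of masked tokens spans 2k−1
   nucleotides and exactly one nucleotide — the *central nucleotide* — is
   covered by no unmasked token.  Every other masked base leaks through the
   overlaps, so on sequence with no context signal the Bayes accuracy per
   masked token is the central-base prior (1/4 for uniform bases), while on
   fully context-determined sequence it is 1.
2. **Next-k-mer prediction.** A classifier over all 4^k k-mers predicts the
   k nucleotides *following* a 50-nt context, with zero positional overlap,
   so token identity cannot leak into the label.  Accuracy is compared to
   the uniform baseline 4^−k (0.004 printed for k=4, rounded from 1/256).
   k is limited to 2..6; the class head doubles 4-fold per unit of k.
3. **Prom300.** Binary classification of intact 300-bp promoter windows
   (−249..+50 around the TSS) against copies in which 15 of 20 equal 15-nt
   parts had their nucleotides shuffled in place.  Shuffling preserves the
   nucleotide multiset of every part exactly, so composition carries no
   signal and only positional structure distinguishes the classes.

Embedding analyses complete the picture: **MEV** (maximum explainable
variance, the share of total variance on the first principal component of
the token-embedding matrix; high values indicate token-identity-dominated
representations), and a 2-D **UMAP** of the embeddings annotated with each
k-mer's central sub-k-mer and its purine/pyrimidine (R/Y) pattern, against a
static **Word2Vec-CBOW** baseline trained on the same tokenized corpus.

## Reference model

The probing harness is model-agnostic: any object satisfying the masked-LM
contract (per-masked-position probability rows over the full vocabulary, a
token-embedding matrix, a trainable encoder) can be plugged in, including
external transformer checkpoints through a thin adapter that maps tokenizer
ids and tensor shapes.  For self-contained runs the package ships
`ReferenceMaskedLM`, a deliberately small transformer encoder implemented in
NumPy with hand-written backpropagation (verified against finite differences
in the test suite):

- token embeddings + fixed sinusoidal positional encodings;
- 2 pre-LayerNorm blocks of 2-head self-attention and a ReLU feed-forward
  (64-dim model, 128-dim feed-forward);
- an MLM head over the 4^k + 5 token vocabulary; cross-entropy at masked
  positions only.

Sinusoidal (analytic) rather than learned positional encodings were chosen
so that input length is not baked into the weights: Prom300 windows tokenize
to ~297 tokens, far beyond the 64-token pretraining context, and the
fine-tuner raises the model's input-length limit automatically (logged)
instead of truncating five sixths of the promoter.

Pretraining defaults (one CPU, ≈90 s): 2000 sub-sequences of 20–60 tokens,
Adam lr 2·10⁻³, batch 32, 1200 steps.  These schedule values are the
package's own desk-scale choices, picked so that the positive control (below)
converges reliably across seeds.  `TrainingConfig` keeps the published
full-scale fine-tuning protocol as its defaults — Adam lr 10⁻⁶, ε 10⁻⁸,
β₂ 0.99 (a single quoted "beta" is read as the second-moment coefficient,
β₁ stays 0.9; both are exposed), batch 64, 150 iterations for next-k-mer,
10 epochs for Prom300, classifier dropout 0.5 — and
`TrainingConfig.desk_scale()` swaps in lr 10⁻³, which actually moves the
tiny freshly-initialized encoder within 150 iterations.

Sequence-level representation for both classification heads is a mean-pool
over token positions.  Fine-tuning copies the encoder weights, so a base
model can back several task heads without cross-contamination; all weights
are updated unless `freeze_encoder` is set.

## Synthetic study conditions

The generators define the conditions every control runs under:

- **Periodic genome** (positive control): exact tiling of the 7-mer unit
  `ACGTTAG`, 1.3 Mnt.  Period 7 is coprime with the 510-nt chunking of the
  next-k-mer builder, so chunks cycle through all phases and the label is a
  deterministic function of the context.  Expected outcomes: masked-token
  accuracy near 1, next-4-mer accuracy ≫ 10 × 4⁻⁴.
- **iid genome** (negative control): uniform independent bases, 1.3 Mnt.
  No context exists; next-4-mer accuracy must stay inside the 3σ binomial
  envelope of 1/256, and masked accuracy must not exceed 0.5 (the flanks
  determine all but the central base; at full convergence the ceiling is the
  0.25 central-base prior — the desk-scale schedule does not train long
  enough on unlearnable data to reach even that, which is fine for a bound).
- **Markov genome**: order-m chain (m ≤ 5 to keep transition tables
  estimable) with a rotating-preference transition matrix of configurable
  strength; used for parameter-recovery tests and as an alternative
  learnable control.
- **Synthetic promoters**: 300-nt sequences with three copies of the 8-nt
  motif `TATAATCG` planted at offsets 40/121/230 in an iid background whose
  base frequencies (A/T 0.375, C/G 0.125) match the motif's composition.
  The signal must be *sub-part positional*: within-part shuffling preserves
  every part's composition, so any part-level compositional gradient would
  survive the shuffle and void the negative construction.  With three motif
  copies the probability that a shuffled record keeps all of them intact is
  ≈0.25³ ≈ 0.016 (each 15-nt part is left unshuffled with probability 5/20),
  so near-perfect separation is attainable in principle.

What the generators deliberately do **not** emulate: real-genome k-mer
composition, repeat families, promoter biology (CpG islands, TATA-box
positional preference distributions), or soft-masked/ambiguous bases beyond
exclusion.  Green controls therefore show the *machinery* (datasets, models,
metrics) behaves as designed, not that any real-genome number is reproduced.

## Numerical and design choices

- Token ids are lexicographic over A<C<G<T (base-4 integer encoding); no
  attempt is made to match any external checkpoint's id order.
- All internal coordinates are 0-based half-open; the TSS window "−249..+50"
  is a closed 300-position range with the TSS at offset 0 (BED input is
  0-based; minus-strand windows are reverse-complemented).
- FASTA records containing non-ACGT characters are excluded whole by
  default (`split_at_invalid=True` splits them into valid runs instead,
  which is what one would use on a real soft-masked assembly); lowercase is
  uppercased.
- Sub-sequence lengths are drawn in *tokens* (510 full length, 20 minimum,
  50% full-length probability) and converted with +k−1 nucleotides; the
  next-k-mer builder works in *nucleotides* (510-nt chunks, first 50 context,
  trailing partial chunk dropped).
- The masked builder emits one masked sample per sub-sequence, with the
  chosen token uniform over positions where the pattern fits with at least
  one unmasked flanking token on each side; Prom300 shuffles choose their 15
  parts freshly per record, and degenerate shuffles (identical to the
  original, e.g. homopolymers) keep the `shuffled` label.
- Argmax ties in evaluation break toward the lowest token id and are
  counted; ranks are 1-based with stable ordering.  The "negligible
  probability" floor of the rank profile is 0.01, config-exposed.
- MEV uses column-mean-centred, unscaled PCA; scaling would change the
  statistic.  Special tokens are excluded from MEV/UMAP.  MEV is linear and
  hence a lower bound on explainable structure; no non-linear analogue is
  attempted.
- MCC with a zero denominator factor is defined as 0.  Both the
  positions-first and samples-first aggregations of masked accuracy are
  reported, since either reading of a whole-model accuracy is defensible.
- UMAP defaults: n_neighbors 15, min_dist 0.1, Euclidean, seed 42.
- The CBOW embedder uses a full-softmax output layer (practical because the
  k-mer vocabulary is ≤4096), window 5 per side, vector size 768, min_count
  1, mini-batch gradient descent; epochs and learning rate are exposed and
  recorded since the canonical three parameters do not pin them down.
- Unobserved k-mers (possible only on tiny corpora) get no CBOW vector and
  are reported, not zero-filled.

## Problem sizes

Desk-scale runs use 1.3-Mnt genomes, 2000 pretraining sub-sequences of ≤60
tokens, 2500 next-k-mer samples (80/20 split), 250 promoters (500 Prom300
records, 80/20 split), and a 64-dim/2-layer/2-head reference model.  On one
CPU: pretraining ≈90 s, next-k-mer fine-tuning (150 iterations) ≈20 s,
Prom300 fine-tuning (10 epochs over 297-token inputs) ≈90 s, CBOW ≈10 s,
UMAP ≈30 s including JIT warm-up.  All sizes are configuration values; the
500,000-sample cap and 20%-of-sub-sequences selection of a full-scale run
are the library defaults, shrunk in the shipped configs.

## Known limitations

- The reference model is a probe harness, not a pretrained foundation model;
  its absolute accuracies are meaningful only relative to the synthetic
  controls.
- Pure-NumPy training is single-threaded and float64; it is sized for
  minutes, not for genome-scale corpora.
- The Prom300 CLI path does not parse promoter-database native formats;
  inputs arrive as BED + FASTA or pre-extracted 300-nt FASTA.
- `run_pipeline` reproduces byte-identical artifacts only under a fixed
  config and library versions (UMAP coordinates, in particular, are
  version-sensitive).
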