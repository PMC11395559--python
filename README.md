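# dnalm-probe

A probing toolkit for DNA language models that use **overlapping k-mer
tokenization**.  Because adjacent overlapping tokens share k−1 nucleotides,
a masked token's sequence is almost entirely recoverable from its unmasked
neighbours — so strong masked-prediction accuracy can reflect *token
identity* learning rather than genuine *sequence context* learning.  This
package implements the tasks and analyses that pull those two apart, for
anyone evaluating or designing genomic language models:

- **Tokenization** — the 4^k + 5 vocabulary (all k-mers plus CLS/PAD/UNK/
  SEP/MASK), overlapping tokenization/detokenization, genome k-mer
  frequency tables.
- **Masked-token task** — sub-sequence sampling (50% full 510-token windows,
  otherwise uniform 20–510), the per-k mask patterns (4-mer: −1,0,1,2;
  5-mer: −2..2; 6-mer: −2..3) that leave exactly one *central nucleotide*
  covered by no unmasked token, and per-offset accuracy / rank-probability
  readouts.
- **Next-k-mer task** — predict the k nucleotides following a 50-nt context
  (4^k classes, k = 2..6, zero positional overlap), judged against the
  uniform baseline 4^−k; accuracy above it requires real context learning.
- **Prom300** — intact 300-bp promoter windows (−249..+50 around the TSS)
  versus copies with 15 of 20 equal parts nucleotide-shuffled in place
  (composition-preserving negatives); F1 / precision / recall / MCC.
- **Embedding analyses** — model token embeddings vs a Word2Vec-CBOW
  baseline, maximum explainable variance (MEV = first-PC share of variance),
  and UMAP maps annotated by each k-mer's central sub-k-mer and its
  purine/pyrimidine (R/Y) pattern.
- **Reference model & synthetic genomes** — a tiny NumPy transformer masked
  LM (gradient-checked backprop) and iid / Markov / periodic genome and
  planted-motif promoter generators, so every stage runs end-to-end on one
  CPU in minutes with controls whose expected outcomes are known.

The scientific details, default parameters and limitations are documented
in [docs/methods.md](docs/methods.md).

## Worked example

The bundled pipeline synthesizes a genome, pretrains the reference model,
fine-tunes the next-k-mer head and analyses the embeddings:

```python
from dnalm_probe.pipeline import run_pipeline

manifest = run_pipeline({"seed": 0}, "out/run")
for key, value in manifest.results.items():
    print(f"{key}: {value}")
```

On the default configuration (periodic `ACGTTAG` genome, 64-dim reference
model, 2500 next-4-mer samples) this prints:

```
pretrain_final_loss: 0.006378549597051581
masked_overall_accuracy: 0.9875
next_kmer_accuracy: 1.0
mev_model: 0.32136663716005637
```

Reading the numbers: every base of a periodic genome is determined by its
context, so after pretraining the model recovers masked tokens almost
perfectly (0.9875 across the four mask offsets) and the fine-tuned
next-4-mer head is exact (1.0, against a random baseline of 1/256 ≈ 0.004).
Swapping `"genome": {"mode": "iid", "length": 400000}` into the config
removes all context: next-4-mer accuracy then stays statistically at the
baseline — the toolkit's core contrast.  `mev_model` is the fraction of
embedding variance on the first principal component.  The same stages are
available as composable functions and sklearn-style estimators
(`ReferenceMaskedLM`, `NextKmerClassifier`, `Prom300Classifier`,
`Word2VecCBOW`), and from the shell:

```bash
dnalm-probe synth genome --mode periodic --length 400000 --out genome.fasta
dnalm-probe train-ref --fasta genome.fasta --out ckpt/
dnalm-probe build nextkmer --fasta genome.fasta --k 4 --max-samples 2500 --out nk.tsv
dnalm-probe finetune nextkmer --checkpoint ckpt/ --data nk.tsv --report nk.json
dnalm-probe embed model --checkpoint ckpt/ --out emb.tsv
dnalm-probe analyze mev --embedding emb.tsv --report mev.json
```

External masked LMs can be probed by wrapping them in the small model
contract (probability rows over the vocabulary at masked positions, a
token-embedding matrix, a trainable encoder); see
`dnalm_probe.models.check_contract`.

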