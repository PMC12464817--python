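# hinttok — hint token learning for protein variant-effect classification

`hinttok` implements **hint token learning (HTL)**: a mutation-aware
tokenization strategy for classifying the functional impact of protein
point mutations from sequence alone. A variant differing from its wild
type at one residue out of hundreds is nearly invisible to a sequence
classifier; HTL makes the change explicit by flanking every mutated
residue with two special tokens before tokenization:

```
wild type   M D V F M            (V3A)
mutant      M D A F M
augmented   M D [MUT_start] A [MUT_end] F M
```

The two hint tokens are appended to the tokenizer vocabulary in fixed
order, so with a 30-symbol base vocabulary they receive ids 30 and 31.
The package provides the full experimental pipeline around this idea,
runnable on a laptop CPU:

* **`hinttok.mutation`** — mutation notation (`D26E`), equal-length
  diffing, hint-token augmentation/stripping, vocabulary extension,
  integer encoding, pair-preserving truncation;
* **`hinttok.splitting`** — multi-label stratified splits (joint strata
  over class label × mutation count) and position-grouped splits in which
  no mutated residue position recurs across train/validation/test
  (transitive grouping of co-occurring positions via union-find);
* **`hinttok.training`** — a from-scratch numpy transformer classifier,
  the training protocol (up to 50 epochs, early stopping with patience
  15, selection by validation weighted F1), a tree-structured Parzen
  estimator (TPE) hyperparameter search (10 trials), and support-weighted
  metrics with the weighted-recall = accuracy identity;
* **`hinttok.sae`** — layer-wise sparse autoencoders on per-residue
  embeddings and the domain-activation statistics

  A = (1/N_l) Σ_j (1/N_s) Σ_i A_ij / R,  ΔA_rel = (A_HTL − A_NO_HTL) / max(A_HTL, A_NO_HTL)

  where A_ij counts activated residues inside annotated functional
  domains for test sample i at layer j and R is the number of domain
  residues;
* **`hinttok.synthetic`** — seeded deep-mutational-scanning-style
  libraries with a planted rule (mutation inside a domain ⇒ loss of
  function, plus label noise ε) and a closed-form Bayes ceiling on the
  achievable weighted F1.

## Worked example

```python
>>> import hinttok as ht
>>> m = ht.parse_mutation_string("V3A")
>>> rec = ht.MutantRecord("fig", "MDVFM", (m,), "LOF")
>>> aug = ht.insert_hint_tokens(rec)
>>> aug.elements
('M', 'D', '[MUT_start]', 'A', '[MUT_end]', 'F', 'M')
>>> vocab = ht.extend_vocabulary(ht.base_vocabulary())   # 21 base symbols
>>> (vocab.mut_start_id, vocab.mut_end_id)
(21, 22)
>>> ht.encode(aug, vocab)
[11, 3, 21, 1, 22, 5, 11]
```

The hint ids (21, 22) bracket the mutated residue's id (1, i.e. `A`);
stripping them recovers `MDAFM`. Improvement arithmetic used when
comparing fine-tuning runs:

```python
>>> ht.relative_improvement(0.64, 0.25)   # % change in weighted F1
156.0
>>> ht.absolute_improvement(0.58, 0.41)   # percentage points
17.0
```

A full paired benchmark on one synthetic library (training the tiny
encoder with and without hint tokens under identical budgets):

```python
>>> from hinttok import run_htl_benchmark
>>> out = run_htl_benchmark([0, 1, 2, 3, 4])     # ~8 min on one CPU
>>> round(out["median_f1_htl"], 3), round(out["median_f1_control"], 3)
(0.875, 0.57)
>>> round(out["planted_rule_ceiling"], 3)
0.95
```

The hint-token arm reaches a median held-out weighted F1 of 0.875 against
a Bayes ceiling of 0.95 (the label noise ε = 0.05 makes perfect scores
impossible), while the control arm stays at the majority-class collapse —
the characteristic failure of standard fine-tuning on this kind of data.

A CLI mirrors the pipeline for shell use:

```bash
hinttok simulate --seed 0 --out-dir lib/
hinttok tokenize --wt lib/wildtype.fasta --variants lib/variants.tsv --htl --out tokens.tsv
hinttok split --wt lib/wildtype.fasta --variants lib/variants.tsv \
    --strategy position_grouped --seed 0 --out-dir splits/
```

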