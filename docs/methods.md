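# Methods

## The problem

Deep mutational scanning (DMS) experiments assign activity labels (e.g.
wild-type-like, loss of function, gain of function) to large libraries of
protein point-substitution variants. Sequence-only classifiers struggle on
such data because a variant differs from the wild type at only one or a few
of hundreds of residues, a perturbation easily lost inside a long token
stream. Hint token learning (HTL) attacks this directly: every mutated
residue is flanked by two special tokens, `[MUT_start]` and `[MUT_end]`,
before tokenization, so the model is told *where* to look and must only
learn *what* the change means.

## Sequence augmentation and vocabulary

A mutation is written `<ref><position><alt>` (e.g. `D26E`, 1-based
positions); a variant record holds the wild type, a position-sorted set of
substitutions, and the derived mutant sequence. Augmentation inserts the
hint pair around each mutated residue right-to-left so earlier positions
never shift; stripping the hint symbols reproduces the mutant sequence
exactly, and the number of pairs always equals the number of mutations.
The two hint tokens are appended to the base vocabulary in a fixed order
(start, then end), so ids are deterministic: with a 30-symbol base
vocabulary they become 30 and 31. Only substitutions are supported —
insertions and deletions are rejected with a clear error, since DMS variant
tables are substitution libraries and equal-length diffing is exact.

Over-long sequences are truncated to a window centred on the first
mutation; a hint pair is never split (a pair straddling the window
boundary is dropped whole). The serialized text form supports both a
whitespace-separated dialect (for tokenizers that expect one residue per
token, the default) and a compact dialect.

## Dataset splitting

Two protocols are provided, each seed-deterministic:

* **Multi-label stratification** forms joint strata over (class label,
  mutation-count bin) with bins {1, 2, 3–5, 6+}, shuffles each stratum and
  slices it at floored targets, remainders going to train. Strata smaller
  than the number of sets go wholly to train with a warning. This
  preserves both the label distribution and the mutation-count
  distribution across train/validation/test.
* **Position grouping** guarantees that all variants mutating the same
  residue position land in the same set, so evaluation measures
  generalization to unseen positions. Positions co-occurring in one
  record are merged transitively (union-find over the co-occurrence
  graph): a record mutating {5, 80} and another mutating {80, 200} form a
  single three-position group. Groups are assigned largest-first to the
  set with the greatest remaining deficit, with a label-balance tiebreak
  and a seeded shuffle among equal-sized groups. Exact ratios are
  impossible under grouping constraints; the audit reports achieved
  proportions, and a tolerance parameter (default 0.05) defines what
  counts as acceptable stratification error.

## Classifier and training protocol

The default model is a small from-scratch transformer encoder written in
numpy: token embeddings plus learned positional embeddings, two pre-norm
transformer blocks (4-head self-attention, 2× feed-forward width, residual
connections, layer normalization), mean pooling over non-pad positions and
a linear softmax head. Forward and backward passes are hand-derived and
verified against finite differences in float64; training uses Adam on
float32 parameters with seeded shuffling and optional inverted dropout on
the residual branches.

Two initialization details matter at this scale. Token embeddings are
initialized at std 0.1 and, in the sinusoidal-position variant, the O(1)
positional encodings are scaled by 0.1: with the conventional 0.02-std
embedding init the positional component outweighs token identity ~35:1 and
the classifier stalls indefinitely at the majority class. Learned
positional embeddings are the default because they let the network attach
a per-position score directly instead of decoding sinusoids through the
feed-forward layer, which markedly shortens the feature-learning plateau
on position-dependent tasks. Hint-token embedding rows can be
re-initialized from the embedding-matrix mean plus small seeded noise when
starting from a pretrained checkpoint whose vocabulary lacked them.

The training protocol is: up to 50 epochs with early stopping once the
validation score fails to improve for 15 consecutive epochs (strict
improvement; the best-validation checkpoint is restored), model selection
by validation weighted F1, and hyperparameter search with a
tree-structured Parzen estimator (TPE) over 10 trials. Class imbalance is
handled only through support-weighted metrics — weighted F1, precision
and recall, reported rounded to two decimals with full precision kept
internally. Weighted recall equals accuracy by algebraic identity, which
the tests exploit as an invariant.

The TPE sampler splits observed trials at the γ = 0.25 quantile of the
objective, fits per-dimension Parzen (Gaussian-mixture) densities to the
good and bad sets, and returns the candidate maximizing the density ratio
l(x)/g(x) among 24 draws from l. Each observation's bandwidth is its
largest gap to a neighbouring observation (interval endpoints count as
neighbours, floor 0.03 on the unit scale); a uniform prior component is
mixed into both densities. The first 5 trials are random draws through
exactly the same code path as the pure random sampler, so setting
`n_startup = n_trials` reproduces random search bit-for-bit — a property
the tests assert. A narrower fixed-bandwidth variant was tried first and
discarded: it anchors on the best startup point and creeps too slowly to
beat random search on even a 1-D quadratic.

## SAE interpretability

To ask *why* HTL helps, layer-wise sparse autoencoders are trained on the
per-residue hidden states of the fine-tuned classifier (the residual
stream after each block, hint-token and pad slots excluded). Each SAE is
a single rectified latent layer (default width 4× the embedding dimension)
trained with Adam on MSE plus an L1 latent penalty λ (default 1e-3). A
residue is *activated* when its maximum latent activation exceeds a
threshold τ (default 1e-6); the threshold, width, penalty and optimizer
settings are exposed as configuration because no canonical values exist
for this model scale.

Given functional-domain intervals (1-based inclusive, matching mutation
notation) with R total domain residues, the per-sample per-layer count
A_ij of activated in-domain residues is averaged as

    A = (1/N_l) Σ_j (1/N_s) Σ_i A_ij / R,

and the effect of HTL is summarized by the relative change

    ΔA_rel = (A_HTL − A_NO_HTL) / max(A_HTL, A_NO_HTL),

which is antisymmetric, bounded in [−1, 1], and defined as 0 at (0, 0) —
the continuous limit, chosen so degenerate runs do not poison averages.
"Deeper layers" are the last ⌈N_l/3⌉ layers by default; with the 2-layer
desk model this is the final layer. Whether the embedding layer itself
should enter the average is left configurable via the layer subset; the
default uses the post-block states only.

## Synthetic libraries and the planted rule

The generator emulates a DMS-style library: a uniform random wild type,
variants with a configurable mutation-count distribution, uniformly drawn
positions, and labels from a planted rule — loss of function iff any
mutation falls inside an annotated domain interval (with a designated
gain-of-function sub-interval taking precedence in the three-class
scheme), then independent label flips with probability ε. The rule ties
labels to domain membership deliberately, so the SAE domain-activation
statistics have a known ground-truth direction on synthetic data.

Default study conditions: 120 residues, 600 single-mutant variants, two
domains covering 30% of positions ((21, 44) and (73, 84)), binary labels,
ε = 0.05. Uniform position sampling then yields a ~30/70 LOF/WT-like
imbalance, exercising the weighted metrics. Because the rule is known,
the Bayes-optimal weighted F1 against the noisy labels has a closed form
(hypergeometric avoidance probabilities give the planted class
frequencies; symmetric flips give the confusion fractions), used as an
explicit performance ceiling: ε = 0 gives 1.0 and a balanced binary
problem gives 1 − ε.

What the generator does *not* model: real fitness-score distributions and
thresholds, residue-composition biases, epistasis between mutations, and
any structural signal. Passing benchmarks therefore demonstrate that the
pipeline extracts a position-linked mutational signal when one exists and
that hint tokens make that signal accessible to a small model — not that
the method reaches any particular accuracy on real DMS datasets.

## Benchmark scale

The paired benchmark trains the 2-layer, 64-dim, 4-head encoder twice per
seed (hint-token arm and control arm) with a budget of 20 epochs,
patience 8, learning rate 2e-3, batch 32 — a scaled-down version of the
50/15 protocol with identical logic, sized so a five-seed benchmark runs
on one CPU core in minutes. Under these conditions the hint-token arm
typically reaches held-out weighted F1 ≈ 0.9 (ceiling ≈ 0.95) while the
control arm stays at the majority-class collapse (~0.53), the
characteristic failure mode of sequence-only fine-tuning without hints. The acceptance script uses three replicate seeds; the test suite
uses five.

The benchmark's SAEs use λ = 0.1 and τ = 0.5 (20 epochs per layer on the
test-set embeddings) rather than the module defaults: at τ = 1e-6 every
residue of both arms counts as activated and the A statistic saturates
at 1.0 for any model, carrying no information. A threshold on the scale
of typical latent magnitudes makes activation selective; the observed
contrast is large — hint-token embeddings produce median per-residue
max-latent activations several times those of the control model — and
the direction of ΔA_rel is insensitive to the exact λ in the 0.1–5
range. ΔA_rel remains a reported, directional statistic rather than a
hard assertion.

## Numerical and degenerate-input choices

* Attention masking uses additive −1e9 on pad keys; pad positions are
  excluded from pooling and from SAE statistics, so right-padding never
  changes logits (tested to 1e-10).
* Early stopping uses strict improvement; ties count as stale epochs.
* Set-size targets are floored, remainders to train.
* A single position group covering every record cannot be split and
  raises; a stratum smaller than the number of sets falls back to train.
* Non-finite training or SAE losses raise immediately with diagnostics
  rather than continuing silently.
* `relative_improvement` requires a positive baseline; the (0, 0) case of
  ΔA_rel returns 0 by convention.

## Known limitations

* The desk-scale encoder does not approach the representational power of
  pretrained protein language models; absolute scores on real datasets
  are out of scope by design, and pretrained checkpoints enter only
  through an optional `.npz` parameter archive.
* Position-grouped evaluation with learned positional embeddings is
  intrinsically pessimistic for the tiny model (held-out positions have
  untrained embeddings); the benchmark therefore uses the stratified
  protocol, and position grouping is validated structurally.
* TPE is implemented per-dimension (no interaction modelling), matching
  the classic formulation.
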