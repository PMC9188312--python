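# Methods

## The classification model

A protein sequence over the 20 canonical amino acids is encoded as a
`len_w × 20` one-hot matrix: row *i* is the indicator vector of residue
*i*; rows past the sequence's end are zero (the pad symbol '-'); sequences
longer than `len_w` keep their N-terminal prefix and drop the rest.
Non-standard residues (X, B, Z, J, U, O) also map to the zero vector: the
encoding defines exactly 20 one-hot symbols plus the zero pad, and gene
callers emit these symbols rarely enough that treating them as pad costs
nothing measurable. The alphabet order ("ACDEFGHIKLMNPQRSTVWY") is
arbitrary but serialized with every trained model, since the convolution
weights are indexed by it.

The network is deliberately small:

| layer | shape | notes |
| --- | --- | --- |
| conv1d | kernel 7 × 20 channels, 50 filters, ReLU | learned motif detectors |
| global max-pool | → 50 features | best match per filter, position-invariant |
| dropout | rate 0.1 | |
| dense | 100 units, ReLU | |
| dropout | rate 0.1 | |
| output | K units, softmax | K categories, "others" last |

Training minimises mean categorical cross-entropy (natural log) with Adam
(learning rate 1e-3, batch 64, 20 epochs by default). The forward and
backward passes are implemented directly in NumPy — the whole model is six
weight tensors and global max-pooling makes the convolutional gradient a
cheap gather — which keeps the package free of any deep-learning framework
dependency. Weight init is He-style for the ReLU layers and Glorot for
the output; all randomness (init, shuffling, dropout masks) derives from a
single config seed, so one seed reproduces a training history exactly.

Default hyperparameters (`len_w` 900, kernel 7, 50 filters, 100 dense
units, dropout 0.1) are the tuned configuration for marker proteins, whose
lengths almost never exceed 900 residues; every value is configurable and
the `crossvalidate` harness (stratified, seeded k-fold) supports grid
exploration. Optimiser settings are conventional defaults, stated as such.

## Per-sequence loss and open-set rejection

With a one-hot truth vector the cross-entropy L = −Σ y_k ln p_k collapses
to −ln p of a single class. At application time the only class available
is the predicted one, so every sequence is scored L = −ln p_argmax and
reported on the log10 scale. Probabilities are clamped to
[1e-12, 1−1e-12] and the loss floored at 1e-12 before log10, so scores
are always finite and orderable (a saturated softmax gives log10 loss
−12).

Cutoff calibration collects true-positive log10 losses per target category
on a labeled set and takes the smallest order statistic whose empirical
CDF reaches the retention quantile (default 0.99, i.e. the inverted-CDF
quantile). This makes the retention guarantee exact by construction: at
least 99% of calibration true positives satisfy `log10_loss ≤ cutoff`.
An alternative boxplot-whisker rule (min(max, Q3 + 1.5·IQR)) is available
behind a flag for users who prefer the visual-boxplot convention.
Application is inclusive at the boundary: a loss exactly equal to the
cutoff is accepted; "others" predictions are never subject to cutoffs.
Rejection only ever moves predictions *out of* target categories, so on
any fixed dataset per-category precision cannot drop (unless it was
already undefined) and recall cannot rise — the package asserts both.

## Evaluation

Metrics are one-vs-rest per category: Accuracy (TP+TN)/n, Precision
TP/(TP+FP), Recall TP/(TP+FN), F1 their harmonic mean. Zero denominators
report 0 with an explicit flag, keeping tables total. Macro averages run
over the target categories only (excluding "others"); plain multiclass
accuracy is emitted separately and labeled distinctly.

The imbalance sweep holds the positive set fixed and grows the "others"
pool through *nested* seeded subsets: each larger pool contains every
smaller one. Nesting turns two observations into exact invariants rather
than statistical tendencies — recall is literally identical at every pool
size, and raw false positives can only accumulate, so raw precision is
non-increasing. Independent draws per size would show the same behaviour
only in expectation.

## Synthetic data: what it emulates and what it does not

A synthetic family is a set of consensus motifs (default two 15-mers)
planted at anchored positions inside i.i.d. background sequence, with
per-residue substitution rate μ inside motif copies and optional
single-residue indels at motif edges. Lengths are truncated-normal
(default 300 ± 40, clamped at the motif budget and 30 residues).
"Others" are pure background: separability is controlled solely by the
motifs. Open-set families — the hard negatives — can be derived from a
target family by perturbing its consensus at 35% of positions, emulating
remote homologs; this is what gives the rejection rule realistic
false-positive pressure, since entirely random novel families are simply
absorbed by "others".

What this captures: motif-driven family identity, within-family
divergence, length variation, open-set pressure from related families.
What it does not: real amino-acid composition bias, profile-HMM-style
position-specific conservation, phylogenetic correlation between
sequences, or the label noise of real database annotations. Passing the
benchmark therefore demonstrates that the architecture, the training loop,
the calibration rule, and the rejection bookkeeping are correct and that
the method behaves as designed under class imbalance — not that any
particular precision will be attained on real metagenomes.

## Benchmark problem sizes

The standard end-to-end benchmark uses 3 families × (500 train + 200
test), 800 training / 320 test background others, 5,000 open-set
sequences from two unseen families, μ = 0.1, and nested sweep pools of
{1k, 3k, 5k, 10k} (open set plus 5,000 extra background). The encoding
window for this benchmark is 512: sequences average 300 residues, so the
full 900 window would only add all-zero padding rows that the global
max-pool ignores. One run trains in about a minute on a single core.

## Curation filters

Keyword selection is case-insensitive substring matching on the FASTA
description; a record matching target phrases of two categories is
rejected as ambiguous, and any noise keyword ("hypothetical", "possible",
"like", "predicted") rejects the record. Noise keywords match on word
boundaries by default so "like" rejects "portal-like" but not "unlikely".
The length filter computes within-category quantiles at Hazen plotting
positions (position q·n − ½, clamped to the extremes): on lengths 1..100
the 5%/95% filter flags exactly the five shortest and five longest, and
with only two records nothing is ever flagged. Flagged records are
returned for manual verification rather than silently dropped; a strict
mode re-labels them "others". "Others" subsampling is a seeded uniform
draw without replacement (default 20,000).

## Numerical and degenerate-input conventions

- Argmax ties (e.g. a uniform softmax) resolve to the lowest category
  index, which orders target categories before "others".
- An all-zero input matrix (pure pad) is valid and yields an ordinary
  probability vector.
- Training aborts with a diagnostic on a non-finite loss rather than
  continuing silently.
- Model archives store config, category order, alphabet and weights
  together; loading verifies the format version and, on request, the
  alphabet, and reproduces predictions bit-for-bit.

## Known limitations

- Single-label classification only; a protein matching two categories at
  once (rare for these markers) cannot be expressed.
- The loss cutoff is a per-category scalar; no probabilistic calibration
  (temperature scaling, conformal prediction) is attempted.
- The NumPy training loop is single-core and intended for desk-scale
  corpora (thousands to tens of thousands of sequences), not GPU-scale
  training.
- Whether to truncate the N- or C-terminus of over-long sequences is a
  convention; the N-terminal prefix is kept.
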