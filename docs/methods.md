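# Methods

## Sequence representation

A genome is a string over {A, C, G, T, N}; everything outside ACGT is
normalized to the single sentinel `N` at ingest, and every window that
touches an `N` is skipped by all counters. The feature vector of a genome
is its k-mer relative-frequency vector: counts from a sliding window of
length k, divided by the number of *valid* windows. The classical
denominator n − k + 1 is generalized to the valid-window count so that
ambiguous or masked stretches do not deflate frequencies.

Strand handling (`strand_mode="both"`, the default): the forward sequence
and its reverse complement are scanned as two separate passes and the
counts summed. Windows never span a junction between the two strands, the
frequencies still sum to 1, and every word ends up with exactly the same
frequency as its reverse complement. The full 4^k feature space is kept —
no canonical-k-mer collapsing — so a word and its reverse complement are
redundant but individually addressable features, which keeps learned rules
readable. Default k = 4 (configurable 3–6): the smallest k at which
composition separates bacterial taxa well, while 4^k stays tiny.

Low-complexity masking reimplements the classic DUST triplet score: every
window of length w (default 64) is scored by its overlapping-triplet
counts c_t as Σ c_t(c_t − 1)/2 / (m − 1), m = w − 2, and windows above the
threshold (default 2.0) are masked to `N`. Triplets containing `N` are
ignored, which makes the operation idempotent; output length always equals
input length. The defaults are the conventional ones; masking is off by
default because, consistent with the preprocessing experiments below, it
does not change classification on this kind of signal.

## Significance scores (noise filtration)

Raw frequencies mix taxon signal with genome-wide composition. The
relative deviation

    z(W) = (p(W) − p̃(W)) / p̃(W)

re-expresses each word against a null expectation p̃. Three estimators are
provided, all computed per genome from the same strand mode and
valid-window denominators as the k-mer counts:

- **markov_k2** (order k−2 Markov): p̃(W) = p(W[1..k−1]) · p(W[2..k]) /
  p(W[2..k−1]); requires k ≥ 3. When the interior word is absent the
  expectation is 0 and a policy applies: `score_zero` (default, the score
  is 0) or `drop_feature` (the feature row is removed from the matrix).
  Megabase-scale genomes never hit this case; short test sequences do.
- **boundary**: p̃(W) = (f(W[1])·f(W[2..k]) + f(W[1..k−1])·f(W[k])) / 2,
  the symmetric average of the two boundary factorizations, computed on
  relative frequencies (the only scale on which the two products are
  commensurable).
- **iid**: p̃(W) = Π_i f(W[i]) from single-nucleotide frequencies. The
  per-position factors are multiplied in sorted order so the product is
  bit-identical for a word and its reverse complement under both-strand
  counting; without the canonical ordering, floating-point
  non-associativity breaks the exact symmetry the tests assert.

Only the expectation form of these scores is implemented — no variance
normalization and no compositional (CLR/ILR) transforms.

## Supervised discretization

Rule literals need interval bounds. Per feature, recursive minimum
description length partitioning (MDLP) sorts the training values,
considers midpoints between adjacent distinct values at class boundaries,
takes the entropy-minimizing cut, and accepts it only if its information
gain exceeds (log2(N−1) + Δ)/N with Δ = log2(3^c − 2) − [cE − c₁E₁ − c₂E₂];
accepted cuts recurse into both sides. Features that yield no cut are kept
as single-interval, uninformative features (stable feature indices) —
learners simply cannot split on them. An unsupervised equal-frequency
splitter (quantile cuts, duplicates collapsed) exists for experiments on
interval counts.

Intervals are half-open [lo, hi) everywhere, including the printable rule
dialect: a value exactly equal to an upper bound does **not** match.
Discretization is always fitted inside the training fold only; the CV
harness enforces this and a test spies on it. Whether to discretize once
globally or per fold is a genuinely open design point; per fold is the
leakage-free choice.

## Rule learners

Both learners produce an ordered decision list plus a default class;
prediction is the conclusion of the first rule whose literals all hold.
Literal bounds come from the MDLP cuts (or, for the RIPPER grower in
`discretizer="raw"` mode, midpoints between consecutive sorted values of
the growing data).

**RIPPER-style.** Classes are processed in ascending prevalence (ties
lexicographic), each against all remaining classes. Per rule: grow on a
2/3 split by greedily adding the literal with the best FOIL information
gain until no negatives are covered; prune on the held-out 1/3 by keeping
the literal prefix that maximizes (p − n)/(p + n). Rule addition stops
when the ruleset description length exceeds the best seen by 64 bits
(theory bits: subset-coding of the chosen conditions; exception bits:
log-binomial coding of false positives and negatives), or when a rule errs
on more than half of its pruning coverage. Two optimization passes then
compare each rule against a freshly grown replacement and a revision,
keeping the shortest total description, and rules whose removal shortens
the description are dropped. The default class is the majority among
uncovered training samples.

Tie-breaking is fully deterministic and intentionally signature-seeking:
on equal FOIL gain, prefer fewer covered negatives, then the *enrichment*
direction (f(W) ≥ t over f(W) < t — a genomic signature is an
over-representation, and an enrichment literal names the taxon's own
characteristic word rather than a sibling's depleted one), then the wider
empty data gap around the threshold (the maximum-margin separator
generalizes best and, on planted data, is the planted word rather than
one of its junction artifacts), then the lexicographically smaller k-mer.

**PART-style.** Repeatedly: build a pruned decision tree on the remaining
samples, convert its best leaf (most samples covered; ties broken by fewer
errors, more enrichment-side conditions, shallower path) into a rule,
remove the covered samples. Trees split *binarily* at individual MDLP cut
points (f(W) ≥ cut), chosen by gain ratio with the same margin tie-break;
binary splits at interval boundaries are the standard C4.5 treatment of
numeric attributes and keep one noise-accepted secondary cut from
dragging down a good feature's gain ratio, as a multiway split over all of
its cells would. Pruning replaces a subtree by a leaf whenever the
pessimistic error estimate (binomial upper confidence bound, confidence
0.25, minimum leaf size 2) does not get worse.

A within-rule disjunction on one feature (the complement of an interval)
is representable: a literal holds a union of half-open intervals. The
learners only ever emit single-interval literals; the union form exists
for parsing published rule sets. Model complexity is reported as number
of rules (default excluded), mean literals per rule, and distinct k-mers.

## Evaluation

Accuracy is A = c/t. Cross-validation is stratified k-fold (default 10):
per class, samples are shuffled and dealt round-robin, so per-class fold
sizes differ by at most one. The aggregate accuracy is pooled over all
folds (total correct / total tested), which matches A = c/t literally and
equals the fold-size-weighted mean of per-fold accuracies. Classes with a
single member cannot be stratified and are excluded with a warning; when
the smallest class is below the fold count, the fold count is reduced to
it. Before any rank-level analysis, classes with fewer than nine specimens
are filtered out (too few for meaningful training and testing). The
per-rank report runs filter + CV per rank and learner and prints percent
accuracies (2 decimals) with row-wise mean ± standard deviation; ranks
with no usable classes are marked `-`.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes:
taxon-specific biases in 4-mer frequencies on an i.i.d. background,
nested across ranks. A taxonomy (default 2 phyla × 1 class × 1 order ×
1 genus × 2 species = 4 species) is drawn; every taxon **with siblings**
receives 2 signature 4-mers, globally distinct and never the reverse
complement of another signature, so signatures stay unambiguous under
both-strand counting. Taxa without siblings get no signal of their own —
none is needed (the partition they induce coincides with an ancestor's),
and it keeps the total planted mass under the 30% saturation guard that
rejects over-saturated configurations.

Each genome (default 50 kb, 10 per species) is uniform background into
which non-overlapping copies of every lineage signature are planted at
random positions until the word's forward-strand frequency reaches
bias × its background expectation (default bias 5, i.e. 5/256 ≈ 0.0195,
capped at 0.05): the number of planted copies is the target count minus
the expected background count. Planted copies never overlap each other;
overlap with chance background occurrences simply adds to the measured
frequency. Under both-strand counting the measured enrichment of a planted
word is (bias + 1)/2, since its reverse complement mirrors the signal on
the other strand; the fidelity checks therefore measure the forward
strand. With bias 0 nothing is planted and genome composition is exactly
background. All outputs are deterministic functions of the seed, down to
FASTA bytes.

What the generator does *not* emulate: phylogenetic substitution
structure, GC skew, repeats, coding constraints, or shared signal between
unrelated taxa. Passing the benchmark shows the pipeline recovers planted
compositional signal at realistic magnitudes and calibrates correctly
under nulls — not that real genomes are this cleanly separable. One real
phenomenon the insertion scheme *does* reproduce is correlated side
signal: junction words formed where planted copies meet background are
themselves class-correlated at roughly half the signature's contrast,
which is exactly why the margin tie-break matters.

Recovery is scored as the fraction of learned-rule literals whose k-mer
(or its reverse complement) was planted somewhere along the lineage of the
taxon the rule concludes.

## Numerical and degenerate-input choices

- Frequencies sum to 1 within 1e−9 whenever any window is valid; a record
  with no valid window yields an all-zero vector plus a warning.
- z-scores with zero expectation follow the configured policy (default 0).
- MDLP tie between equal-entropy cuts: the smaller cut value wins.
- All learner randomness (grow/prune splits) flows from one seeded
  generator; equal seeds give byte-identical serialized models, CV
  results, reports and simulated FASTA.
- Exit codes of the CLI: 0 success, 2 bad arguments (including k outside
  3–6 without `--allow-any-k`), 3 input format errors, 4 empty dataset
  after rare-class filtering.

## Problem sizes

The default benchmark is 40 genomes of 50 kb with 256 features; the test
suite and the acceptance script use it (plus 10–20 kb variants for
structural tests), chosen so the complete pipeline — simulation, counting,
per-fold MDLP, both learners, 10-fold CV at five ranks, nulls and the
preprocessing comparison — demonstrates every contract at comfortably
interactive runtimes.

## Known limitations

- RIPPER description-length bookkeeping follows the standard formulation
  in spirit but does not promise parity with any particular legacy
  implementation, and the optimization pass is a compact variant
  (replacement + revision judged by total description length).
- DUST parity with the NCBI binary is not promised; the triplet score and
  defaults are the conventional ones.
- The significance scores implement expectations only (no variance term).
- k is capped at 12 (4^k feature blow-up); the CLI guards k to 3–6 unless
  overridden.
- Real-data effects — assembly gaps, contamination, plasmids, horizontal
  transfer — are out of scope for the generator and untested here.
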