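# Methods

## The segmentation model

`protseg` treats a protein's per-residue embedding matrix (L residues × D
dimensions) as a multivariate signal along the sequence and poses boundary
detection as offline change-point analysis. The working assumption is that a
functional unit (folded domain, IDR, compositional bias, targeting signal)
embeds as an approximately stationary stretch of rows, and that transitions
between units shift the row distribution. Nothing is trained: detection is a
fixed kernel statistic on the embedding, which is what makes the approach
zero-shot and applicable to regions with too few labelled examples to train
on.

### Kernel cost and gain curve

For rows `x_a .. x_{b-1}` the RBF-kernel least-squares cost is

    c(a, b) = n − (1/n) Σ_{i,j} exp(−γ ‖x_i − x_j‖²),  n = b − a,

zero when all rows are identical and growing with within-window
heterogeneity. A window of `window = 30` residues (even, default from the
sliding-window design: 15 before vs 15 after) is slid over all admissible
centers `t ∈ [w/2, L − w/2]`, and the discrepancy

    gain(t) = c(t−w/2, t+w/2) − c(t−w/2, t) − c(t, t+w/2)

is recorded. The implementation evaluates the kernel only on the |i−j| < w
band with per-offset cumulative sums, so a protein costs O(L·w·D + L·w)
rather than O(L²·D); an O(n²) double-loop oracle is kept in the tests.

**Bandwidth.** γ is resolved per protein by the median heuristic
(γ = 1 / median pairwise squared row distance, estimated from a seeded sample
of 2 000 row pairs). This keeps the statistic scale-free across embedding
providers and dimensions. Degenerate matrices (all rows identical) fall back
to γ = 1, where the kernel is constant anyway; a fixed-γ override exists for
oracle comparisons.

### Boundary selection

Candidates are local maxima of the gain curve with positive gain (plateaus
keep their first position; positivity is tested against `1e−9 · window` to
absorb floating-point cancellation in the cost differences, not as a
sensitivity knob). They are accepted greedily in decreasing gain order under
a minimum spacing of `window/2` (non-maximum suppression — two boundaries
cannot fall inside one window), stopping at the budget
`ceil(3 · L / 100)` boundaries. Proteins shorter than the window return a
single whole-protein segment rather than erroring.

**A known property of the budget.** Under homogeneous noise the expected
cost of n i.i.d. rows is `(n−1)(1−κ)` with κ the mean off-diagonal kernel
value, so the expected gain of a homogeneous window is `(1−κ) > 0`: with
noisy, temporally uncorrelated rows essentially every surviving local
maximum has positive gain and the budget binds. The "peaks, not budget,
limit the output" saturation regime is therefore a property of
signal-limited inputs — smooth real embeddings, or the generator's
noise-free limit, where homogeneous gains are exactly zero and the
qualifying peaks are exactly the true change points. The acceptance suite
measures saturation (budget 3 vs 6 per 100 residues) in that regime; on the
noisy synthetic corpus the budget binds by design and doubling it adds
boundaries.

### Boundary confidence and segment scores

Each internal boundary gets a confidence score: per embedding dimension a
two-sample t statistic (Welch form; 0/0 treated as 0) between the ≤ 15 rows
before and ≤ 15 after, aggregated as the mean absolute t over dimensions —
an aggregation chosen to be symmetric and dimension-count invariant. A
segment's score is the mean of its two boundary scores; terminal segments
use their single scored boundary; a single-segment protein stays unscored.
These scores rank predictions for precision-recall-at-k curves; they are
computed per prefix rather than with library PR routines because interval
predictions never enumerate all possible segments, so recall does not reach
1 as the threshold loosens.

### Over-segmentation correction

The detector deliberately over-segments relative to coarse annotations. Two
corrections are provided. The cosine merge recomputes all-pairs cosine
similarity of the protein's pooled segment embeddings; if the globally most
similar pair is adjacent in sequence, it is merged (union interval,
embedding re-pooled from the residue matrix) and the loop repeats; it stops
when the most similar pair is non-adjacent or fewer than 6 segments remain.
Proteins that start below 6 segments are never touched: with 3 segments the
middle one is adjacent to everything and would always merge regardless of
similarity. Iteration to the fixed point is the default; `iterate=False`
applies at most one merge. The cluster merge simply collapses maximal runs
of adjacent same-cluster segments. Both are monotone in segment count and
preserve the tiling invariant (checked by property tests).

## Annotation transfer and evaluation

Transfer uses the inclusive 30 %-of-segment intersection rule; the segment
length is always the denominator, and annotations of any size may donate
labels. Multi-class mode takes the qualifying annotation with the highest
IoU (ties: longer annotation, then lexicographic label — determinism, since
the rule itself does not order ties); multi-label mode takes every
qualifying label once. A segment is flagged as an IDR when the union of its
disorder-source overlaps covers ≥ 30 % of it (union rather than any single
annotation — the more permissive reading when disorder calls are fragmented).
Protein-level label sets (e.g. compartment localization) broadcast to all
segments or, with `idr_only`, to flagged segments only. Corpus-level label
filtering removes labels seen fewer than 25 times; stripped segments remain
in the corpus as neighbour candidates.

The segmentation benchmark filters positives to annotations ≥ 30 residues
that do not span their whole protein, on proteins ≥ 60 residues. Matching is
best-IoU per side, not one-to-one assignment: AIoU(pred) averages each
prediction's best IoU against the positives, AIoU(pos) symmetrically;
precision and recall count the segments whose best IoU reaches the 0.5
threshold. A single positive can therefore validate several predictions —
stated in the report metadata because it differs from detection-style
bipartite matching. Boundary evaluation pairs each positive with its
highest-IoU overlapping prediction (ties: earlier start) and scores the
start- and end-offsets separately, strictly below 10 residues counting as
recovered; unpaired positives contribute two misses so the denominator is
always 2·n_pos. Score-aware deduplication of external predictions drops the
worse-scoring member of any same-protein pair with IoU > 0.5, greedily from
the best prediction down.

## Nearest-neighbour categorization

Labels are predicted by copying the label (set) of the nearest corpus
member under cosine distance. Protein-level labels use same-protein
exclusion (every segment of the protein shares the label, so self-protein
neighbours are uninformative); positional labels exclude only adjacent
segments of the same protein (they usually inherit the same annotation).
When the nearest neighbour is excluded the next admissible one is used. The
exact backend is a brute-force cosine scan; an approximate backend is a
declared contract for very large corpora and is not used by any test. The
multi-class report is a count matrix C[true, predicted] normalized per
predicted-label column, so the diagonal reads precision; 95 % binomial CIs
are Wald by default with Wilson behind a flag (the CI flavour is a
reporting convention, labelled in the output). Multi-label evaluation
scores each label as a binary task against the neighbour's label set.
Discovery-mode k-NN pools the top-k neighbours over several queries,
removes duplicates, and joins adjacent same-protein results into one
interval; exact self-matches are excluded by identity, not by value.

## Colour mapping and clustering helpers

Segment embeddings are reduced to 3 dimensions (default: UMAP with a fixed
seed; any corpus→(n,3) reducer can be plugged in, and tests use a fixed
linear projection so the contract is checkable deterministically), centred
per dimension on the corpus mean, and passed through a sigmoid scaled by
255: `channel = 255 · σ(X_d − mean_d)`. A segment at the corpus mean maps to
127.5; channels are strictly monotone in their coordinate; values stay
float until serialization, where they round to integer RGB. Centring
happens once over the fitted corpus — incremental re-colouring of a growing
corpus is unsupported because colours are only comparable within one fit.
Heatmap row ordering uses average-linkage agglomerative clustering on
cosine distance with optimal leaf ordering; residue-level clustering cuts
the same dendrogram at cosine distance 0.5.

## Discovery statistics

The enrichment test asks whether a cluster of residues carries more binary
site annotations (e.g. methylation) than chance. It is operationally a
permutation test: site flags are shuffled among exchangeable residues —
residues of the same amino-acid type within the same protein, or within the
same annotated region when a `region_id` column is supplied (the region
definition is the caller's, not guessed) — holding cluster membership
fixed. The observed statistic is the flagged fraction of the cluster; the
null is the distribution of that fraction over `n = 10 000` within-group
permutations (vectorized as one argsort per group across all shuffles);
reported are the z-score against the null moments and the empirical
p-value `r/n`, printed as `< 1/n` when no null draw reaches the observation
(no +1 smoothing, matching the r/n reporting convention). Unannotated
segments are grouped by Leiden community detection on a symmetrized cosine
k-NN graph (k = 15) at resolution 2.0 with unlimited iterations and a fixed
seed, in the full embedding dimension — no reduction before clustering.

## Synthetic data: what it does and does not emulate

The generator stands in for proteome-scale pLM embeddings. Each protein is
piecewise-constant: planted boundaries split L = 300 residues into blocks of
≥ 40, each block takes one of 4 class means (adjacent blocks always differ),
and rows are the block mean plus isotropic Gaussian noise (SD 1). Class
means are drawn once per corpus and rescaled so that `separation` means a
per-dimension separation: the minimum pairwise distance between class means
is `separation · noise_sd · √D` — i.e. two adjacent blocks differ by
`separation` noise SDs per coordinate on RMS average. D defaults to 32
rather than 1024 purely for speed; every algorithm is dimension-agnostic.
Default conditions: 100 proteins, 3 boundaries each, separation 2.

Real pLM embeddings differ in ways the generator does not model: rows are
strongly autocorrelated along the sequence, anisotropic, and transitions
are gradual rather than step-like. Passing tests on the generator therefore
certify the algorithmic contracts (oracle equivalence, recovery of planted
truth, calibration), not proteome-scale benchmark numbers; the i.i.d. noise
is in fact harsher than real data for the saturation property discussed
above. Site-flag tables for the shuffle test are generated under an
exchangeable null (flags placed uniformly within each protein) or with a
weighted tilt towards cluster members for the enriched case.

## Numerical choices and degenerate inputs

- Costs are clamped at ≥ 0; gains are compared against `1e−9 · window`.
- Median-heuristic sampling uses a seeded generator; identical inputs give
  identical boundaries.
- t-statistics with zero variance and zero mean difference are 0; with
  nonzero difference they are +inf (the segment still ranks above finite
  scores).
- Cosine similarity treats zero vectors as unit-norm to avoid NaNs; leaf
  ordering returns input order when all rows are identical.
- Annotation rows with non-numeric positions are dropped and counted;
  inverted or out-of-range intervals are rejected with warnings.
- Empirical p-values are never 0: below resolution they are reported as the
  `< 1/n` marker with `empirical_p = None`.

## Problem sizes

Tests and the acceptance script run on one CPU in well under a minute
each: 100-protein corpora (L = 300, D = 32) for recovery/saturation, 100
random 50×8 matrices for the kernel oracle, 1 000 random interval pairs for
the IoU oracle, 50 seeded corpora (~100 segments each) for 1-nn precision,
and 200 replicate datasets × 500 shuffles for type-I calibration. These
sizes were chosen as the smallest at which the statistical checks have
stable Monte-Carlo error.

## Known limitations

- The saturation property does not hold under temporally uncorrelated noise
  (see above); on such inputs the boundary budget is the binding constraint.
- Boundary confidence scores are heuristic ranks, not calibrated
  probabilities.
- The ProtT5 adapter validates its contract (row count = sequence length,
  refusal of sequences ≥ 8 000 residues) but requires `torch` +
  `transformers` at runtime; all tests run on precomputed or synthetic
  matrices. Batch- and hardware-dependent jitter of pLM inference is out of
  scope.
- The colour map is corpus-relative: colours from different fits are not
  comparable.
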