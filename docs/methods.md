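# Methods

## Scanpath representation

A trial's eye-movement record enters the analysis as an ordered sequence
of fixated AOI labels. The representation deliberately discards fixation
durations, saccade geometry and higher-order sequential structure: the
working assumption is that the strategies of interest differ in their
*first-order* transition patterns between semantically meaningful
regions. Where that assumption fails (strategies differing only in
timing, or in second-order structure), the method is blind by design.

Fixations are binned by rectangle membership with half-open intervals
[x0, x1) × [y0, y1). Rectangles must be pairwise disjoint (validated at
scheme construction; overlap is an error), so every on-stimulus point
belongs to exactly one AOI and boundary fixations resolve
deterministically. Fixations outside every AOI are dropped by default
and the per-trial removal count is always reported; a strict mode raises
instead. No minimum-duration filter is applied — event detection is
assumed done upstream.

The transition matrix is built from consecutive-pair counts and
row-normalised. Two conventions matter and are worth stating:

- **Zero rows.** An AOI with no outgoing transitions keeps an all-zero
  row rather than a uniform one. A uniform row would inject d⁻¹
  probability mass into every cell of an unvisited AOI's row, moving
  such trials toward the centroid of the simplex and distorting
  distances; all-zero keeps unvisited AOIs neutral in the Euclidean
  geometry the clustering uses.
- **Self-transitions** are retained by default. Collapsing repeated
  fixations (maximal runs of the same label → one label) is an explicit
  option, appropriate for stimuli where within-AOI refixations are
  frequent and carry little strategic information; after collapsing, the
  count matrix has a zero diagonal. Toggle counts are invariant to
  collapsing, since a toggle crosses between distinct AOI groups.

Sequences with fewer than two labels carry no transitions; they produce
all-zero vectors, are excluded from clustering by default, and the
exclusion count is reported.

## Clustering

Vectors are clustered with standard k-means minimising within-cluster
sum of squared Euclidean distances (scikit-learn's Lloyd algorithm,
k-means++ seeding). Because only "standard k-means" is specified by the
method, determinism comes from configuration: 50 restarts by default,
best solution by WSS, fixed `random_state`; convergence tolerance 1e-8
on relative WSS change, 300 iterations maximum. No column
standardisation is applied — all d² features already share the
probability scale.

The number of clusters is a user decision made from the scree of WSS
against k. The package computes and reports the curve but never selects
an elbow automatically, reflecting the inherently subjective nature of
the procedure.

Cluster indices are arbitrary, so any comparison against reference
labels first resolves label switching. For k = 2 the rule is: keep the
estimated labels if the confusion-matrix diagonal sum is at least the
off-diagonal sum, otherwise swap (ties keep identity). This guarantees
aligned total accuracy ≥ 0.5. For k > 2 the permutation maximising the
diagonal is found by optimal assignment (Hungarian algorithm), again
preferring identity on ties.

Derived diagnostics:

- **Classification accuracy** — total (diagonal / grand total) and
  per-class (diagonal / true-class row sum, reported missing for absent
  classes); **estimated class proportions** are column sums over the
  grand total.
- **Center stability** — across replicate simulations, the Pearson
  correlation over the d² center entries is computed for every unordered
  pair of replicates, per cluster label (labels aligned to truth
  first), and summarised by median and IQR. Constant centers make the
  correlation undefined; such pairs are counted and excluded. All pairs
  are used by default; an optional seeded subsample of pairs exists as
  a speed valve for very large replicate counts.
- **Representativeness** — a trial's Euclidean distance to a cluster
  center divided by the sum of its distances to all centers; smaller is
  more typical, scores sum to 1 across clusters. A variant excluding the
  own-cluster distance from the denominator is exposed as an option,
  since either reading of "relative to the other clusters" is
  defensible; the all-cluster form is the default because its scores
  are normalised. When a trial coincides with two or more centers the
  score is undefined and reported as a tie (NaN).
- **Cross-solution agreement** — the joint count table of two
  solutions' assignments over the same trials, plus the agreement rate
  after optimal label matching; used to judge whether solutions with
  different k nest.

## The Mastermind simulator

The generator emulates scanpaths on a two-pin deductive Mastermind item
with six AOIs — five conjecture rows (1–5) and the response area (6) —
where the third row's feedback suffices to solve the item. Two
strategies are modelled as first-order Markov kernels (start
distribution + 6 × 6 row-stochastic template):

- **systematic** (label 1): starts mostly on row 3, toggles strongly
  between row 3 and the response, short sequences (mean 8 fixations);
- **top-to-bottom** (label 2): starts on row 1, advances down the rows
  with per-row excursions to the response and back, occasional
  regressions, long sequences (mean 18 fixations). Its row 3 carries a
  substantial excursion to the response (0.40) and the response returns
  preferentially to row 3 (0.26), so top-to-bottom scanpaths can
  transiently resemble the systematic signature — deliberate overlap
  that makes the recovery problem non-trivial and is the main source of
  asymmetric misclassification (top-to-bottom trials mistaken for
  systematic more often than the reverse, and hence a slight
  underestimation of the top-to-bottom proportion).

Sequence length is a shifted negative binomial (minimum 2 fixations, so
every scanpath has at least one transition; dispersion 4 and 6
respectively). Within-strategy variability comes from a single
contamination parameter ε: each transition is replaced with probability
ε by a uniform draw over all six AOIs. ε = 0.10 for both strategies is
the calibrated default — chosen so that two-cluster recovery on
balanced samples sits in the low-to-mid 0.90s rather than at ceiling,
the regime the method is meant to be stress-tested in. All generator
defaults live in one JSON-serialisable configuration
(`DEFAULT_KERNEL_CONFIG`) and can be overridden from a file.

A sample of n simulated players contains an exact count round(n·p) of
top-to-bottom scanpaths: p is a sample proportion, contributing no
sampling variance. One master seed spawns an independent stream per
sequence, so sequence i is invariant to the sample size and to
generation order. Each simulated player contributes a single item.

What the generator does *not* emulate: fixation coordinates and
durations, saccade geometry, item-to-item variation, within-trial
strategy switching, or participant-level consistency across items.
Passing recovery tests on this data therefore demonstrates that the
pipeline can separate two first-order Markov populations under
contamination noise at realistic sequence lengths — not that real
populations are two such kernels.

## The simulation study

The evaluation runs a factorial grid over sample size n ∈ {20, 60, 100}
and top-to-bottom proportion p ∈ {0.25, 0.50, 0.75}. Per replicate: a
fresh sample is simulated, transition vectors built (self-transitions
retained), two-cluster k-means fitted, labels aligned to truth, and
total accuracy, per-strategy accuracy, the estimated top-to-bottom
proportion and the aligned centers recorded. Cells are summarised by
medians and interquartile ranges; center stability uses all unordered
replicate pairs. Replicates with degenerate clustering (fewer distinct
vectors than clusters) would be counted and excluded, not silently
dropped.

The design object defaults to 600 replicates per cell; the test suite
and the acceptance script run 100–200 replicates per cell, which keeps
the full grid under a minute on a single CPU while leaving the cell
medians stable to the granularity the summaries are read at (the
Monte-Carlo IQRs of neighbouring replication counts overlap, which the
suite asserts). Scree curves (k = 1..10) are computed on a configurable
subset of replicates (default 10 per cell) since they are inspected
qualitatively, not aggregated into a decision. Reproducibility is exact:
the same master seed yields bit-identical study results.

## Numerical and degenerate-input conventions

- k-means requires at least k distinct vectors; duplicates below that
  threshold raise a named error rather than producing empty clusters.
- Empty-cluster handling during Lloyd iterations follows scikit-learn's
  internal relocation remedy.
- Per-class accuracy for a class absent from the sample is NaN
  ("missing"), never 0/0.
- Toggle rate for a single-fixation trial is missing, not zero.
- Seeds are kept below 2³¹ wherever they cross into library APIs.

## Limitations

- First-order transition matrices cannot distinguish strategies that
  differ in higher-order structure or timing, and very different
  scanpaths can share a transition matrix.
- k-means implicitly favours equal-sized, spherical clusters; under a
  dominant strategy (p = 0.75) this biases assignment toward the
  minority cluster and degrades accuracy — visible in the study's
  monotone accuracy drop from balanced to unbalanced cells.
- AOI schemes must be known in advance and rectangular; data-driven or
  non-rectangular regions are out of scope.
- The simulator's two-kernel world is a favourable case: real data may
  hold more sub-patterns, within-trial switching, and hierarchical
  (participant/item) structure that the method ignores.
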