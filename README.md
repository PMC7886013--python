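# scanclust

Unsupervised discovery of latent cognitive strategies from eye-movement
scanpaths.

When people solve a cognitive task — a deductive Mastermind game, a
matrix-reasoning item — they may adopt qualitatively different scanning
strategies, and which strategy a given trial reflects is usually
unobserved. `scanclust` infers such latent groups from eye movements
alone: each trial's fixation sequence over pre-defined areas of interest
(AOIs) is summarised by its first-order transition matrix, and the
matrices are clustered with k-means. The package is aimed at
eye-tracking researchers who have fixation data (or pre-coded AOI
sequences) on stimuli that divide naturally into labeled regions.

## Method

For a stimulus with *d* AOIs, a trial's scanpath is the ordered sequence
of fixated AOI labels. Counting consecutive pairs gives a *d* × *d*
count matrix; row-normalising yields the transition probability matrix
**M**, where **M**<sub>ij</sub> = P(next fixation on AOI *j* | current
fixation on AOI *i*). Rows of AOIs with no outgoing transitions are kept
identically zero. Each matrix is flattened row-major into a
*d*²-vector, the *n* trial vectors are stacked into an *n* × *d*² data
matrix, and standard k-means (squared-Euclidean within-cluster sum of
squares, k-means++ seeding, 50 restarts, deterministic per seed)
partitions the trials. The number of clusters is chosen by inspecting
the scree of within-cluster sum of squares — never automatically.

Supporting tools cover the full workflow:

- **aoi_mapping** — rectangle AOI schemes (half-open, validated
  disjoint), fixation-to-AOI binning with explicit off-AOI handling,
  sequence CSV I/O;
- **transitions** — counts, probabilities, vectorisation, optional
  collapsing of repeated fixations;
- **strategy_clustering** — k-means, scree data, label-switching
  resolution against reference labels (confusion-matrix diagonal rule),
  classification accuracy and class-proportion estimates, cluster-center
  stability across replicates (pairwise Pearson correlations),
  per-trial representativeness scores, cross-solution agreement;
- **mastermind_simulator** — a calibrated generator of labeled synthetic
  Mastermind scanpaths over 6 AOIs (five conjecture rows + response)
  under a *top-to-bottom* and a *systematic* strategy;
- **simulation_study** — the factorial Monte-Carlo evaluation of
  strategy recovery (accuracy, proportion recovery, center stability);
- **scanpath_metrics** — fixation counts, toggle counts/rates, and
  per-cluster outcome tabulations.

## Worked example

Simulate a balanced sample of 60 players (half using each strategy),
cluster their transition matrices, and score recovery against the known
labels:

```python
from scanclust import (SimulationParams, simulate_sample, build_data_matrix,
                       kmeans_cluster, confusion_matrix, align_labels,
                       classification_metrics, scree)

seqs = simulate_sample(SimulationParams(n=60, p=0.5, seed=42))
X, meta = build_data_matrix(seqs)          # (60, 36) data matrix
sol = kmeans_cluster(X, k=2, seed=1)
C = confusion_matrix(meta["true_strategy"], sol.assignments, k=2)
perm = align_labels(C)                     # resolve label switching
m = classification_metrics(
    confusion_matrix(meta["true_strategy"], perm[sol.assignments - 1], k=2))
```

This prints (via the obvious `print` calls):

```
first systematic scanpath: [3, 4, 3, 5, 6]
data matrix: (60, 36)
total accuracy: 0.900
per-class accuracy (systematic, top-to-bottom): (0.900, 0.900)
estimated top-to-bottom proportion: 0.500
k=1  wss=107.2
k=2  wss=83.8
k=3  wss=74.1
k=4  wss=67.1
```

The systematic scanpath toggles between the informative third row and
the response area (AOI 6); two-cluster k-means recovers 90 % of the true
strategy labels in this single sample, estimates the strategy mix at
0.50, and the scree drops sharply from k = 1 to k = 2 and flattens
after — the signature of two latent groups.

The same workflow is available from the shell:

```bash
scanclust simulate --n 100 --p 0.5 --seed 1 --out seqs.csv
scanclust cluster --in seqs.csv --from-sequences 6 --k 2 --seed 1 --out-dir results/
scanclust study --reps 100 --seed 1 --out-dir study/
scanclust metrics --in seqs.csv --d 6 --response-aois 6 --out metrics.csv
```

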