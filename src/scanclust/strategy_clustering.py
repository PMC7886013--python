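"""k-means clustering of transition vectors and its evaluation diagnostics.

The d^2-dimensional transition vectors are clustered with standard
k-means (squared-Euclidean within-cluster sum of squares, k-means++
seeding, many restarts, deterministic per seed).  Entries already share
the probability scale, so no column standardisation is applied.

Because cluster indices are arbitrary, comparing an estimated solution
against reference labels (ground truth in simulations, or another
solution) requires resolving label switching: estimated labels are
permuted to maximise the diagonal of the confusion matrix.  For k = 2
this is the simple rule "keep the labels if the diagonal sum is at least
the off-diagonal sum, otherwise swap".

The remaining helpers provide the diagnostics used to evaluate a
clustering: scree data (within-cluster sum of squares by k),
classification accuracy and estimated class proportions, stability of
cluster centers across replicate simulations (pairwise Pearson
correlations), per-trial representativeness scores, and agreement
between solutions with different k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

__all__ = [
    "ClusterSolution",
    "ClassificationMetrics",
    "kmeans_cluster",
    "scree",
    "confusion_matrix",
    "align_labels",
    "apply_permutation",
    "classification_metrics",
    "center_stability",
    "representativeness",
    "cross_solution_agreement",
]

DEFAULT_N_INIT = 50
_MAX_ITER = 300
_TOL = 1e-8


@dataclass(frozen=True)
class ClusterSolution:
    """A fitted k-means solution; cluster labels are 1..k."""

    k: int
    centers: np.ndarray  # (k, d^2)
    assignments: np.ndarray  # (n,) ints in 1..k
    wss: float
    seed: int
    n_init: int

    def relabel(self, perm: np.ndarray) -> "ClusterSolution":
        """Return the same solution with cluster j renamed perm[j-1]."""
        perm = np.asarray(perm)
        inv = np.empty(self.k, dtype=int)
        inv[perm - 1] = np.arange(1, self.k + 1)
        new_centers = self.centers[inv - 1]
        new_assign = perm[self.assignments - 1]
        return ClusterSolution(
            k=self.k,
            centers=new_centers,
            assignments=new_assign,
            wss=self.wss,
            seed=self.seed,
            n_init=self.n_init,
        )


def kmeans_cluster(
    vectors: np.ndarray,
    k: int,
    seed: int,
    n_init: int = DEFAULT_N_INIT,
) -> ClusterSolution:
    """Best-of-``n_init`` k-means fit, deterministic given the seed.

    Raises if there are fewer vectors than k, or fewer *distinct*
    vectors than k (duplicate points cannot support k centers).
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        raise ValueError("vectors must be a 2-D array (n, d^2)")
    n = X.shape[0]
    if n < k:
        raise ValueError(f"cannot fit k={k} clusters to {n} vectors")
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(
            f"only {n_distinct} distinct vectors among {n}; "
            f"cannot support k={k} clusters"
        )
    km = KMeans(
        n_clusters=k,
        n_init=n_init,
        random_state=int(seed) % (2**31),
        max_iter=_MAX_ITER,
        tol=_TOL,
        algorithm="lloyd",
    ).fit(X)
    return ClusterSolution(
        k=k,
        centers=km.cluster_centers_.copy(),
        assignments=km.labels_.astype(int) + 1,
        wss=float(km.inertia_),
        seed=int(seed),
        n_init=int(n_init),
    )


def scree(
    vectors: np.ndarray,
    k_max: int,
    seed: int,
    n_init: int = DEFAULT_N_INIT,
) -> list[tuple[int, float]]:
    """Within-cluster sum of squares for k = 1..k_max, for scree inspection.

    No elbow is selected automatically: choosing the number of clusters
    from the scree plot is left to the analyst.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    return [
        (k, kmeans_cluster(vectors, k, seed=seed, n_init=n_init).wss)
        for k in range(1, k_max + 1)
    ]


def confusion_matrix(
    true_labels: Sequence[int], estimated_labels: Sequence[int], k: int
) -> np.ndarray:
    """k x k counts: rows index true (reference) labels, columns estimated."""
    t = np.asarray(true_labels, dtype=int)
    e = np.asarray(estimated_labels, dtype=int)
    if t.shape != e.shape:
        raise ValueError("label vectors differ in length")
    C = np.zeros((k, k), dtype=np.int64)
    np.add.at(C, (t - 1, e - 1), 1)
    return C


def align_labels(confusion: np.ndarray) -> np.ndarray:
    """Permutation of estimated labels maximising the confusion diagonal.

    Returns ``perm`` with ``perm[j-1]`` the new name of estimated
    cluster j.  For k = 2 this reduces to: keep the identity when the
    diagonal sum is >= the off-diagonal sum, otherwise swap.  Ties keep
    the identity permutation.
    """
    C = np.asarray(confusion)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {C.shape}")
    k = C.shape[0]
    if k == 2:
        if C[0, 0] + C[1, 1] >= C[0, 1] + C[1, 0]:
            return np.array([1, 2])
        return np.array([2, 1])
    # general case: optimal assignment of estimated columns to true rows
    row_ind, col_ind = linear_sum_assignment(-C)
    perm = np.empty(k, dtype=int)
    perm[col_ind] = row_ind + 1
    if np.trace(C) >= C[row_ind, col_ind].sum():
        return np.arange(1, k + 1)
    return perm


def apply_permutation(labels: Sequence[int], perm: np.ndarray) -> np.ndarray:
    """Rename labels: cluster j becomes perm[j-1]."""
    labels = np.asarray(labels, dtype=int)
    return np.asarray(perm)[labels - 1]


@dataclass(frozen=True)
class ClassificationMetrics:
    total_accuracy: float
    per_class_accuracy: np.ndarray  # NaN where the true class is empty
    estimated_proportions: np.ndarray


def classification_metrics(confusion: np.ndarray) -> ClassificationMetrics:
    """Accuracy and class-proportion estimates from an aligned confusion matrix.

    Per-class accuracy is diagonal over true-class (row) total, reported
    as NaN for classes absent from the sample; the estimated proportion
    of class j is the column-j total over the grand total.
    """
    C = np.asarray(confusion, dtype=float)
    total = C.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    row_sums = C.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row_sums > 0, np.diag(C) / row_sums, np.nan)
    return ClassificationMetrics(
        total_accuracy=float(np.trace(C) / total),
        per_class_accuracy=per_class,
        estimated_proportions=C.sum(axis=0) / total,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan  # constant vector: correlation undefined
    return float(np.dot(a, b) / (na * nb))


def center_stability(
    center_sets: Sequence[np.ndarray],
    max_pairs: int | None = None,
    seed: int = 0,
) -> dict[int, dict[str, float | np.ndarray]]:
    """Pairwise Pearson correlations of like-labeled centers across replicates.

    ``center_sets`` holds one (k, d^2) array per replicate, with labels
    already aligned across replicates (e.g. to ground truth).  For each
    cluster label the correlation over the d^2 center entries is
    computed for every unordered pair of replicates and summarised by
    the median and interquartile range.  Undefined correlations
    (constant centers) are recorded as NaN and excluded from summaries.

    ``max_pairs`` optionally subsamples replicate pairs (seeded) as a
    speed valve for very large replicate counts; default is all pairs.
    """
    if len(center_sets) < 2:
        raise ValueError("center stability needs at least 2 replicates")
    k = center_sets[0].shape[0]
    if any(cs.shape != center_sets[0].shape for cs in center_sets):
        raise ValueError("replicate center sets differ in shape")
    R = len(center_sets)
    pairs = [(i, j) for i in range(R) for j in range(i + 1, R)]
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    out: dict[int, dict[str, float | np.ndarray]] = {}
    stacked = np.stack(center_sets)  # (R, k, d^2)
    for c in range(k):
        cors = np.array(
            [_pearson(stacked[i, c], stacked[j, c]) for i, j in pairs]
        )
        valid = cors[~np.isnan(cors)]
        out[c + 1] = {
            "correlations": cors,
            "median": float(np.median(valid)) if valid.size else np.nan,
            "q25": float(np.percentile(valid, 25)) if valid.size else np.nan,
            "q75": float(np.percentile(valid, 75)) if valid.size else np.nan,
            "n_undefined": int(np.isnan(cors).sum()),
        }
    return out


def representativeness(
    vector: np.ndarray,
    centers: np.ndarray,
    include_own: bool = True,
) -> np.ndarray:
    """Relative Euclidean distance of a transition vector to each center.

    ``score_c = d_c / sum_j d_j`` where ``d_j`` is the Euclidean distance
    to center j; smaller means more representative of that cluster, and
    with the all-cluster denominator (default) the scores sum to 1.
    With ``include_own=False`` the denominator for cluster c excludes
    ``d_c`` itself.  If the vector coincides with two or more centers all
    relevant distances vanish and the scores are NaN (a tie).
    """
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 2 or centers.shape[0] < 2:
        raise ValueError("need at least 2 cluster centers")
    dists = np.linalg.norm(centers - np.asarray(vector, dtype=float), axis=1)
    if include_own:
        total = dists.sum()
        if total == 0:
            return np.full(len(dists), np.nan)
        return dists / total
    denom = dists.sum() - dists
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, dists / denom, np.nan)
    return scores


def cross_solution_agreement(
    solution_a: "ClusterSolution", solution_b: "ClusterSolution"
) -> tuple[np.ndarray, float]:
    """Joint assignment counts of two solutions over the same vectors.

    Returns the k_a x k_b count table (entry (a, b): vectors in cluster
    a of A and cluster b of B) and the agreement rate after optimally
    matching B's labels to A's.
    """
    a = solution_a.assignments
    b = solution_b.assignments
    if a.shape != b.shape:
        raise ValueError("solutions cover different numbers of vectors")
    table = np.zeros((solution_a.k, solution_b.k), dtype=np.int64)
    np.add.at(table, (a - 1, b - 1), 1)
    row_ind, col_ind = linear_sum_assignment(-table)
    agreement = float(table[row_ind, col_ind].sum() / table.sum())
    return table, agreement
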