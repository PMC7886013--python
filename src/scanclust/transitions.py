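"""First-order AOI transition matrices and their vector representation.

Each scanpath (ordered AOI labels) is summarised by a d x d matrix of
transition counts ``C``, where ``C[i, j]`` counts consecutive fixation
pairs moving from AOI i to AOI j.  Row-normalising gives the transition
probability matrix ``M``: conditional on a fixation on AOI i, ``M[i, j]``
is the probability that the next fixation lands on AOI j.  Rows of AOIs
with no outgoing transitions are kept identically zero (not uniform), so
never-visited AOIs contribute nothing to the clustering space; their
labels are recorded in ``zero_rows``.

Matrices are flattened row-major into length-d^2 vectors and stacked into
an n x d^2 data matrix, the input to k-means clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .aoi_mapping import AOISequence

__all__ = [
    "TransitionCounts",
    "TransitionMatrix",
    "collapse_repeats",
    "transition_counts",
    "transition_matrix",
    "vectorize",
    "unvectorize",
    "sequence_to_vector",
    "build_data_matrix",
    "write_vectors",
    "read_vectors",
]


@dataclass(frozen=True)
class TransitionCounts:
    d: int
    C: np.ndarray  # (d, d) nonnegative ints
    n_transitions: int

    def __post_init__(self) -> None:
        if self.C.shape != (self.d, self.d):
            raise ValueError(f"count matrix shape {self.C.shape} != ({self.d}, {self.d})")
        if int(self.C.sum()) != self.n_transitions:
            raise ValueError("count matrix total does not match n_transitions")


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic d x d matrix; all-zero rows listed in ``zero_rows`` (1-based)."""

    d: int
    M: np.ndarray
    zero_rows: frozenset[int]

    def __post_init__(self) -> None:
        if self.M.shape != (self.d, self.d):
            raise ValueError(f"matrix shape {self.M.shape} != ({self.d}, {self.d})")
        rowsums = self.M.sum(axis=1)
        for i, s in enumerate(rowsums, start=1):
            if i in self.zero_rows:
                if not np.allclose(self.M[i - 1], 0.0):
                    raise ValueError(f"row {i} declared zero but has mass")
            elif not np.isclose(s, 1.0):
                raise ValueError(f"row {i} sums to {s}, expected 1")


def collapse_repeats(seq: AOISequence) -> AOISequence:
    """Collapse maximal runs of identical consecutive labels to one label.

    Used for stimuli where within-AOI refixations are frequent and
    uninformative (e.g. matrix-reasoning response areas); idempotent.
    """
    labels = seq.labels
    collapsed = [lab for i, lab in enumerate(labels) if i == 0 or lab != labels[i - 1]]
    return replace(seq, labels=collapsed)


def transition_counts(seq: AOISequence) -> TransitionCounts:
    """Count consecutive AOI pairs; a length-<2 sequence yields all zeros."""
    C = np.zeros((seq.d, seq.d), dtype=np.int64)
    labels = seq.labels
    for a, b in zip(labels, labels[1:]):
        C[a - 1, b - 1] += 1
    return TransitionCounts(d=seq.d, C=C, n_transitions=max(len(labels) - 1, 0))


def transition_matrix(counts: TransitionCounts) -> TransitionMatrix:
    """Row-normalise counts into transition probabilities."""
    rowsums = counts.C.sum(axis=1)
    M = np.zeros((counts.d, counts.d), dtype=float)
    nonzero = rowsums > 0
    M[nonzero] = counts.C[nonzero] / rowsums[nonzero, None]
    zero_rows = frozenset(int(i) + 1 for i in np.flatnonzero(~nonzero))
    return TransitionMatrix(d=counts.d, M=M, zero_rows=zero_rows)


def vectorize(tm: TransitionMatrix) -> np.ndarray:
    """Row-major flattening of M into a length-d^2 vector."""
    return tm.M.reshape(-1).copy()


def unvectorize(v: np.ndarray, d: int) -> TransitionMatrix:
    """Inverse of :func:`vectorize`; exact round-trip."""
    v = np.asarray(v, dtype=float)
    if v.shape != (d * d,):
        raise ValueError(f"vector length {v.size} != d^2 = {d * d}")
    M = v.reshape(d, d)
    zero_rows = frozenset(int(i) + 1 for i in np.flatnonzero(M.sum(axis=1) == 0))
    return TransitionMatrix(d=d, M=M.copy(), zero_rows=zero_rows)


def sequence_to_vector(seq: AOISequence, collapse: bool = False) -> np.ndarray:
    if collapse:
        seq = collapse_repeats(seq)
    return vectorize(transition_matrix(transition_counts(seq)))


def build_data_matrix(
    sequences: Sequence[AOISequence],
    collapse: bool = False,
    drop_degenerate: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack per-trial transition vectors into an n x d^2 data matrix.

    Sequences with fewer than 2 labels (after optional collapsing) carry
    no transitions and produce all-zero vectors; by default they are
    excluded, and the returned metadata frame reports how many were
    dropped via its ``attrs['n_degenerate_dropped']``.

    Returns ``(X, meta)`` where ``meta`` has one row per retained trial
    (participant, item, true_strategy).
    """
    if not sequences:
        raise ValueError("no sequences supplied")
    d = sequences[0].d
    if any(s.d != d for s in sequences):
        raise ValueError("sequences have inconsistent d")
    rows, meta_rows = [], []
    n_dropped = 0
    for s in sequences:
        s2 = collapse_repeats(s) if collapse else s
        if drop_degenerate and len(s2) < 2:
            n_dropped += 1
            continue
        rows.append(sequence_to_vector(s2))
        meta_rows.append(
            {"participant": s.participant, "item": s.item, "true_strategy": s.true_strategy}
        )
    if not rows:
        raise ValueError("all sequences were degenerate (fewer than 2 labels)")
    X = np.vstack(rows)
    meta = pd.DataFrame(meta_rows)
    meta.attrs["n_degenerate_dropped"] = n_dropped
    return X, meta


def write_vectors(X: np.ndarray, meta: pd.DataFrame, d: int, target) -> None:
    """Write the data matrix as CSV; cell_{(i-1)*d+j} holds M_ij (row-major)."""
    cols = [f"cell_{c}" for c in range(1, d * d + 1)]
    out = pd.concat(
        [meta.reset_index(drop=True), pd.DataFrame(X, columns=cols)], axis=1
    )
    out.to_csv(target, index=False)


def read_vectors(source) -> tuple[np.ndarray, pd.DataFrame, int]:
    """Read a transition-vector CSV; returns (X, meta, d)."""
    df = pd.read_csv(source)
    cells = [c for c in df.columns if c.startswith("cell_")]
    if not cells:
        raise ValueError("no cell_* columns found in vector table")
    d = int(round(len(cells) ** 0.5))
    if d * d != len(cells):
        raise ValueError(f"{len(cells)} cell columns is not a perfect square")
    cells = [f"cell_{c}" for c in range(1, d * d + 1)]
    X = df[cells].to_numpy(dtype=float)
    meta = df[[c for c in df.columns if not c.startswith("cell_")]].copy()
    return X, meta, d
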