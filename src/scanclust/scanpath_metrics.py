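"""Descriptive scanpath statistics: fixation counts, toggles, outcomes.

A *toggle* is a transition that crosses, in either direction, the
boundary between the problem area and the designated response AOIs
(e.g. the response-alternatives matrix in matrix-reasoning tasks).
The toggle rate divides the toggle count by the total number of
transitions in the scanpath.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aoi_mapping import AOISequence

__all__ = ["ToggleSummary", "toggle_summary", "fixation_counts", "outcome_by_cluster"]


@dataclass(frozen=True)
class ToggleSummary:
    n_fixations: int
    n_transitions: int
    n_toggles: int
    toggle_rate: float  # NaN when there are no transitions


def toggle_summary(seq: AOISequence, response_aois: set[int]) -> ToggleSummary:
    """Count boundary crossings between problem and response AOIs.

    ``response_aois`` must be a non-empty proper subset of 1..d.  Both
    directions (into and out of the response area) count as toggles.
    """
    if not response_aois:
        raise ValueError("response_aois must be non-empty")
    if not response_aois <= set(range(1, seq.d + 1)):
        raise ValueError(f"response_aois {response_aois} not within 1..{seq.d}")
    if response_aois >= set(range(1, seq.d + 1)):
        raise ValueError("response_aois must be a proper subset of the AOIs")
    is_resp = [lab in response_aois for lab in seq.labels]
    n_toggles = sum(a != b for a, b in zip(is_resp, is_resp[1:]))
    n_transitions = max(len(seq) - 1, 0)
    rate = n_toggles / n_transitions if n_transitions > 0 else float("nan")
    return ToggleSummary(
        n_fixations=len(seq),
        n_transitions=n_transitions,
        n_toggles=n_toggles,
        toggle_rate=rate,
    )


def fixation_counts(
    sequences: Sequence[AOISequence], assignments: Sequence[int]
) -> pd.DataFrame:
    """Per-cluster summaries of sequence lengths (fixation counts).

    Clusters with no members appear with n = 0 and NaN summaries.
    """
    if len(sequences) != len(assignments):
        raise ValueError("one assignment per sequence required")
    lengths = np.array([len(s) for s in sequences])
    clusters = np.asarray(assignments, dtype=int)
    rows = []
    for c in sorted(set(clusters.tolist())):
        x = lengths[clusters == c]
        rows.append(
            {
                "cluster": c,
                "n": int(x.size),
                "mean": float(x.mean()) if x.size else np.nan,
                "median": float(np.median(x)) if x.size else np.nan,
                "q25": float(np.percentile(x, 25)) if x.size else np.nan,
                "q75": float(np.percentile(x, 75)) if x.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def outcome_by_cluster(
    assignments: Sequence[int], outcomes: Sequence[int]
) -> pd.DataFrame:
    """Tabulate a binary outcome (e.g. correct answer) per cluster.

    Returns columns cluster, n, n_correct, prop_correct.
    """
    clusters = np.asarray(assignments, dtype=int)
    y = np.asarray(outcomes, dtype=int)
    if clusters.shape != y.shape:
        raise ValueError("assignments and outcomes differ in length")
    if not set(np.unique(y).tolist()) <= {0, 1}:
        raise ValueError("outcomes must be binary (0/1)")
    rows = []
    for c in sorted(set(clusters.tolist())):
        mask = clusters == c
        n = int(mask.sum())
        n_correct = int(y[mask].sum())
        rows.append(
            {
                "cluster": c,
                "n": n,
                "n_correct": n_correct,
                "prop_correct": n_correct / n,
            }
        )
    return pd.DataFrame(rows)
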