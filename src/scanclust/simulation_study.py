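"""Monte-Carlo evaluation of strategy recovery on simulated Mastermind data.

Runs a factorial design over sample size n and top-to-bottom proportion
p.  Each replicate draws a fresh simulated sample, converts every
scanpath to a 6 x 6 transition matrix, vectorises, fits two-cluster
k-means, aligns the estimated labels to ground truth via the confusion-
matrix diagonal rule, and records:

* total and per-strategy classification accuracy,
* the estimated proportion of top-to-bottom scanpaths,
* the aligned cluster centers (for cross-replicate stability:
  pairwise Pearson correlations per cluster),
* optionally, the within-cluster sum of squares for k = 1..k_max on a
  subset of replicates, for scree inspection.

Per-cell results are summarised by medians and interquartile ranges.
Label alignment to truth happens before both the accuracy and the
center-stability computations.  Scree curves are reported for
inspection only; no automatic choice of k is made.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mastermind_simulator import (
    SYSTEMATIC,
    TOP_TO_BOTTOM,
    SimulationParams,
    StrategyKernel,
    default_kernels,
    simulate_sample,
)
from .strategy_clustering import (
    align_labels,
    apply_permutation,
    center_stability,
    classification_metrics,
    confusion_matrix,
    kmeans_cluster,
    scree,
)
from .transitions import build_data_matrix

__all__ = ["StudyDesign", "CellResult", "StudyResult", "run_cell", "run_study"]


@dataclass(frozen=True)
class StudyDesign:
    """The factorial simulation design and its computational settings."""

    n_values: tuple[int, ...] = (20, 60, 100)
    p_values: tuple[float, ...] = (0.25, 0.50, 0.75)
    reps: int = 600
    k_for_metrics: int = 2
    k_max_scree: int = 10
    seed: int = 1
    n_init: int = 50
    scree_reps: int = 10  # scree curves are computed on this many replicates per cell
    kernels: dict[int, StrategyKernel] | None = None

    def __post_init__(self) -> None:
        if self.reps < 2:
            raise ValueError("reps must be >= 2")
        if not self.n_values or not self.p_values:
            raise ValueError("design grid must be non-empty")


@dataclass
class CellResult:
    """Raw per-replicate results for one (n, p) design cell."""

    n: int
    p: float
    total_accuracy: np.ndarray
    systematic_accuracy: np.ndarray  # NaN where the true class is empty
    top_to_bottom_accuracy: np.ndarray
    estimated_p_top_to_bottom: np.ndarray
    aligned_centers: list[np.ndarray]
    scree_curves: list[list[tuple[int, float]]]
    n_failed: int

    def summarize(self) -> dict:
        def mq(x: np.ndarray) -> dict:
            v = x[~np.isnan(x)]
            if v.size == 0:
                return {"median": np.nan, "q25": np.nan, "q75": np.nan}
            return {
                "median": float(np.median(v)),
                "q25": float(np.percentile(v, 25)),
                "q75": float(np.percentile(v, 75)),
            }

        stability = center_stability(self.aligned_centers)
        return {
            "n": self.n,
            "p": self.p,
            "total_accuracy": mq(self.total_accuracy),
            "systematic_accuracy": mq(self.systematic_accuracy),
            "top_to_bottom_accuracy": mq(self.top_to_bottom_accuracy),
            "estimated_p_top_to_bottom": mq(self.estimated_p_top_to_bottom),
            "center_correlation_systematic": {
                k: v for k, v in stability[SYSTEMATIC].items() if k != "correlations"
            },
            "center_correlation_top_to_bottom": {
                k: v
                for k, v in stability[TOP_TO_BOTTOM].items()
                if k != "correlations"
            },
            "n_failed": self.n_failed,
        }


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint32)[0]) % (2**31)


def run_cell(
    n: int,
    p: float,
    reps: int,
    seed: int,
    kernels: dict[int, StrategyKernel] | None = None,
    n_init: int = 50,
    k: int = 2,
    scree_reps: int = 0,
    k_max_scree: int = 10,
) -> CellResult:
    """Run all replicates of one design cell.

    Replicates whose clustering is degenerate (fewer distinct transition
    vectors than clusters) are excluded and counted in ``n_failed``
    rather than silently dropped.
    """
    kernels = kernels if kernels is not None else default_kernels()
    rep_seeds = np.random.SeedSequence(seed).spawn(reps)
    total, acc_sys, acc_ttb, prop_ttb = [], [], [], []
    centers_list: list[np.ndarray] = []
    scree_curves: list[list[tuple[int, float]]] = []
    n_failed = 0
    for r, rep_ss in enumerate(rep_seeds):
        sim_ss, km_ss = rep_ss.spawn(2)
        params = SimulationParams(
            n=n, p=p, kernels=kernels, seed=_derive_seed(sim_ss)
        )
        sequences = simulate_sample(params)
        X, meta = build_data_matrix(sequences, collapse=False, drop_degenerate=True)
        truth = meta["true_strategy"].to_numpy(dtype=int)
        km_seed = _derive_seed(km_ss)
        try:
            solution = kmeans_cluster(X, k=k, seed=km_seed, n_init=n_init)
        except ValueError:
            n_failed += 1
            continue
        C = confusion_matrix(truth, solution.assignments, k=k)
        perm = align_labels(C)
        aligned = solution.relabel(perm)
        C_aligned = confusion_matrix(truth, aligned.assignments, k=k)
        metrics = classification_metrics(C_aligned)
        total.append(metrics.total_accuracy)
        acc_sys.append(metrics.per_class_accuracy[SYSTEMATIC - 1])
        acc_ttb.append(metrics.per_class_accuracy[TOP_TO_BOTTOM - 1])
        prop_ttb.append(metrics.estimated_proportions[TOP_TO_BOTTOM - 1])
        centers_list.append(aligned.centers)
        if r < scree_reps:
            scree_curves.append(scree(X, k_max_scree, seed=km_seed, n_init=n_init))
    return CellResult(
        n=n,
        p=p,
        total_accuracy=np.asarray(total, dtype=float),
        systematic_accuracy=np.asarray(acc_sys, dtype=float),
        top_to_bottom_accuracy=np.asarray(acc_ttb, dtype=float),
        estimated_p_top_to_bottom=np.asarray(prop_ttb, dtype=float),
        aligned_centers=centers_list,
        scree_curves=scree_curves,
        n_failed=n_failed,
    )


@dataclass
class StudyResult:
    """All design cells plus tabular summaries of the full study."""

    design: StudyDesign
    cells: dict[tuple[float, int], CellResult]

    def summaries(self) -> dict[tuple[float, int], dict]:
        return {key: cell.summarize() for key, cell in self.cells.items()}

    def accuracy_table(self) -> pd.DataFrame:
        """Median (IQR) of total and per-strategy classification accuracy."""
        rows = []
        for (p, n), s in self.summaries().items():
            rows.append(
                {
                    "p": p,
                    "n": n,
                    **_flatten("total", s["total_accuracy"]),
                    **_flatten("systematic", s["systematic_accuracy"]),
                    **_flatten("top_to_bottom", s["top_to_bottom_accuracy"]),
                }
            )
        return pd.DataFrame(rows)

    def proportion_table(self) -> pd.DataFrame:
        """Median (IQR) of the estimated top-to-bottom proportion."""
        rows = [
            {"p": p, "n": n, **_flatten("p_top_to_bottom", s["estimated_p_top_to_bottom"])}
            for (p, n), s in self.summaries().items()
        ]
        return pd.DataFrame(rows)

    def stability_table(self) -> pd.DataFrame:
        """Median (IQR) of pairwise center correlations per cluster."""
        rows = []
        for (p, n), s in self.summaries().items():
            rows.append(
                {
                    "p": p,
                    "n": n,
                    **_flatten("systematic", s["center_correlation_systematic"]),
                    **_flatten(
                        "top_to_bottom", s["center_correlation_top_to_bottom"]
                    ),
                }
            )
        return pd.DataFrame(rows)

    def scree_table(self) -> pd.DataFrame:
        """Median within-cluster sum of squares by k across scree replicates."""
        rows = []
        for (p, n), cell in self.cells.items():
            if not cell.scree_curves:
                continue
            arr = np.array([[w for _, w in curve] for curve in cell.scree_curves])
            for j, k in enumerate(kk for kk, _ in cell.scree_curves[0]):
                rows.append(
                    {"p": p, "n": n, "k": k, "wss_median": float(np.median(arr[:, j]))}
                )
        return pd.DataFrame(rows)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.accuracy_table().to_csv(out / "table1.csv", index=False)
        self.proportion_table().to_csv(out / "table2.csv", index=False)
        self.stability_table().to_csv(out / "table3.csv", index=False)
        self.scree_table().to_csv(out / "scree.csv", index=False)
        manifest = {
            "n_values": list(self.design.n_values),
            "p_values": list(self.design.p_values),
            "reps": self.design.reps,
            "seed": self.design.seed,
            "n_init": self.design.n_init,
            "scree_reps": self.design.scree_reps,
            "k_for_metrics": self.design.k_for_metrics,
            "k_max_scree": self.design.k_max_scree,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _flatten(prefix: str, mq: dict) -> dict:
    return {
        f"{prefix}_median": mq["median"],
        f"{prefix}_q25": mq["q25"],
        f"{prefix}_q75": mq["q75"],
    }


def run_study(design: StudyDesign) -> StudyResult:
    """Execute the full design grid with independent per-cell seed streams."""
    cell_seeds = np.random.SeedSequence(design.seed).spawn(
        len(design.p_values) * len(design.n_values)
    )
    cells: dict[tuple[float, int], CellResult] = {}
    i = 0
    for p in design.p_values:
        for n in design.n_values:
            cells[(p, n)] = run_cell(
                n=n,
                p=p,
                reps=design.reps,
                seed=_derive_seed(cell_seeds[i]),
                kernels=design.kernels,
                n_init=design.n_init,
                k=design.k_for_metrics,
                scree_reps=design.scree_reps,
                k_max_scree=design.k_max_scree,
            )
            i += 1
    return StudyResult(design=design, cells=cells)
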