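"""Mapping fixations to areas of interest (AOIs) and AOI-sequence I/O.

An AOI scheme is a set of labeled, pairwise-disjoint rectangles on the
stimulus (screen coordinates, origin top-left, y increasing downward).
Rectangle membership uses half-open intervals ``[x0, x1) x [y0, y1)`` so
that shared edges are claimed by exactly one rectangle and boundary
handling is deterministic.

A trial's scanpath is operationalized as the ordered sequence of fixated
AOI labels (:class:`AOISequence`).  Fixations falling outside every AOI
are either dropped (with the removal count reported per trial) or raise,
depending on policy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "Fixation",
    "AOIRegion",
    "AOIScheme",
    "AOISequence",
    "AssignmentResult",
    "assign_fixations",
    "read_fixations",
    "read_sequences",
    "write_sequences",
]


@dataclass(frozen=True)
class Fixation:
    """A single fixation event within a (participant, item) trial.

    ``index`` is the 1-based ordinal position of the fixation in its
    trial; ``x``/``y`` are screen coordinates in pixels.
    """

    participant: str
    item: str
    index: int
    x: float
    y: float
    duration: float | None = None

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(
                f"non-finite fixation coordinates ({self.x}, {self.y}) "
                f"in trial ({self.participant}, {self.item})"
            )


@dataclass(frozen=True)
class AOIRegion:
    """Axis-aligned rectangle ``[x0, x1) x [y0, y1)`` with integer label."""

    label: int
    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(
                f"region {self.label}: degenerate rectangle "
                f"({self.x0},{self.y0})-({self.x1},{self.y1})"
            )

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def overlaps(self, other: "AOIRegion") -> bool:
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
        )


@dataclass(frozen=True)
class AOIScheme:
    """A validated set of ``d`` disjoint rectangular AOIs labeled 1..d."""

    d: int
    regions: tuple[AOIRegion, ...]

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError(f"an AOI scheme needs d >= 2 regions, got d={self.d}")
        labels = sorted(r.label for r in self.regions)
        if labels != list(range(1, self.d + 1)):
            raise ValueError(
                f"region labels must be exactly 1..{self.d}, got {labels}"
            )
        regs = self.regions
        for i in range(len(regs)):
            for j in range(i + 1, len(regs)):
                if regs[i].overlaps(regs[j]):
                    raise ValueError(
                        f"AOI regions {regs[i].label} and {regs[j].label} overlap"
                    )

    def locate(self, x: float, y: float) -> int | None:
        """Label of the unique region containing (x, y), or None."""
        for r in self.regions:
            if r.contains(x, y):
                return r.label
        return None

    @classmethod
    def from_dict(cls, doc: dict) -> "AOIScheme":
        regions = tuple(
            AOIRegion(int(r["label"]), r["x0"], r["y0"], r["x1"], r["y1"])
            for r in doc["regions"]
        )
        return cls(d=int(doc["d"]), regions=regions)

    @classmethod
    def from_json(cls, path) -> "AOIScheme":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "d": self.d,
            "regions": [
                {"label": r.label, "x0": r.x0, "y0": r.y0, "x1": r.x1, "y1": r.y1}
                for r in self.regions
            ],
        }


@dataclass
class AOISequence:
    """One trial's ordered sequence of fixated AOI labels.

    ``true_strategy`` is only set on simulated data, where the generating
    strategy is known; it is the ground truth against which unsupervised
    cluster assignments are scored.
    """

    participant: str
    item: str
    labels: list[int]
    d: int
    true_strategy: int | None = None

    def __post_init__(self) -> None:
        bad = [v for v in self.labels if not (1 <= v <= self.d)]
        if bad:
            raise ValueError(
                f"trial ({self.participant}, {self.item}): AOI labels {bad} "
                f"outside 1..{self.d}"
            )

    def __len__(self) -> int:
        return len(self.labels)


class AssignmentResult(NamedTuple):
    sequences: list[AOISequence]
    n_removed: dict[tuple[str, str], int]


def _group_trials(fixations: Iterable[Fixation]):
    trials: dict[tuple[str, str], list[Fixation]] = {}
    for f in fixations:
        trials.setdefault((f.participant, f.item), []).append(f)
    for key, fixs in trials.items():
        idx = [f.index for f in fixs]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(
                f"trial {key}: fixation indices not strictly increasing: {idx}"
            )
    return trials


def assign_fixations(
    fixations: Sequence[Fixation],
    scheme: AOIScheme,
    off_aoi_policy: Literal["drop", "error"] = "drop",
) -> AssignmentResult:
    """Bin each fixation into its AOI, one label sequence per trial.

    With ``off_aoi_policy='drop'`` fixations falling outside every region
    are removed and the per-trial removal count reported; with
    ``'error'`` the first off-AOI fixation raises, naming the trial and
    fixation index.  Input order within a trial is preserved.
    """
    if off_aoi_policy not in ("drop", "error"):
        raise ValueError(f"unknown off_aoi_policy {off_aoi_policy!r}")
    sequences: list[AOISequence] = []
    removed: dict[tuple[str, str], int] = {}
    for (participant, item), fixs in _group_trials(fixations).items():
        labels: list[int] = []
        n_off = 0
        for f in fixs:
            lab = scheme.locate(f.x, f.y)
            if lab is None:
                if off_aoi_policy == "error":
                    raise ValueError(
                        f"fixation {f.index} of trial ({participant}, {item}) "
                        f"at ({f.x}, {f.y}) falls outside every AOI"
                    )
                n_off += 1
            else:
                labels.append(lab)
        sequences.append(AOISequence(participant, item, labels, scheme.d))
        removed[(participant, item)] = n_off
    return AssignmentResult(sequences, removed)


def read_fixations(source) -> list[Fixation]:
    """Read a fixation table (CSV: participant,item,fix_index,x,y[,duration_ms])."""
    df = pd.read_csv(source)
    required = {"participant", "item", "fix_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fixation table missing columns: {sorted(missing)}")
    has_dur = "duration_ms" in df.columns
    return [
        Fixation(
            participant=str(row.participant),
            item=str(row.item),
            index=int(row.fix_index),
            x=float(row.x),
            y=float(row.y),
            duration=float(row.duration_ms) if has_dur else None,
        )
        for row in df.itertuples(index=False)
    ]


def read_sequences(source, d: int) -> list[AOISequence]:
    """Read AOI sequences from CSV (participant,item,fix_index,aoi[,true_strategy]).

    Labels are validated against 1..d and rows are ordered by fix_index
    within each trial; trials may be interleaved in the file.
    """
    df = pd.read_csv(source)
    required = {"participant", "item", "fix_index", "aoi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sequence table missing columns: {sorted(missing)}")
    bad = df[(df["aoi"] < 1) | (df["aoi"] > d)]
    if not bad.empty:
        rownum = int(bad.index[0]) + 2  # header is line 1
        raise ValueError(
            f"AOI label {bad['aoi'].iloc[0]} outside 1..{d} at file line {rownum}"
        )
    has_strategy = "true_strategy" in df.columns
    sequences = []
    for (participant, item), grp in df.groupby(["participant", "item"], sort=False):
        if grp["fix_index"].duplicated().any():
            dup = int(grp.loc[grp["fix_index"].duplicated(), "fix_index"].iloc[0])
            raise ValueError(
                f"trial ({participant}, {item}): duplicate fix_index {dup}"
            )
        grp = grp.sort_values("fix_index")
        strategy = None
        if has_strategy and grp["true_strategy"].notna().all():
            strategy = int(grp["true_strategy"].iloc[0])
        sequences.append(
            AOISequence(
                participant=str(participant),
                item=str(item),
                labels=[int(v) for v in grp["aoi"]],
                d=d,
                true_strategy=strategy,
            )
        )
    return sequences


def write_sequences(sequences: Sequence[AOISequence], target) -> None:
    """Write AOI sequences as the CSV accepted by :func:`read_sequences`."""
    rows = []
    any_strategy = any(s.true_strategy is not None for s in sequences)
    for s in sequences:
        for i, lab in enumerate(s.labels, start=1):
            row = {
                "participant": s.participant,
                "item": s.item,
                "fix_index": i,
                "aoi": lab,
            }
            if any_strategy:
                row["true_strategy"] = s.true_strategy
            rows.append(row)
    pd.DataFrame(rows).to_csv(target, index=False)
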