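"""Spatial clustered-search statistics for the grid search task.

The central quantity is the *dispersion measure*: for each selected tile,
the mean Manhattan distance to every other selected tile, averaged over
tiles and then over a participant's five grids.  Low values mean clustered
search, high values dispersed search.  The sequential-step variant measures
the Manhattan distance between consecutive selections, and its
resource-contingent split (steps after a reward vs. after a blank)
quantifies area-restricted search: local search after a hit, global
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist


@dataclass
class ClickSequence:
    """Ordered tile selections within one landscape.

    A full experimental sequence has exactly 80 distinct selections; the
    metrics below only require two or more.
    """

    rows: np.ndarray
    cols: np.ndarray
    payoffs: np.ndarray
    landscape_id: str | None = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        self.payoffs = np.asarray(self.payoffs, dtype=int)
        if not (len(self.rows) == len(self.cols) == len(self.payoffs)):
            raise ValueError("rows, cols and payoffs must have equal length")

    def __len__(self) -> int:
        return len(self.rows)

    @classmethod
    def from_tuples(cls, selections, landscape_id=None) -> "ClickSequence":
        """Build from (trial, row, col, payoff) tuples, sorted by trial."""
        sel = sorted(selections)
        _, rows, cols, pays = zip(*sel)
        return cls(np.array(rows), np.array(cols), np.array(pays), landscape_id)

    def validate_full(self, n_clicks: int = 80) -> None:
        """Enforce the experimental contract: n_clicks distinct tiles."""
        if len(self) != n_clicks:
            raise ValueError(f"expected {n_clicks} selections, got {len(self)}")
        if len({(r, c) for r, c in zip(self.rows, self.cols)}) != len(self):
            raise ValueError("selections revisit a tile")


@dataclass
class GridSearchRecord:
    """One participant's grid task: condition plus five click sequences."""

    participant_id: str
    condition: str
    sequences: list = field(default_factory=list)


def manhattan(p: tuple[int, int], q: tuple[int, int]) -> int:
    """|r1 - r2| + |c1 - c2| between two grid cells."""
    return abs(p[0] - q[0]) + abs(p[1] - q[1])


def pairwise_dispersion(seq: ClickSequence) -> float:
    """Mean over selected tiles of each tile's mean Manhattan distance to all
    other selected tiles.

    Algebraically equal to the mean over all unordered tile pairs, which is
    how it is computed here; selection order is irrelevant.
    """
    if len(seq) < 2:
        raise ValueError("dispersion needs at least 2 selections")
    pts = np.column_stack([seq.rows, seq.cols]).astype(float)
    return float(pdist(pts, metric="cityblock").mean())


def participant_dispersion(rec: GridSearchRecord) -> float:
    """Unweighted mean of per-grid dispersion across the participant's grids."""
    missing = [i for i, s in enumerate(rec.sequences, 1) if s is None or len(s) < 2]
    if missing or not rec.sequences:
        raise ValueError(f"missing or degenerate grids: {missing or 'all'}")
    return float(np.mean([pairwise_dispersion(s) for s in rec.sequences]))


def step_distances(seq: ClickSequence) -> np.ndarray:
    """Manhattan distance between selection t and t-1, for t = 2..n."""
    if len(seq) < 2:
        raise ValueError("step distances need at least 2 selections")
    return np.abs(np.diff(seq.rows)) + np.abs(np.diff(seq.cols))


def mean_step(seq: ClickSequence) -> float:
    return float(step_distances(seq).mean())


def participant_mean_step(rec: GridSearchRecord) -> float:
    return float(np.mean([mean_step(s) for s in rec.sequences]))


def contingent_step_means(seq: ClickSequence) -> tuple[float, float]:
    """(mean step after a hit, mean step after a miss).

    The step ending at selection t is classified by the payoff of selection
    t-1 ("after a resource was found"); the first selection contributes no
    step.  A class with no steps (e.g. a grid with zero hits before the last
    click) yields NaN.
    """
    steps = step_distances(seq)
    prev_hit = seq.payoffs[:-1] > 0
    after_hit = steps[prev_hit]
    after_miss = steps[~prev_hit]
    return (
        float(after_hit.mean()) if after_hit.size else math.nan,
        float(after_miss.mean()) if after_miss.size else math.nan,
    )


def participant_contingent_means(rec: GridSearchRecord) -> tuple[float, float]:
    """Per-grid contingent means averaged across grids, skipping grids where
    a class is undefined (rather than imputing); if a class is undefined in
    every grid the participant-level value is NaN."""
    per_grid = np.array([contingent_step_means(s) for s in rec.sequences], dtype=float)
    out = []
    for col in per_grid.T if per_grid.size else (np.array([]), np.array([])):
        vals = col[~np.isnan(col)]
        out.append(float(vals.mean()) if vals.size else math.nan)
    return out[0], out[1]
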