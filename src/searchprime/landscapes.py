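"""Reward-landscape generation for the grid search task.

Two families of 20x20 payoff grids are produced, mirroring the two
experimental conditions:

* **clustered** — rewards aggregated into a few patches, grown by iterative
  Moore-neighbourhood accretion (a patchy neutral-landscape model); whole
  landscapes are regenerated until the total reward count falls in [77, 83].
* **dispersed** — rewards placed one at a time by random sequential
  placement with Moore-neighbourhood inhibition: a candidate tile whose
  8-neighbourhood already holds a reward is accepted only with a small
  probability (0.001 by default), so exactly 80 rewards end up spread apart.

Every tile pays either 0 or 100 points, so a dispersed landscape has a mean
payoff of exactly 20 points per tile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

REWARD = 100
GRID_SIZE = 20

#: Offsets of the 8 cells surrounding a cell (Moore neighbourhood).
MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class LandscapeError(ValueError):
    """Raised for invalid landscape matrices or infeasible generator settings."""


@dataclass(frozen=True)
class ClusteredParams:
    """Settings for the patchy (clustered) generator.

    ``n_patches_range`` and ``patch_size_range`` are inclusive integer
    intervals sampled uniformly and independently; ``reward_count_range`` is
    the retention band on the total number of reward tiles.
    """

    n_patches_range: tuple[int, int] = (3, 5)
    patch_size_range: tuple[int, int] = (10, 20)
    reward_count_range: tuple[int, int] = (77, 83)
    grid_size: int = GRID_SIZE
    max_regenerations: int = 10_000

    def __post_init__(self) -> None:
        for lo, hi in (self.n_patches_range, self.patch_size_range, self.reward_count_range):
            if lo > hi or lo < 1:
                raise LandscapeError(f"empty or non-positive range ({lo}, {hi})")
        if self.grid_size ** 2 < self.n_patches_range[1] * self.patch_size_range[1]:
            raise LandscapeError("grid too small for the requested patches")


@dataclass(frozen=True)
class DispersedParams:
    """Settings for the inhibition-based (dispersed) generator."""

    n_reward: int = 80
    moore_accept_prob: float = 0.001
    grid_size: int = GRID_SIZE
    max_attempts: int = 10_000  # per full placement pass, then restart
    max_restarts: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.moore_accept_prob <= 1.0:
            raise LandscapeError("moore_accept_prob must be in [0, 1]")
        if self.n_reward > self.grid_size ** 2:
            raise LandscapeError("more rewards than tiles")


@dataclass
class Landscape:
    """A payoff grid plus its condition label and RNG provenance."""

    payoffs: np.ndarray
    condition: str  # "clustered" | "dispersed"
    seed_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.payoffs = np.asarray(self.payoffs, dtype=int)
        validate_payoffs(self.payoffs, grid_size=self.payoffs.shape[0] or GRID_SIZE)
        if self.condition not in ("clustered", "dispersed"):
            raise LandscapeError(f"unknown condition {self.condition!r}")

    @property
    def n_reward(self) -> int:
        return int((self.payoffs == REWARD).sum())

    @property
    def mean_payoff(self) -> float:
        return float(self.payoffs.mean())


def validate_payoffs(m: np.ndarray, grid_size: int = GRID_SIZE) -> None:
    if m.ndim != 2 or m.shape != (grid_size, grid_size):
        raise LandscapeError(f"payoff matrix must be {grid_size}x{grid_size}, got {m.shape}")
    if not np.isin(m, (0, REWARD)).all():
        bad = sorted(set(m.ravel()) - {0, REWARD})
        raise LandscapeError(f"payoffs must be 0 or {REWARD}; found {bad}")


def _moore_neighbours(cell: tuple[int, int], n: int):
    r, c = cell
    for dr, dc in MOORE:
        rr, cc = r + dr, c + dc
        if 0 <= rr < n and 0 <= cc < n:
            yield rr, cc


def _grow_patch(occupied: set, size: int, n: int, rng: np.random.Generator) -> set:
    """Grow one patch by uniform Moore-frontier accretion.

    The patch seed starts on a cell not already holding a reward; growth
    candidates are the 8-neighbours of the patch that are not yet *in this
    patch*, so different patches may overlap (the retention loop absorbs the
    resulting variance in total reward count).
    """
    empty = [(r, c) for r in range(n) for c in range(n) if (r, c) not in occupied]
    seed = empty[rng.integers(len(empty))]
    patch = {seed}
    while len(patch) < size:
        frontier = sorted({nb for cell in patch for nb in _moore_neighbours(cell, n)} - patch)
        if not frontier:
            break
        patch.add(frontier[rng.integers(len(frontier))])
    return patch


def generate_clustered(
    params: ClusteredParams = ClusteredParams(), rng: np.random.Generator | None = None
) -> Landscape:
    """Generate one clustered landscape, regenerating until the reward count
    lands in ``params.reward_count_range``."""
    rng = np.random.default_rng() if rng is None else rng
    n = params.grid_size
    lo, hi = params.reward_count_range
    for attempt in range(params.max_regenerations):
        occupied: set = set()
        n_patches = int(rng.integers(params.n_patches_range[0], params.n_patches_range[1] + 1))
        for _ in range(n_patches):
            size = int(rng.integers(params.patch_size_range[0], params.patch_size_range[1] + 1))
            occupied |= _grow_patch(occupied, size, n, rng)
        if lo <= len(occupied) <= hi:
            payoffs = np.zeros((n, n), dtype=int)
            for r, c in occupied:
                payoffs[r, c] = REWARD
            return Landscape(
                payoffs,
                "clustered",
                seed_info={"generator": "clustered", "regenerations": attempt + 1},
            )
    raise LandscapeError(
        f"no clustered landscape with {lo}-{hi} rewards after {params.max_regenerations} tries"
    )


def generate_dispersed(
    params: DispersedParams = DispersedParams(), rng: np.random.Generator | None = None
) -> Landscape:
    """Generate one dispersed landscape by sequential placement with
    Moore-neighbourhood inhibition."""
    rng = np.random.default_rng() if rng is None else rng
    n = params.grid_size
    for restart in range(params.max_restarts):
        occupied: set = set()
        empty = [(r, c) for r in range(n) for c in range(n)]
        attempts = 0
        while len(occupied) < params.n_reward and attempts < params.max_attempts:
            attempts += 1
            i = int(rng.integers(len(empty)))
            cand = empty[i]
            inhibited = any(nb in occupied for nb in _moore_neighbours(cand, n))
            if inhibited and rng.random() >= params.moore_accept_prob:
                continue
            occupied.add(cand)
            empty[i] = empty[-1]
            empty.pop()
        if len(occupied) == params.n_reward:
            payoffs = np.zeros((n, n), dtype=int)
            for r, c in occupied:
                payoffs[r, c] = REWARD
            return Landscape(
                payoffs,
                "dispersed",
                seed_info={"generator": "dispersed", "restarts": restart},
            )
    raise LandscapeError(
        f"could not place {params.n_reward} inhibited rewards within "
        f"{params.max_restarts} restarts"
    )


def write_landscape(landscape: Landscape, path: str | Path) -> None:
    """Write the payoff matrix as a 20-row CSV with a JSON metadata sidecar.

    Coordinates are 0-based (row, col), row-major: CSV row *i*, column *j*
    is grid cell (i, j).
    """
    path = Path(path)
    np.savetxt(path, landscape.payoffs, fmt="%d", delimiter=",")
    meta = {
        "condition": landscape.condition,
        "n_reward": landscape.n_reward,
        "seed_info": landscape.seed_info,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def read_landscape(path: str | Path) -> Landscape:
    """Read a landscape written by :func:`write_landscape`; the payoff
    matrix round-trips bit-exactly. Malformed shapes or entries outside
    {0, 100} are rejected."""
    path = Path(path)
    rows = [line.split(",") for line in path.read_text().strip().splitlines()]
    try:
        payoffs = np.array([[int(float(v)) for v in row] for row in rows], dtype=int)
    except ValueError as exc:
        raise LandscapeError(f"non-integer entry in {path}: {exc}") from exc
    meta_path = path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    validate_payoffs(payoffs, grid_size=payoffs.shape[1] if payoffs.ndim == 2 else GRID_SIZE)
    if payoffs.shape[0] != payoffs.shape[1]:
        raise LandscapeError(f"payoff matrix must be square, got {payoffs.shape}")
    return Landscape(
        payoffs,
        meta.get("condition", "clustered"),
        seed_info=meta.get("seed_info", {}),
    )


def landscape_pool(
    condition: str,
    n: int = 40,
    rng: np.random.Generator | None = None,
    clustered_params: ClusteredParams = ClusteredParams(),
    dispersed_params: DispersedParams = DispersedParams(),
) -> list[Landscape]:
    """The study keeps a pool of 40 landscapes per condition from which each
    participant's 5 grids are drawn without replacement."""
    rng = np.random.default_rng() if rng is None else rng
    gen = generate_clustered if condition == "clustered" else generate_dispersed
    params = clustered_params if condition == "clustered" else dispersed_params
    return [gen(params, rng) for _ in range(n)]
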