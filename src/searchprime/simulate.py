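"""Synthetic study generator with known ground truth.

Simulates the full two-condition experiment — landscape pools, grid-search
agents, pre/post anagram sessions and exclusion-relevant nuisance
behaviours — so the whole analysis pipeline can be exercised and calibrated
without human data.

* The grid agent is a win-stay/lose-shift policy: after a hit it searches
  within a small Chebyshev radius of its last selection with probability
  ``p_local_after_hit`` (global uniform otherwise), and analogously after a
  miss.  A strongly win-stay agent on patchy landscapes produces clustered
  search (low dispersion, short after-hit steps); a win-shift agent on
  dispersed landscapes does the opposite.
* Letter-set dwell times are log-normal.  The post-test phase is scaled by
  a multiplicative practice factor (< 1 makes everyone faster post-test, so
  both arms show negative delta-t), and a condition-by-phase effect
  ``delta`` on the log scale injects ground-truth priming into the
  clustered arm; ``delta = 0`` reproduces the null.
* Correct words are 4-letter draws from the 6-letter set; with probability
  ``chain_prob`` a word is instead derived from an earlier word by a
  single-letter substitution, from the immediately preceding word or (with
  probability ``anchor_persistence``) from the set's first solution.  High
  anchor persistence lowers the similarity between *consecutive* words,
  reproducing the direction of the within-set priming signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .anagrams import AnagramSession, LetterSet, Visit, WordEvent, generate_lettersets
from .landscapes import (
    ClusteredParams,
    DispersedParams,
    Landscape,
    landscape_pool,
)
from .spatial import ClickSequence

CONDITIONS = ("clustered", "dispersed")


@dataclass(frozen=True)
class AgentParams:
    """Win-stay/lose-shift search policy for the grid task."""

    p_local_after_hit: float = 0.9
    p_local_after_miss: float = 0.3
    local_radius: int = 1  # Chebyshev radius of "local"

    def __post_init__(self) -> None:
        for p in (self.p_local_after_hit, self.p_local_after_miss):
            if not 0.0 <= p <= 1.0:
                raise ValueError("policy probabilities must be in [0, 1]")
        if self.local_radius < 1:
            raise ValueError("local_radius must be >= 1")


#: Defaults calibrated to the qualitative study pattern: an area-restricted
#: searcher in the clustered arm (local after hits, still mostly local after
#: misses, i.e. it probes around a patch before leaving), and a win-shift
#: agent in the dispersed arm that jumps away after a reward.  These give a
#: clustered-arm mean step near 2.6 tiles, a dispersion gap with |d| well
#: above 1, and the after-hit/after-miss reversal between arms.
DEFAULT_AGENTS = {
    "clustered": AgentParams(p_local_after_hit=0.95, p_local_after_miss=0.9),
    "dispersed": AgentParams(p_local_after_hit=0.2, p_local_after_miss=0.6),
}


@dataclass(frozen=True)
class PrimingParams:
    """Generative model for letter-set dwell times.

    Dwell ~ LogNormal(log_dwell_mean + [post]*log(practice_effect)
    + [post & clustered]*delta, log_dwell_sd).  ``delta`` is the ground-truth
    condition-by-phase priming effect on the log scale; 0 is the null.
    """

    log_dwell_mean: float = math.log(90.0)  # median dwell 90 s per set
    log_dwell_sd: float = 0.5
    practice_effect: float = 0.7  # post-test sets ~30% faster
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.log_dwell_sd <= 0:
            raise ValueError("log_dwell_sd must be positive")
        if self.practice_effect <= 0:
            raise ValueError("practice_effect must be positive")


@dataclass(frozen=True)
class WordStreamParams:
    """Word-production model within a letter-set."""

    words_per_set_mean: float = 2.8  # mean correct words per letter-set
    chain_prob: float = 0.6  # P(word is an edit of an earlier word)
    anchor_persistence: float = 0.2  # P(edit source is the set's first word)
    incorrect_rate: float = 0.1  # invalid submissions, kept in the logs


DEFAULT_WORDS = {
    "clustered": WordStreamParams(anchor_persistence=0.7),
    "dispersed": WordStreamParams(anchor_persistence=0.1),
}


@dataclass
class StudyConfig:
    """Conditions of one simulated study; defaults mirror the experiment
    (168 per condition, 5 grids of 80 clicks, 14 letter-sets per phase,
    pools of 40 landscapes per condition)."""

    n_per_condition: int = 168
    seed: int = 0
    agents: dict = field(default_factory=lambda: dict(DEFAULT_AGENTS))
    priming: PrimingParams = PrimingParams()
    words: dict = field(default_factory=lambda: dict(DEFAULT_WORDS))
    p_comprehension_fail: float = 0.0
    p_inactivity: float = 0.0
    p_low_words: float = 0.0
    p_incomplete: float = 0.0
    n_grids: int = 5
    clicks_per_grid: int = 80
    n_lettersets: int = 14
    pool_size: int = 40
    balanced_assignment: bool = True  # False: Bernoulli arms (unequal n)
    clustered_params: ClusteredParams = ClusteredParams()
    dispersed_params: DispersedParams = DispersedParams()

    def __post_init__(self) -> None:
        if self.n_per_condition < 2:
            raise ValueError("need at least 2 participants per condition")
        for p in (self.p_comprehension_fail, self.p_inactivity, self.p_low_words, self.p_incomplete):
            if not 0.0 <= p <= 1.0:
                raise ValueError("nuisance rates must be in [0, 1]")


def simulate_grid_search(
    landscape: Landscape,
    agent: AgentParams,
    rng: np.random.Generator,
    n_clicks: int = 80,
    landscape_id: str | None = None,
) -> ClickSequence:
    """Run the win-stay/lose-shift agent for ``n_clicks`` distinct tiles.

    After a hit (miss), with probability ``p_local_after_hit``
    (``p_local_after_miss``) the next tile is uniform among unrevealed tiles
    within ``local_radius`` of the last selection, falling back to a global
    uniform draw when no local tile is unrevealed; the first click is
    global uniform.
    """
    n = landscape.payoffs.shape[0]
    pay = landscape.payoffs
    unrevealed = [(r, c) for r in range(n) for c in range(n)]
    index = {cell: i for i, cell in enumerate(unrevealed)}

    def take(i: int) -> tuple[int, int]:
        cell = unrevealed[i]
        last = unrevealed[-1]
        unrevealed[i] = last
        index[last] = i
        unrevealed.pop()
        del index[cell]
        return cell

    rows, cols, pays = [], [], []
    last: tuple[int, int] | None = None
    rad = agent.local_radius
    for _ in range(n_clicks):
        cell = None
        if last is not None:
            p_local = agent.p_local_after_hit if pay[last] > 0 else agent.p_local_after_miss
            if rng.random() < p_local:
                local = [
                    (last[0] + dr, last[1] + dc)
                    for dr in range(-rad, rad + 1)
                    for dc in range(-rad, rad + 1)
                    if (last[0] + dr, last[1] + dc) in index
                ]
                if local:
                    cell = take(index[local[int(rng.integers(len(local)))]])
        if cell is None:
            cell = take(int(rng.integers(len(unrevealed))))
        rows.append(cell[0])
        cols.append(cell[1])
        pays.append(int(pay[cell]))
        last = cell
    return ClickSequence(np.array(rows), np.array(cols), np.array(pays), landscape_id)


def _chain_word(source: str, letters: str, rng: np.random.Generator) -> str:
    """Derive a word from ``source`` by substituting one letter with a
    letter of the set not already used (e.g. tale -> gale)."""
    unused = [ch for ch in letters.lower() if ch not in source]
    if not unused:
        return source
    pos = int(rng.integers(len(source)))
    return source[:pos] + unused[int(rng.integers(len(unused)))] + source[pos + 1 :]


def _fresh_word(letters: str, rng: np.random.Generator) -> str:
    picks = rng.choice(list(letters.lower()), size=4, replace=False)
    return "".join(picks)


def simulate_anagram_session(
    phase: str,
    condition: str,
    priming: PrimingParams,
    rng: np.random.Generator,
    lettersets: list[LetterSet] | None = None,
    words: WordStreamParams = WordStreamParams(),
    n_lettersets: int = 14,
    low_word_count: bool = False,
    generate_words: bool = True,
    start_time: float = 0.0,
) -> AnagramSession:
    """Simulate one anagram phase: log-normal dwells per letter-set, word
    submissions placed within each dwell, stopping at 30 correct words or
    when the letter-sets run out.

    ``low_word_count`` throttles word production so the participant finishes
    all 14 sets with well under 20 correct words (an exclusion behaviour).
    ``generate_words=False`` keeps word *counts* but skips word strings, for
    calibration runs that only need dwell-time outcomes.
    """
    if lettersets is None:
        lettersets = generate_lettersets(n_lettersets, rng)
    mu = priming.log_dwell_mean
    if phase == "post":
        mu += math.log(priming.practice_effect)
        if condition == "clustered":
            mu += priming.delta
    lam = 0.5 if low_word_count else max(words.words_per_set_mean - 1.0, 0.0)

    visits = []
    t = start_time
    total = 0
    for i, ls in enumerate(lettersets[:n_lettersets], start=1):
        dwell = float(rng.lognormal(mu, priming.log_dwell_sd))
        n_correct = int(rng.poisson(lam)) if low_word_count else 1 + int(rng.poisson(lam))
        truncated = False
        if total + n_correct >= 30:
            n_correct = 30 - total
            truncated = True
        n_incorrect = int(rng.binomial(max(n_correct, 1), words.incorrect_rate))
        if truncated and n_correct + n_incorrect:
            # the finishing set is cut short; scale its dwell to the share
            # of submissions actually made (it is excluded from t_A anyway)
            dwell *= (n_correct + n_incorrect) / (1 + rng.poisson(lam) + n_incorrect)
            dwell = max(dwell, 1.0)
        n_words = n_correct + n_incorrect
        times = np.sort(rng.uniform(0.0, dwell, size=n_words)) + t
        correct_flags = np.array([True] * n_correct + [False] * n_incorrect)
        rng.shuffle(correct_flags)
        events = []
        prev_word = anchor = None
        for k in range(n_words):
            if not generate_words:
                events.append(WordEvent("", bool(correct_flags[k]), float(times[k])))
                continue
            if correct_flags[k]:
                if prev_word is not None and rng.random() < words.chain_prob:
                    src = (
                        anchor
                        if anchor is not None and rng.random() < words.anchor_persistence
                        else prev_word
                    )
                    w = _chain_word(src, ls.letters, rng)
                else:
                    w = _fresh_word(ls.letters, rng)
                if anchor is None:
                    anchor = w
                prev_word = w
            else:
                w = _fresh_word(ls.letters, rng)[:3]  # too short: invalid
            events.append(WordEvent(w, bool(correct_flags[k]), float(times[k])))
        visits.append(Visit(i, t, t + dwell, events))
        t += dwell
        total += n_correct
        if total >= 30:
            break
    return AnagramSession(phase, visits)


def simulate_delta_t(
    n: int,
    condition: str,
    priming: PrimingParams,
    rng: np.random.Generator,
    words: WordStreamParams = WordStreamParams(),
    n_lettersets: int = 14,
) -> np.ndarray:
    """Vectorized sampler of the delta-t outcome for ``n`` participants.

    Statistically equivalent to running :func:`simulate_anagram_session`
    for the pre and post phases and applying :func:`anagrams.delta_t`
    (log-normal dwells, 1 + Poisson correct words per set, stop at 30,
    finishing set excluded), but drawn as whole matrices so that
    calibration studies with thousands of replicates stay cheap.
    """
    lam = max(words.words_per_set_mean - 1.0, 0.0)

    def phase_mean(mu: float) -> np.ndarray:
        dwell = rng.lognormal(mu, priming.log_dwell_sd, size=(n, n_lettersets))
        counts = 1 + rng.poisson(lam, size=(n, n_lettersets))
        cum = counts.cumsum(axis=1)
        reached = cum >= 30
        fin = np.where(reached.any(axis=1), reached.argmax(axis=1), n_lettersets)
        cols = np.arange(n_lettersets)
        visited = cols[None, :] <= np.minimum(fin, n_lettersets - 1)[:, None]
        keep = visited & (cols[None, :] != fin[:, None])
        with np.errstate(invalid="ignore"):  # 0 remaining sets -> NaN (missing)
            return (dwell * keep).sum(axis=1) / keep.sum(axis=1)

    mu_pre = priming.log_dwell_mean
    mu_post = mu_pre + math.log(priming.practice_effect)
    if condition == "clustered":
        mu_post += priming.delta
    return phase_mean(mu_post) - phase_mean(mu_pre)


@dataclass
class StudyTables:
    """The three CSV-shaped tables consumed by the analysis pipeline."""

    participants: pd.DataFrame
    clicks: pd.DataFrame
    anagram: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(out / "participants.csv", index=False)
        self.clicks.to_csv(out / "clicks.csv", index=False)
        self.anagram.to_csv(out / "anagram.csv", index=False)


def _assign_conditions(cfg: StudyConfig, rng: np.random.Generator) -> list[str]:
    n = cfg.n_per_condition
    if cfg.balanced_assignment:
        conds = ["clustered"] * n + ["dispersed"] * n
        rng.shuffle(conds)
        return conds
    return ["clustered" if rng.random() < 0.5 else "dispersed" for _ in range(2 * n)]


def simulate_study(cfg: StudyConfig) -> StudyTables:
    """Simulate the whole experiment and return the three event tables.

    Deterministic for a fixed ``cfg.seed``: rerunning yields byte-identical
    CSVs.  Shared stimuli (landscape pools, the 28 letter-sets) are drawn
    once; each participant then gets 5 landscapes without replacement from
    their condition's pool, a grid-agent run per landscape, and pre/post
    anagram sessions with the configured nuisance behaviours.
    """
    rng = np.random.default_rng(cfg.seed)
    pools = {
        c: landscape_pool(
            c, cfg.pool_size, rng,
            clustered_params=cfg.clustered_params,
            dispersed_params=cfg.dispersed_params,
        )
        for c in CONDITIONS
    }
    lettersets = generate_lettersets(2 * cfg.n_lettersets, rng)
    pre_sets, post_sets = lettersets[: cfg.n_lettersets], lettersets[cfg.n_lettersets :]
    conditions = _assign_conditions(cfg, rng)

    part_rows, click_rows, anagram_rows = [], [], []
    for pid_num, cond in enumerate(conditions, start=1):
        pid = f"P{pid_num:04d}"
        low_words = rng.random() < cfg.p_low_words
        comp_fail = rng.random() < cfg.p_comprehension_fail
        inactive = rng.random() < cfg.p_inactivity
        incomplete = rng.random() < cfg.p_incomplete

        sessions = {}
        for phase, sets in (("pre", pre_sets), ("post", post_sets)):
            s = simulate_anagram_session(
                phase, cond, cfg.priming, rng,
                lettersets=sets, words=cfg.words[cond],
                n_lettersets=cfg.n_lettersets, low_word_count=low_words,
            )
            sessions[phase] = s
            for v in s.visits:
                anagram_rows.append(
                    dict(participant_id=pid, phase=phase, letterset_index=v.letterset_index,
                         event="enter", word="", correct="", time_s=round(v.enter_time, 3))
                )
                for w in v.words:
                    anagram_rows.append(
                        dict(participant_id=pid, phase=phase, letterset_index=v.letterset_index,
                             event="submit", word=w.word, correct=w.correct,
                             time_s=round(w.time, 3))
                    )
                anagram_rows.append(
                    dict(participant_id=pid, phase=phase, letterset_index=v.letterset_index,
                         event="exit", word="", correct="", time_s=round(v.exit_time, 3))
                )

        grid_ids = rng.choice(cfg.pool_size, size=cfg.n_grids, replace=False)
        total_points = 0
        for g, li in enumerate(grid_ids, start=1):
            seq = simulate_grid_search(
                pools[cond][li], cfg.agents[cond], rng, n_clicks=cfg.clicks_per_grid,
                landscape_id=f"{cond}-{li:02d}",
            )
            total_points += int(seq.payoffs.sum())
            for t, (r, c, p) in enumerate(zip(seq.rows, seq.cols, seq.payoffs), start=1):
                click_rows.append(
                    dict(participant_id=pid, condition=cond, grid_index=g,
                         trial=t, row=int(r), col=int(c), payoff=int(p))
                )

        # grid-task duration: log-normal minutes, clustered arm faster
        grid_minutes = float(
            rng.lognormal(math.log(5.5 if cond == "clustered" else 7.0), 0.35)
        )
        # nuisance flags map onto the exclusion criteria inputs
        inact_target = int(rng.integers(3)) if inactive else -1  # 0: post-anagram, 1: grid, 2: long freeze
        part_rows.append(
            dict(
                participant_id=pid,
                condition=cond,
                comprehension_fails_anagram=3 if (comp_fail and rng.random() < 0.5) else int(rng.integers(0, 2)),
                comprehension_fails_grid=3 if comp_fail else 0,
                inactivity_warnings_post_anagram=2 if inact_target == 0 else 0,
                inactivity_warnings_grid=2 if inact_target == 1 else 0,
                max_inactivity_during_warning=float(rng.uniform(100, 200)) if inact_target == 2 else 0.0,
                post_instruction_time=float(rng.uniform(15, 60)),
                words_pre=sessions["pre"].total_correct,
                words_post=sessions["post"].total_correct,
                grid_time_s=round(grid_minutes * 60.0, 1),
                total_points=total_points,
                completed=not incomplete,
            )
        )

    return StudyTables(
        pd.DataFrame(part_rows),
        pd.DataFrame(click_rows),
        pd.DataFrame(anagram_rows),
    )
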