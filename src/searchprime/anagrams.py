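"""Letter-set construction and cognitive-search statistics for the anagram task.

Participants see up to 14 six-letter sets per phase (4 consonants + 2
vowels, drawn from the 20 most common English letters) and form words of at
least 4 letters until they have 30 correct words.  The study's outcome is
the change in mean dwell time per letter-set from pre-test to post-test
(delta-t = t_A2 - t_A1), excluding the final set in which the 30th word was
found.  Within-set search style is measured by the bigram similarity of
consecutively submitted words, counting shared adjacent-letter tokens
including start- and end-markers.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

VOWELS = "AEIOU"
#: The 20 most common letters (K, V, X, Z, J, Q excluded) minus the vowels.
CONSONANTS = "BCDFGHLMNPRSTWY"
EXCLUDED = "KVXZJQ"

WORDS_TO_FINISH = 30
MIN_WORD_LEN = 4


@dataclass(frozen=True)
class LetterSet:
    """A six-letter anagram stimulus: 4 consonants and 2 vowels, uppercase."""

    letters: str

    def __post_init__(self) -> None:
        s = self.letters
        if len(s) != 6 or not s.isalpha() or s != s.upper():
            raise ValueError(f"letter-set must be 6 uppercase letters, got {s!r}")
        if any(ch in EXCLUDED for ch in s):
            raise ValueError(f"letter-set {s!r} uses an excluded letter")
        n_vowels = sum(ch in VOWELS for ch in s)
        if n_vowels != 2:
            raise ValueError(f"letter-set {s!r} must have exactly 2 vowels, has {n_vowels}")


def generate_letterset(rng: np.random.Generator) -> LetterSet:
    """Draw 4 consonants and 2 vowels uniformly without replacement within
    class, then shuffle the six letters."""
    cons = rng.choice(list(CONSONANTS), size=4, replace=False)
    vows = rng.choice(list(VOWELS), size=2, replace=False)
    letters = np.concatenate([cons, vows])
    rng.shuffle(letters)
    return LetterSet("".join(letters))


def generate_lettersets(n: int, rng: np.random.Generator) -> list[LetterSet]:
    return [generate_letterset(rng) for _ in range(n)]


def read_lettersets(path) -> list[LetterSet]:
    """Plain-text list, one 6-letter set per line (whitespace between
    letters allowed); by study convention line 1 is the practice set, the
    next 14 the pre-test and the last 14 the post-test sets."""
    sets = []
    for line in open(path):
        line = "".join(line.split()).upper()
        if line:
            sets.append(LetterSet(line))
    return sets


@dataclass
class WordEvent:
    word: str
    correct: bool
    time: float  # seconds from session origin


@dataclass
class Visit:
    """One letter-set dwell: entry/exit times and the words submitted there."""

    letterset_index: int
    enter_time: float
    exit_time: float
    words: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.exit_time < self.enter_time:
            raise ValueError("exit_time before enter_time")

    @property
    def dwell(self) -> float:
        return self.exit_time - self.enter_time

    @property
    def n_correct(self) -> int:
        return sum(w.correct for w in self.words)


@dataclass
class AnagramSession:
    phase: str  # "pre" | "post"
    visits: list = field(default_factory=list)

    @property
    def total_correct(self) -> int:
        return sum(v.n_correct for v in self.visits)

    @property
    def dwells(self) -> np.ndarray:
        return np.array([v.dwell for v in self.visits], dtype=float)


def _finishing_visit(session: AnagramSession) -> int | None:
    """Index of the visit in which the 30th correct word was found, if any."""
    running = 0
    for i, v in enumerate(session.visits):
        running += v.n_correct
        if running >= WORDS_TO_FINISH:
            return i
    return None


def mean_letterset_time(session: AnagramSession) -> float:
    """Mean dwell (s) per visited letter-set, excluding the set in which the
    30th correct word was found (a set cut short by task completion); no
    exclusion if 30 words were never reached.  NaN when no sets remain."""
    dwells = list(session.dwells)
    fin = _finishing_visit(session)
    if fin is not None:
        dwells.pop(fin)
    if not dwells:
        return math.nan
    return float(np.mean(dwells))


def delta_t(pre: AnagramSession, post: AnagramSession) -> float:
    """Post-test minus pre-test mean letter-set time; negative values mean
    faster post-test search.  NaN propagates from either phase."""
    return mean_letterset_time(post) - mean_letterset_time(pre)


def bigrams(word: str) -> list[str]:
    """Decompose a word into adjacent-letter tokens plus start/end markers.

    A word of length L yields L+1 tokens; e.g. "tale" -> ^t, ta, al, le, e$
    (^ marks the start, $ the end).  Case-insensitive; duplicates retained.
    """
    if not word:
        raise ValueError("empty word has no bigrams")
    w = word.lower()
    return [f"^{w[0]}"] + [w[i : i + 2] for i in range(len(w) - 1)] + [f"{w[-1]}$"]


def bigram_similarity(w1: str, w2: str) -> int:
    """Number of bigrams shared between two words: the size of the multiset
    intersection of their token lists (symmetric)."""
    shared = Counter(bigrams(w1)) & Counter(bigrams(w2))
    return sum(shared.values())


def session_bigram_similarity(session: AnagramSession, across_sets: bool = False) -> float:
    """Mean bigram similarity over consecutive pairs of correct words.

    Pairs are formed within a letter-set visit; letter-set boundaries break
    the chain unless ``across_sets`` is set (sensitivity analysis).  NaN when
    no eligible pair exists.
    """
    sims: list[int] = []
    carry: str | None = None
    for v in session.visits:
        prev = carry if across_sets else None
        for w in v.words:
            if not w.correct:
                continue
            if prev is not None:
                sims.append(bigram_similarity(prev, w.word))
            prev = w.word
        carry = prev
    if not sims:
        return math.nan
    return float(np.mean(sims))
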