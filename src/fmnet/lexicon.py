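"""Population valence lexicon: pooled ratings and trichotomous word attributes.

Each word's ratings (1-5 Likert, blanks counted as the neutral score 3) are
pooled across participants.  A word is labelled *negative* when its ratings
have a significantly lower median than the union of all other words'
ratings, and *positive* when significantly higher, according to a two-group
Kruskal-Wallis test at significance level ``alpha`` (default 0.1); all
remaining words are *neutral*.  No multiplicity correction is applied
across words by default (a Benjamini-Hochberg switch is provided).

The pooled score distribution is summarised by the Pearson skewness
coefficient 3*(mean - median)/sigma, with sigma the population standard
deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, StatisticalError
from .io import RATING_MAX, RATING_MIN, RatingForm

ATTRIBUTES = ("positive", "neutral", "negative")

#: a blank rating expresses neutrality and contributes this score
NEUTRAL_RATING = 3

DEFAULT_ALPHA = 0.1


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single two-group Kruskal-Wallis comparison."""

    statistic: float
    p_value: float
    n: int
    alpha: float
    decision: str


@dataclass(frozen=True)
class WordValence:
    word: str
    n_raters: int
    mean: float
    median: float
    attribute: str
    statistic: float
    p_value: float
    unrated: bool = False
    ratings: tuple[int, ...] = ()


@dataclass
class SkewReport:
    mean: float
    median: float
    sd: float
    pearson_skewness: float
    n: int


@dataclass
class ValenceLexicon:
    """Per-word pooled ratings, summary statistics and valence attributes.

    Words that never received a rating are absent; :meth:`attribute`
    returns ``"neutral"`` for them (they are flagged ``unrated`` when a
    network copies attributes onto its nodes).
    """

    words: dict[str, WordValence] = field(default_factory=dict)
    alpha: float = DEFAULT_ALPHA

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def __getitem__(self, word: str) -> WordValence:
        return self.words[word]

    def __iter__(self):
        return iter(self.words)

    def attribute(self, word: str) -> str:
        entry = self.words.get(word)
        return entry.attribute if entry is not None else "neutral"

    def mean_valence(self, word: str) -> float:
        return self.words[word].mean

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "word": wv.word,
                "n_raters": wv.n_raters,
                "mean": wv.mean,
                "median": wv.median,
                "attribute": wv.attribute,
                "kw_statistic": wv.statistic,
                "p_value": wv.p_value,
                "unrated": wv.unrated,
            }
            for wv in self.words.values()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        frame = self.to_frame()
        # shortest round-trip float representation, so re-importing the CSV
        # reproduces every statistic bit-exactly
        for col in ("mean", "median", "kw_statistic", "p_value"):
            frame[col] = frame[col].map(repr)
        frame.to_csv(path, index=False, encoding="utf-8")
        return path

    @classmethod
    def from_csv(cls, path: str | Path, alpha: float = DEFAULT_ALPHA) -> "ValenceLexicon":
        frame = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
        words = {}
        for _, row in frame.iterrows():
            wv = WordValence(
                word=str(row["word"]),
                n_raters=int(row["n_raters"]),
                mean=float(row["mean"]),
                median=float(row["median"]),
                attribute=str(row["attribute"]),
                statistic=float(row["kw_statistic"]),
                p_value=float(row["p_value"]),
                unrated=bool(row["unrated"]),
            )
            words[wv.word] = wv
        return cls(words=words, alpha=alpha)


# ---------------------------------------------------------------------------
# pooling and distribution diagnostics
# ---------------------------------------------------------------------------


def pool_ratings(rating_forms: Sequence[RatingForm]) -> dict[str, list[int]]:
    """Pool ratings per word across participants; blanks contribute a 3.

    Each (participant, word) pair contributes exactly one value; a duplicate
    is an input error, never averaged.
    """
    pooled: dict[str, list[int]] = {}
    seen: set[tuple[str, str]] = set()
    for form in rating_forms:
        for word, rating in form.ratings:
            key = (form.participant_id, word)
            if key in seen:
                raise InputError(
                    f"participant {form.participant_id!r} rated {word!r} twice"
                )
            seen.add(key)
            pooled.setdefault(word, []).append(
                NEUTRAL_RATING if rating is None else rating
            )
    return pooled


def pearson_skewness(scores: Iterable[float], ddof: int = 0) -> float:
    """Pearson skewness 3*(mean - median)/sigma of a score distribution.

    ``ddof=0`` (population standard deviation) by default; a zero standard
    deviation is signalled as degenerate.
    """
    values = np.asarray(list(scores), dtype=float)
    if values.size < 2:
        raise StatisticalError("pearson_skewness needs at least 2 scores")
    sd = float(values.std(ddof=ddof))
    if sd == 0.0:
        raise StatisticalError("pearson_skewness undefined: zero standard deviation")
    return 3.0 * (float(values.mean()) - float(np.median(values))) / sd


# ---------------------------------------------------------------------------
# two-group Kruskal-Wallis
# ---------------------------------------------------------------------------

_EXACT_MIN_GROUP = 5
_EXACT_MAX_TABLES = 200_000


def _exact_kw_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact permutation p-value for the two-group KW statistic.

    For two groups the (tie-corrected) statistic is a monotone function of
    the absolute deviation of one group's rank sum from its expectation, so
    permutations are compared on that deviation directly.
    """
    pooled = np.concatenate([a, b])
    n = pooled.size
    n1 = a.size
    ranks = sps.rankdata(pooled)
    expected = n1 * (n + 1) / 2.0
    observed_dev = abs(float(ranks[:n1].sum()) - expected)
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        dev = abs(float(ranks[list(idx)].sum()) - expected)
        if dev >= observed_dev - 1e-9:
            count += 1
        total += 1
    return count / total


def two_group_kruskal(
    a: Sequence[float],
    b: Sequence[float],
    exact_min_group: int = _EXACT_MIN_GROUP,
    exact_max_tables: int = _EXACT_MAX_TABLES,
) -> tuple[float, float]:
    """Tie-corrected two-group Kruskal-Wallis test.

    Returns ``(statistic, p_value)``.  The p-value uses the chi-squared
    approximation (df = 1) except when the smaller group has fewer than
    ``exact_min_group`` observations and the permutation space is small
    enough, in which case an exact permutation p-value is computed.
    Two groups with all values identical give ``(0.0, 1.0)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatisticalError("two_group_kruskal needs two non-empty groups")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    statistic, p_value = sps.kruskal(a, b)
    if min(a.size, b.size) < exact_min_group and math.comb(
        a.size + b.size, a.size
    ) <= exact_max_tables:
        p_value = _exact_kw_p(a, b)
    return float(statistic), float(p_value)


def classify_word_valence(
    word_ratings: Sequence[float],
    rest_ratings: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
) -> tuple[str, TestResult]:
    """Label a word positive/neutral/negative against the rest of the lexicon.

    The word is positive (negative) when the Kruskal-Wallis p-value is below
    ``alpha`` *and* its median rating is above (below) the median of the
    pooled remaining ratings; otherwise it is neutral.
    """
    word_ratings = np.asarray(word_ratings, dtype=float)
    rest_ratings = np.asarray(rest_ratings, dtype=float)
    if word_ratings.size == 0 or rest_ratings.size == 0:
        raise StatisticalError("classification needs two non-empty rating groups")
    statistic, p_value = two_group_kruskal(word_ratings, rest_ratings)
    attribute = "neutral"
    if p_value < alpha:
        med_word = float(np.median(word_ratings))
        med_rest = float(np.median(rest_ratings))
        if med_word < med_rest:
            attribute = "negative"
        elif med_word > med_rest:
            attribute = "positive"
    result = TestResult(
        statistic=statistic,
        p_value=p_value,
        n=int(word_ratings.size + rest_ratings.size),
        alpha=alpha,
        decision=attribute,
    )
    return attribute, result


def build_lexicon(
    rating_forms: Sequence[RatingForm],
    alpha: float = DEFAULT_ALPHA,
    fdr: bool = False,
) -> tuple[ValenceLexicon, SkewReport]:
    """Classify every rated word against the union of all other ratings.

    Each word i is tested against the pooled ratings of all words j != i,
    with no multiplicity correction by default (``fdr=True`` switches to a
    Benjamini-Hochberg adjusted decision at level ``alpha``).  The skewness
    report is computed on the full pooled distribution; a degenerate pooled
    distribution (zero variance, e.g. every rating a 3) reports skewness 0.
    """
    pooled = pool_ratings(rating_forms)
    if len(pooled) < 2:
        raise InputError(
            f"lexicon needs >= 2 distinct rated words, got {len(pooled)}"
        )
    values = np.arange(RATING_MIN, RATING_MAX + 1)
    counts = {
        word: np.bincount(ratings, minlength=RATING_MAX + 1)[RATING_MIN:]
        for word, ratings in pooled.items()
    }
    total_counts = np.sum(list(counts.values()), axis=0)

    entries: dict[str, WordValence] = {}
    p_values: dict[str, float] = {}
    for word, ratings in pooled.items():
        rest_counts = total_counts - counts[word]
        rest = np.repeat(values, rest_counts)
        attribute, result = classify_word_valence(ratings, rest, alpha=alpha)
        arr = np.asarray(ratings, dtype=float)
        entries[word] = WordValence(
            word=word,
            n_raters=len(ratings),
            mean=float(arr.mean()),
            median=float(np.median(arr)),
            attribute=attribute,
            statistic=result.statistic,
            p_value=result.p_value,
            ratings=tuple(ratings),
        )
        p_values[word] = result.p_value

    if fdr:
        entries = _apply_fdr(entries, p_values, alpha)

    all_scores = np.repeat(values, total_counts).astype(float)
    sd = float(all_scores.std(ddof=0))
    if sd == 0.0:
        skew = 0.0  # constant pooled ratings: mean == median, no asymmetry
    else:
        skew = pearson_skewness(all_scores)
    report = SkewReport(
        mean=float(all_scores.mean()),
        median=float(np.median(all_scores)),
        sd=sd,
        pearson_skewness=skew,
        n=int(all_scores.size),
    )
    return ValenceLexicon(words=entries, alpha=alpha), report


def _apply_fdr(entries, p_values, alpha):
    """Benjamini-Hochberg: demote words whose adjusted p is >= alpha."""
    words = list(p_values)
    raw = np.array([p_values[w] for w in words])
    order = np.argsort(raw)
    m = len(words)
    adjusted = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, raw[i] * m / (rank_idx + 1))
        adjusted[i] = running
    out = {}
    for w, adj in zip(words, adjusted):
        wv = entries[w]
        attribute = wv.attribute if adj < alpha else "neutral"
        out[w] = WordValence(
            word=wv.word,
            n_raters=wv.n_raters,
            mean=wv.mean,
            median=wv.median,
            attribute=attribute,
            statistic=wv.statistic,
            p_value=wv.p_value,
            ratings=wv.ratings,
        )
    return out


# ---------------------------------------------------------------------------
# cross-validation against external norms
# ---------------------------------------------------------------------------


def cross_validate(lexicon: ValenceLexicon, norms) -> tuple[float, float, int]:
    """Kendall tau-b between lexicon mean valence and external norm valence.

    Computed over the overlapping vocabulary; returns (tau, p, n_overlap).
    """
    overlap = sorted(set(lexicon.words) & set(norms.valence))
    if len(overlap) < 2:
        raise StatisticalError(
            f"cross-validation needs >= 2 overlapping words, got {len(overlap)}"
        )
    ours = [lexicon.words[w].mean for w in overlap]
    theirs = [norms.valence[w] for w in overlap]
    result = sps.kendalltau(ours, theirs, variant="b", method="asymptotic")
    return float(result.statistic), float(result.pvalue), len(overlap)
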