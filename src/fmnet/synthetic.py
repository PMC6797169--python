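"""Synthetic forma mentis surveys with known ground truth.

The generator emulates the two survey tasks at desk scale: a vocabulary is
split into planted positive / neutral / negative pools; every participant
(i) rates every vocabulary word by drawing from their pool's rating
distribution over 1-5 (blanks inserted at a participant-specific rate) and
(ii) answers a continuous free-association survey -- ``n_cues`` cue words
(a fixed subset shared by all participants plus a per-participant random
sample, order scrambled), three responses per cue.

Responses follow a mixture controlled by the homophily parameter ``h``:
with probability ``h`` the response is drawn from the cue's own valence
pool (excluding the cue itself), otherwise from the whole vocabulary
(excluding the cue).  Within either candidate set, words are drawn with
Zipf-weighted probabilities (a seeded random rank assignment with weight
rank^-s), reproducing the heavy-tailed response frequencies of real free
association data; uniform sampling at desk-scale vocabularies would
saturate nearly every possible word pair and leave no residual randomness
for degree-preserving null models.

Everything is deterministic under the config seed, and the generator
emits the same file formats the :mod:`fmnet.io` parsers read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .io import (
    BLANK,
    ExternalNormTable,
    RatingForm,
    ResponseForm,
    discard_incomplete_forms,
    drop_warmup,
    normalize_tokens,
    write_association_forms,
    write_norms,
    write_rating_forms,
)
from .lexicon import build_lexicon
from .network import build_network
from .stats import configuration_null_ensemble, edge_endpoint_tau

POOLS = ("positive", "neutral", "negative")

#: rating distributions over scores 1..5 per planted pool.  Chosen to give
#: clearly separated pools at ~30 raters while keeping classification
#: nontrivial at ~10.
DEFAULT_RATING_DISTS: dict[str, tuple[float, ...]] = {
    "positive": (0.0, 0.0, 0.1, 0.4, 0.5),
    "neutral": (0.05, 0.2, 0.5, 0.2, 0.05),
    "negative": (0.5, 0.4, 0.1, 0.0, 0.0),
}

#: degenerate distributions: positive words always rated 5, neutral 3, negative 1
NOISELESS_RATING_DISTS: dict[str, tuple[float, ...]] = {
    "positive": (0.0, 0.0, 0.0, 0.0, 1.0),
    "neutral": (0.0, 0.0, 1.0, 0.0, 0.0),
    "negative": (1.0, 0.0, 0.0, 0.0, 0.0),
}

#: a tighter neutral distribution; combined with a positively imbalanced
#: vocabulary (e.g. pools 190/160/50) the pooled ratings keep median 3 while
#: the mean rises, driving the Pearson skewness above 1 as in strongly
#: Pollyanna-skewed rating data.
SKEWED_RATING_DISTS: dict[str, tuple[float, ...]] = {
    "positive": (0.0, 0.0, 0.1, 0.4, 0.5),
    "neutral": (0.0, 0.1, 0.8, 0.1, 0.0),
    "negative": (0.5, 0.4, 0.1, 0.0, 0.0),
}


@dataclass(frozen=True)
class SurveyConfig:
    """Study-design parameters of a synthetic forma mentis survey.

    Defaults mirror the survey design this package targets: 159
    participants, 50 cues each (10 fixed across participants), three
    responses per cue, 1-5 Likert ratings with blank = neutral, and a
    response vocabulary an order of magnitude larger than a single
    participant's survey.  The default vocabulary is positively
    imbalanced (more positive than negative words), which gives the
    pooled ratings the positive Pearson skewness characteristic of
    real valence-rating data.
    """

    n_participants: int = 159
    n_cues: int = 50
    n_fixed_cues: int = 10
    pool_sizes: tuple[int, int, int] = (170, 170, 60)
    responses_per_cue: int = 3
    homophily: float = 0.4
    rating_dists: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_RATING_DISTS)
    )
    blank_prob: float = 0.05
    heterogeneous_blanks: bool = True
    zipf_exponent: float = 1.0
    seed: int = 0

    @property
    def vocab_size(self) -> int:
        return sum(self.pool_sizes)

    def validate(self) -> None:
        if self.n_participants < 1:
            raise InputError("n_participants must be >= 1")
        if len(self.pool_sizes) != 3 or any(s < 0 for s in self.pool_sizes):
            raise InputError("pool_sizes must be three non-negative integers")
        if self.vocab_size < 2:
            raise InputError("vocabulary must hold at least 2 words")
        if not 0 <= self.n_fixed_cues <= self.n_cues:
            raise InputError("need 0 <= n_fixed_cues <= n_cues")
        if self.n_cues > self.vocab_size:
            raise InputError(
                f"n_cues={self.n_cues} exceeds vocabulary size {self.vocab_size}"
            )
        if not 0.0 <= self.homophily <= 1.0:
            raise InputError("homophily must be in [0, 1]")
        if not 0.0 <= self.blank_prob <= 1.0:
            raise InputError("blank_prob must be in [0, 1]")
        if self.responses_per_cue < 1:
            raise InputError("responses_per_cue must be >= 1")
        for pool in POOLS:
            dist = np.asarray(self.rating_dists[pool], dtype=float)
            if dist.size != 5 or np.any(dist < 0) or abs(dist.sum() - 1.0) > 1e-9:
                raise InputError(f"rating distribution for {pool!r} must sum to 1")

    def to_dict(self) -> dict:
        out = asdict(self)
        out["rating_dists"] = {k: list(v) for k, v in self.rating_dists.items()}
        out["pool_sizes"] = list(self.pool_sizes)
        return out


def compact_config(
    pool_sizes: tuple[int, int, int] = (30, 30, 30),
    n_participants: int = 100,
    homophily: float = 0.0,
    seed: int = 0,
    **overrides,
) -> SurveyConfig:
    """A small-vocabulary configuration with a proportionally shorter survey.

    At small vocabularies a full 50-cue survey saturates nearly every
    possible word pair (the real surveys draw on response vocabularies ~30x
    larger than one participant's form), so the survey length is scaled to
    keep the association graph in the sparse regime where degree-preserving
    null models are meaningful: 6 cues per participant, 2 of them fixed.
    """
    return SurveyConfig(
        n_participants=n_participants,
        n_cues=6,
        n_fixed_cues=2,
        pool_sizes=pool_sizes,
        homophily=homophily,
        seed=seed,
        **overrides,
    )


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-word attributes and expected ratings of a synthetic survey."""

    attributes: Mapping[str, str]
    planted_means: Mapping[str, float]
    pools: Mapping[str, tuple[str, ...]]
    homophily: float
    seed: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "attributes": dict(self.attributes),
            "planted_means": dict(self.planted_means),
            "pools": {k: list(v) for k, v in self.pools.items()},
            "homophily": self.homophily,
            "seed": self.seed,
        }
        path.write_text(
            json.dumps(payload, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
        )
        return path


@dataclass
class SyntheticSurvey:
    config: SurveyConfig
    truth: GroundTruth
    vocabulary: list[str]
    association_forms: list[ResponseForm]
    rating_forms: list[RatingForm]
    norms: ExternalNormTable


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_PREFIX = {"positive": "pos", "neutral": "neu", "negative": "neg"}


def _streams(config: SurveyConfig) -> list[np.random.Generator]:
    # fixed stream order: zipf ranks, ratings, associations, norms
    children = np.random.SeedSequence(config.seed).spawn(4)
    return [np.random.default_rng(c) for c in children]


def generate_vocabulary(config: SurveyConfig) -> tuple[list[str], GroundTruth]:
    """Synthetic tokens tagged by pool, plus the planted ground truth."""
    config.validate()
    vocab: list[str] = []
    pools: dict[str, tuple[str, ...]] = {}
    attributes: dict[str, str] = {}
    planted_means: dict[str, float] = {}
    values = np.arange(1, 6, dtype=float)
    for pool, size in zip(POOLS, config.pool_sizes):
        dist = np.asarray(config.rating_dists[pool], dtype=float)
        expected = float(values @ dist)
        words = tuple(f"{_PREFIX[pool]}{i:03d}" for i in range(1, size + 1))
        pools[pool] = words
        vocab.extend(words)
        for w in words:
            attributes[w] = pool
            planted_means[w] = expected
    truth = GroundTruth(
        attributes=attributes,
        planted_means=planted_means,
        pools=pools,
        homophily=config.homophily,
        seed=config.seed,
    )
    return vocab, truth


def _fixed_cues(config: SurveyConfig, vocab: list[str], truth: GroundTruth) -> list[str]:
    """Fixed cues shared by all participants, drawn round-robin across pools."""
    pools = [list(truth.pools[p]) for p in POOLS if truth.pools[p]]
    fixed: list[str] = []
    i = 0
    while len(fixed) < config.n_fixed_cues:
        pool = pools[i % len(pools)]
        idx = i // len(pools)
        if idx < len(pool):
            fixed.append(pool[idx])
        i += 1
        if i > 10 * config.n_fixed_cues * max(1, len(pools)):  # pragma: no cover
            raise InputError("cannot draw the requested number of fixed cues")
    return fixed


def fixed_cue_words(config: SurveyConfig, truth: GroundTruth) -> list[str]:
    """The cue words shown to every participant (round-robin across pools)."""
    vocab = [w for pool in POOLS for w in truth.pools[pool]]
    return _fixed_cues(config, vocab, truth)


def _blank_rate(config: SurveyConfig, rng: np.random.Generator) -> float:
    """Participant-level blank rate: Beta-distributed around blank_prob.

    The heterogeneity puts a small tail of careless participants beyond the
    25% rejection threshold, mirroring the few-percent form rejection rates
    of supervised in-lab data collection.
    """
    p = config.blank_prob
    if p <= 0.0:
        return 0.0
    if p >= 1.0 or not config.heterogeneous_blanks:
        return p
    return float(rng.beta(1.0, (1.0 - p) / p))


def generate_rating_forms(
    config: SurveyConfig, truth: GroundTruth
) -> list[RatingForm]:
    """Every participant rates every vocabulary word from their pool's law."""
    config.validate()
    vocab = [w for pool in POOLS for w in truth.pools[pool]]
    rng = _streams(config)[1]
    cdfs = {
        pool: np.cumsum(np.asarray(config.rating_dists[pool], dtype=float))
        for pool in POOLS
    }
    pool_of = np.array([POOLS.index(truth.attributes[w]) for w in vocab])
    pool_cdf = np.stack([cdfs[p] for p in POOLS])  # (3, 5)
    forms = []
    n = len(vocab)
    for i in range(config.n_participants):
        p_blank = _blank_rate(config, rng)
        order = rng.permutation(n)
        u = rng.random(n)
        blanks = rng.random(n) < p_blank
        ratings = []
        for j in order:
            if blanks[j]:
                ratings.append((vocab[j], None))
            else:
                score = 1 + int(np.searchsorted(pool_cdf[pool_of[j]], u[j]))
                ratings.append((vocab[j], min(score, 5)))
        forms.append(
            RatingForm(f"p{i:03d}", tuple(ratings), source="synthetic")
        )
    return forms


def generate_association_forms(
    config: SurveyConfig, truth: GroundTruth
) -> list[ResponseForm]:
    """Continuous free-association forms under the homophily mixture model."""
    config.validate()
    vocab = [w for pool in POOLS for w in truth.pools[pool]]
    n = len(vocab)
    index = {w: k for k, w in enumerate(vocab)}
    rng_zipf, _, rng, _ = _streams(config)

    ranks = rng_zipf.permutation(n)  # random frequency rank per word
    weights = (ranks + 1.0) ** (-config.zipf_exponent)

    # per-cue sampling tables (cue excluded from its own candidate set)
    global_cdfs = np.empty((n, n))
    for c in range(n):
        w = weights.copy()
        w[c] = 0.0
        global_cdfs[c] = np.cumsum(w / w.sum())
    pool_members = {
        pool: np.array([index[w] for w in truth.pools[pool]], dtype=int)
        for pool in POOLS
    }
    pool_cdfs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for c in range(n):
        members = pool_members[truth.attributes[vocab[c]]]
        others = members[members != c]
        if others.size == 0:
            continue  # degenerate pool: fall back to the global law
        w = weights[others]
        pool_cdfs[c] = (others, np.cumsum(w / w.sum()))

    fixed = [index[w] for w in _fixed_cues(config, vocab, truth)]
    non_fixed = np.array([k for k in range(n) if k not in set(fixed)], dtype=int)
    k_resp = config.responses_per_cue
    forms = []
    for i in range(config.n_participants):
        p_blank = _blank_rate(config, rng)
        sampled = rng.choice(non_fixed, size=config.n_cues - config.n_fixed_cues, replace=False)
        cues = np.concatenate([np.array(fixed, dtype=int), sampled])
        rng.shuffle(cues)
        entries = []
        for c in cues:
            within = rng.random(k_resp) < config.homophily
            u = rng.random(k_resp)
            blanks = rng.random(k_resp) < p_blank
            responses = []
            for t in range(k_resp):
                if blanks[t]:
                    responses.append(BLANK)
                    continue
                if within[t] and c in pool_cdfs:
                    members, cdf = pool_cdfs[c]
                    j = int(members[np.searchsorted(cdf, u[t])])
                else:
                    j = int(np.searchsorted(global_cdfs[c], u[t]))
                responses.append(vocab[j])
            entries.append((vocab[c], tuple(responses)))
        forms.append(ResponseForm(f"p{i:03d}", tuple(entries), source="synthetic"))
    return forms


def generate_norms(
    config: SurveyConfig, truth: GroundTruth, noise_sd: float = 0.3
) -> ExternalNormTable:
    """A pseudo external norm table: planted means plus rater noise.

    Valence is the planted mean rating with Gaussian noise, clipped to
    [1, 5].  Arousal follows the classic U-shaped valence-arousal pattern
    (affectively extreme words are more arousing than neutral ones).
    """
    rng = _streams(config)[3]
    valence: dict[str, float] = {}
    arousal: dict[str, float] = {}
    for word, mean in truth.planted_means.items():
        v = float(np.clip(mean + rng.normal(0.0, noise_sd), 1.0, 5.0))
        a = float(
            np.clip(1.5 + abs(mean - 3.0) + rng.normal(0.0, noise_sd), 1.0, 5.0)
        )
        valence[word] = v
        arousal[word] = a
    return ExternalNormTable(valence=valence, arousal=arousal, source="synthetic")


def generate_survey(config: SurveyConfig) -> SyntheticSurvey:
    """Generate vocabulary, both survey tasks and the pseudo-norm table."""
    vocab, truth = generate_vocabulary(config)
    return SyntheticSurvey(
        config=config,
        truth=truth,
        vocabulary=vocab,
        association_forms=generate_association_forms(config, truth),
        rating_forms=generate_rating_forms(config, truth),
        norms=generate_norms(config, truth),
    )


def write_survey(survey: SyntheticSurvey, outdir: str | Path) -> dict[str, Path]:
    """Write the survey in the exact formats the io parsers read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": write_association_forms(
            survey.association_forms, outdir / "associations.tsv"
        ),
        "ratings": write_rating_forms(survey.rating_forms, outdir / "ratings.tsv"),
        "norms": write_norms(survey.norms, outdir / "norms.csv"),
        "ground_truth": survey.truth.to_json(outdir / "ground_truth.json"),
    }
    config_path = outdir / "config.json"
    config_path.write_text(
        json.dumps(survey.config.to_dict(), indent=2) + "\n", encoding="utf-8"
    )
    paths["config"] = config_path
    return paths


# ---------------------------------------------------------------------------
# end-to-end analysis and parameter recovery
# ---------------------------------------------------------------------------


def analyse_config(
    config: SurveyConfig,
    warmup_k: int = 3,
    max_blank_frac: float = 0.25,
    alpha: float = 0.1,
    include_null: bool = False,
    n_realisations: int = 50,
    null_seed: int | None = None,
) -> dict:
    """Generate a survey, run the full cleaning/lexicon/network pipeline.

    Returns a flat dict of the quantities used in recovery experiments:
    label accuracy against the planted pools, the observed edge-endpoint
    tau, and (optionally) its configuration-null summary.
    """
    survey = generate_survey(config)
    assoc = normalize_tokens(survey.association_forms)
    assoc = drop_warmup(assoc, warmup_k)
    assoc, rejected_assoc = discard_incomplete_forms(assoc, max_blank_frac)
    ratings, rejected_ratings = discard_incomplete_forms(
        normalize_tokens(survey.rating_forms), max_blank_frac
    )
    lexicon, skew = build_lexicon(ratings, alpha=alpha)
    graph = build_network(assoc, lexicon, population="synthetic")
    tau, p = edge_endpoint_tau(graph)
    rated = [w for w in survey.vocabulary if w in lexicon]
    accuracy = float(
        np.mean([lexicon.attribute(w) == survey.truth.attributes[w] for w in rated])
    )
    out = {
        "h": config.homophily,
        "seed": config.seed,
        "n_participants": config.n_participants,
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_rejected_association_forms": len(rejected_assoc),
        "n_rejected_rating_forms": len(rejected_ratings),
        "pooled_skewness": skew.pearson_skewness,
        "label_accuracy": accuracy,
        "tau": tau,
        "tau_p": p,
    }
    if include_null:
        ensemble = configuration_null_ensemble(
            graph,
            statistic="edge_endpoint_tau",
            n_realisations=n_realisations,
            seed=config.seed if null_seed is None else null_seed,
        )
        null = np.asarray(ensemble.null_taus)
        out.update(
            {
                "null_mean": ensemble.null_mean,
                "null_p_mean": ensemble.null_p_mean,
                "percentile": ensemble.percentile_of_observed,
                "null_max": float(null.max()),
                "null_min": float(null.min()),
                "null_q025": float(np.quantile(null, 0.025)),
                "null_q975": float(np.quantile(null, 0.975)),
            }
        )
    return out


def _cell_seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(s % (2**31)) for s in ss.generate_state(n, dtype=np.uint64)]


def recovery_experiment(
    h_values: Sequence[float] = (0.0, 0.4, 0.8),
    n_seeds: int = 10,
    base: SurveyConfig | None = None,
    include_null: bool = False,
    n_realisations: int = 50,
) -> pd.DataFrame:
    """Planted-parameter recovery across a homophily grid.

    For every (h, seed) cell the full pipeline runs end to end on a fresh
    synthetic survey; the report records planted-label recovery and the
    observed mixing statistic (with its null summary when requested).
    Deterministic: the same inputs always yield the same report.
    """
    base = base if base is not None else compact_config()
    seeds = _cell_seeds(base.seed, len(h_values) * n_seeds)
    rows = []
    k = 0
    for h in h_values:
        for _ in range(n_seeds):
            config = replace(base, homophily=h, seed=seeds[k])
            k += 1
            rows.append(
                analyse_config(
                    config, include_null=include_null, n_realisations=n_realisations
                )
            )
    return pd.DataFrame(rows)
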