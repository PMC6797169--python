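# Methods

This note documents the statistical procedures implemented by `fmnet`, the
assumptions behind them, the synthetic data model used for validation, and
the numerical choices made where the design was genuinely open.

## Survey data model and cleaning

A forma mentis survey yields, per participant, an association form (ordered
cues, up to three responses each, blanks allowed) and a rating form (1–5
Likert valence per word, blank allowed). Cleaning applies three rules in a
fixed order:

1. **Normalization.** All tokens are lowercased, then passed through an
   optional user map (variant → canonical), e.g. `muscles → muscle`,
   `da dove → dove`. The map must be idempotent (canonical forms map to
   themselves), which makes the whole normalization idempotent. No
   automatic spell checking or lemmatization is attempted: orthographic
   repair requires language resources and human judgement, so it stays an
   explicit user input.
2. **Warm-up removal.** The first three *response cells* of each
   association form, in presentation order, are blanked: the earliest
   associates are contaminated by the task instructions. "First three in
   presentation order" equals the responses to the form's first cue;
   presentation order is recorded at read time and preserved.
3. **Blank-fraction rejection.** A form whose blank cells exceed 25% of its
   cells (3 cells per cue for association forms, one per word for rating
   forms) is discarded and logged. Running rejection *after* warm-up
   removal means warm-up-blanked cells count toward the fraction — the
   conservative reading, since the order of the two rules is otherwise
   arbitrary. Blanks are always kept as explicit blanks so the fraction
   stays computable.

Association-task and rating-task rejections are independent: a participant
rejected in one task still contributes to the other. The rejection logs
carry participant ids, so the overlap is reported by the pipeline for
anyone who prefers joint exclusion.

## Valence attributes

Ratings are pooled per word across participants; a blank contributes the
neutral score 3, and each (participant, word) pair contributes exactly one
value (a duplicate is an input error, never averaged). Word *i* is compared
against the union of all other words' ratings with a two-group
Kruskal–Wallis test (tie-corrected, χ² approximation with 1 df). The word
is labelled negative (positive) when p < α = 0.1 **and** its median is
below (above) the median of the rest; otherwise neutral. Nonparametric
testing is used because pooled Likert ratings are heavily tied and skewed.

Numerical choices:

* When the smaller group has < 5 observations and the permutation space is
  ≤ 2·10⁵ tables, the p-value is replaced by an exact permutation p
  (for two groups the tie-corrected H is monotone in the absolute rank-sum
  deviation, so the enumeration compares rank sums). Above that, the χ²
  approximation is adequate.
* Two groups whose pooled values are all identical are reported as
  (H = 0, p = 1): no evidence of difference is obtainable from constant
  data.
* No multiplicity correction is applied across words — α is a per-word
  error rate, which is the convention for descriptive lexicon labelling; a
  Benjamini–Hochberg switch (`fdr=True`) is provided for users who want
  family-wise control.
* Pearson skewness uses the population standard deviation (ddof = 0); the
  choice is configurable and irrelevant beyond O(1/n). The standalone
  operation signals σ = 0 as degenerate, but `build_lexicon` reports 0 for
  a constant pooled distribution (mean = median there, and a lexicon built
  from all-neutral ratings is legitimate input).
* Words that appear only as associates (never rated) default to neutral and
  are flagged `unrated` on the network.

## Network construction

Edges are undirected: the analyses concern neighborhoods and symmetric
mixing, and a free association from *c* to *r* is evidence of a link
between the two concepts regardless of direction. The cue-side provenance
is retained as edge metadata but ignored by every statistic. Edge weight
counts *distinct participants* producing the pair in either orientation
(repeats by the same participant count once). Self-responses are dropped.
The ≥2-participant filter removes idiosyncratic associations; filtering
composes by the maximum threshold and records its level in the metadata.

## Valence auras

The aura of a word is the valence composition of its immediate neighbors,
with each neighbor counted once (an edge-weighted variant is available but
not the default — the aura concept is about *which* concepts surround a
word, not how often). Two labelling rules are supported because the
two natural readings of "most frequent valence" differ on neutral-heavy
neighborhoods:

* **polarity** (default): negative iff #negative > #positive neighbors,
  positive iff the reverse, neutral on a tie. This matches the definition
  of a negative aura as "associated with more negative than positive
  concepts" and never lets neutral neighbors mask polarity.
* **majority**: strict three-class argmax, ties → neutral.

The aura table (fractions per word, suitable for bar-chart export) can be
computed on the filtered or unfiltered network; the choice is recorded in
the network metadata.

## Homophily statistics and the null model

Attributes are scored −m/0/+m; all statistics are rank-based, so any m > 0
gives identical values (m = 1 by default). The edge-endpoint statistic
pairs the scores of the two ends of every link, **symmetrized** (each
undirected edge contributes both orientations): this removes the arbitrary
orientation of an undirected edge from the statistic. A single-orientation
mode (random orientation per edge, seeded) exists as a sensitivity check.
The node-neighborhood statistic pairs each word's score with the unweighted
mean score of its neighbors, consistent with the aura definition. Kendall
tau-b (tie-corrected) is used throughout; p-values use the normal
approximation except for n ≤ 8, where the full permutation distribution is
enumerated. Tau-b is undefined when either paired vector is constant (its
tie-correction denominator vanishes); this is signalled, not NaN-ed.

The null model fixes each node's degree **and** valence attribute while
randomising links: every realisation applies 10·|E| accepted
degree-preserving double-edge swaps to the simple graph, rejecting
proposals that would create self-loops or multi-edges. Swapping on the
graph directly (rather than stub matching) guarantees simplicity without
whole-graph rejection sampling. Edge weights are ignored by the mixing
statistics (a weight-replicated mode is available), so rewired edges carry
weight 1. A graph too dense or constrained to mix (proposal acceptance
below ~0.5%) raises an error rather than silently under-mixing.

The ensemble reports the observed tau, the null mean, the mean of
per-realisation p-values, and the percentile of the observed value among
the null taus. The per-realisation p-values test each null network against
*its own* zero-correlation hypothesis — they are reported for completeness,
but only the percentile is a valid inferential summary of "is the observed
mixing stronger than degree + attribute composition explains".

## Aura contrasts against external norms

For a target attribute (e.g. negative words), the words whose aura matches
a condition (e.g. negative aura) are compared against *all* words of that
attribute — a subset-vs-superset contrast, deliberately mirroring the
"surrounded by the same aura vs surrounded by any aura" comparison — on an
external measure (norm valence or arousal), using the same two-group
Kruskal–Wallis machinery, with group sizes and the direction of the median
difference reported.

## Synthetic data model

The generator plants the ground truth the pipeline should recover:

* **Vocabulary** split into positive/neutral/negative pools. The default
  vocabulary (170/170/60) is positively imbalanced, reproducing the
  Pollyanna asymmetry of real lexica; with the default rating
  distributions this drives the pooled Pearson skewness to ≈ +0.9 (median
  pinned at 3 while the mean rises). A tighter neutral distribution
  (`SKEWED_RATING_DISTS`) pushes it above 1.
* **Ratings**: each participant rates every word from their pool's
  distribution over 1–5 — defaults (.5/.4/.1/0/0 mirrored for the
  poles, .05/.2/.5/.2/.05 for neutral) give clear pools at ~30 raters while
  keeping classification nontrivial at ~10. A noiseless preset (always
  5/3/1) exists for exact-recovery checks.
* **Associations**: for each response slot, with probability h the word is
  drawn from the cue's own pool (excluding the cue), otherwise from the
  whole vocabulary (excluding the cue). Within the candidate set, words are
  drawn with Zipf weights (rank⁻¹·⁰ over a seeded random rank assignment).
  The heavy tail is both empirically realistic — free-association response
  frequencies are strongly skewed — and structurally necessary at desk
  scale: real surveys put ~24k responses into a ~4.5k-word response
  vocabulary (graph density ~10⁻³), whereas uniform sampling over a
  few-hundred-word synthetic vocabulary would saturate nearly all possible
  word pairs and leave a degree-preserving null model nothing to rewire.
* **Blanks**: participant-level blank rates are Beta-distributed around the
  configured mean (default 5%), giving a small tail of careless
  participants; at the default survey length this yields form rejection
  rates of a few percent, matching supervised in-lab data collection.
* **Determinism**: all streams derive from one `SeedSequence`; the same
  config yields byte-identical files.

What the generator does **not** model: real lexical content (tokens are
synthetic), topic structure among cues, polysemy and spelling variation
(the normalization map is exercised with constructed fixtures instead), and
any dependence of a participant's associations on their own ratings beyond
the pool structure. Passing recovery tests therefore demonstrates that the
pipeline's statistics behave correctly under a controlled association
process — not that real survey data satisfies the planted-pool model.

### Scaled-down experiment design

Calibration and power experiments run at a 90-word vocabulary
(pools 30/30/30, 100 participants). At that vocabulary a full 50-cue × 3
survey per participant (15,000 draws against at most 4,005 distinct pairs)
would saturate the pair space regardless of the sampling law, so
`compact_config` scales the survey to 6 cues (2 fixed) per participant,
keeping the survey-to-vocabulary ratio in the sparse regime of real data.
With 20 seeds per condition:

* at h = 0 the observed edge-endpoint tau falls inside the null ensemble's
  central 95% in ≥ 90% of seeds (calibration);
* at h = 0.8 it exceeds all 50 null taus in ≥ 95% of seeds (power), and the
  seed-averaged tau is monotone in h over {0, 0.4, 0.8}.

## Known limitations

* The against-the-rest test is applied once per word on overlapping data
  (every "rest" shares most ratings); labels are descriptive, not jointly
  inferential.
* The configuration null preserves degrees and attributes but not higher-
  order structure (clustering, cue/response roles); a significant percentile
  means "not explained by degree + attribute counts", nothing stronger.
* Auras of low-degree words are unstable (a degree-2 word's aura flips with
  one neighbor); the aura table reports degrees so users can filter.
* With 50 null realisations the percentile has a resolution of 2 points;
  raise `n_realisations` for sharper tail statements.
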