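# fmnet — forma mentis networks

`fmnet` builds and analyses **forma mentis networks**: undirected networks of
free associations whose nodes carry population-level valence attributes.
They model how a group of people (say, high-school students vs. professional
researchers) conceptually structures its stance toward a topic — which words
remind them of which, and whether each word feels positive, neutral or
negative to that population.

The package is for cognitive/network scientists and education researchers
who run the two-task survey the framework relies on:

1. a **continuous free-association task** — each participant sees 50 cue
   words and writes up to three associative responses per cue;
2. a **valence rating task** — each participant rates words on a 1–5 Likert
   scale (1 = very negative, 5 = very positive; a blank counts as neutral).

## The model

* **Cleaning.** Tokens are lowercased and normalized through a user-supplied
  variant→canonical map; the first three associates of each form are blanked
  (warm-up/priming removal); forms with more than 25% blank cells are
  discarded and logged.
* **Valence attributes.** Ratings are pooled per word (blank → 3). Word *i*
  is labelled *negative* (*positive*) when its ratings *wᵢ* have a lower
  (higher) median than the pooled rest ⋃₍ⱼ≠ᵢ₎ *wⱼ* under a two-group
  Kruskal–Wallis test at α = 0.1; otherwise *neutral*. The pooled score
  distribution is summarised by the Pearson skewness 3(mean − median)/σ.
* **Network.** Nodes are words; an undirected edge {c, r} records that some
  participant produced response r to cue c; the weight counts the *distinct*
  participants who produced the pair. A filtered variant keeps only edges
  supported by ≥ 2 participants.
* **Valence auras.** The aura of a word summarises the valence composition
  of its immediate neighborhood: negative if it has more negative than
  positive neighbors, positive in the mirror case, neutral on a tie.
* **Emotional homophily.** Scoring attributes −m/0/+m (m = 1), two Kendall
  tau-b statistics quantify mixing: between the scores of link endpoints
  (both orientations of every edge), and between each word's score and its
  neighbors' mean score. Observed values are compared with a
  **configuration-model null** that fixes every node's degree and attribute
  while rewiring links by degree-preserving double-edge swaps (50
  realisations; the observed value's percentile in the null ensemble is the
  recommended inferential summary).
* **External validation.** Lexicon means can be cross-validated against any
  affective norm table (word, mean valence, optional mean arousal) via
  Kendall tau, and aura-defined word groups can be contrasted on external
  valence/arousal with Kruskal–Wallis tests.

Because real survey data of this kind is collected anonymously and rarely
redistributable, the package ships a first-class **synthetic survey
generator** with planted valence pools, tunable same-valence association
bias h ∈ [0, 1], Zipf-weighted response frequencies, skewed rating
distributions and participant-level blank rates — so the whole pipeline is
testable end to end with known ground truth.

## Worked example

```python
from fmnet import (
    compact_config, generate_survey, build_lexicon, build_network,
    compute_aura, configuration_null_ensemble,
)
from fmnet.io import discard_incomplete_forms, drop_warmup

config = compact_config(n_participants=60, homophily=0.6, seed=42)
survey = generate_survey(config)

assoc, _ = discard_incomplete_forms(drop_warmup(survey.association_forms, 3), 0.25)
ratings, _ = discard_incomplete_forms(survey.rating_forms, 0.25)

lexicon, skew = build_lexicon(ratings, alpha=0.1)
print(f"{len(lexicon)} words classified; pooled Pearson skewness {skew.pearson_skewness:.3f}")

graph = build_network(assoc, lexicon)
print(f"network: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges")

aura = compute_aura(graph, "neg001")
print(f"aura of 'neg001': {aura.frac_negative:.0%} negative / "
      f"{aura.frac_positive:.0%} positive neighbours -> {aura.aura}")

result = configuration_null_ensemble(graph, "edge_endpoint_tau", n_realisations=50, seed=42)
print(f"edge-endpoint tau {result.tau_observed:.3f} vs null mean {result.null_mean:.4f} "
      f"(percentile {result.percentile_of_observed:.0f})")
```

prints

```
90 words classified; pooled Pearson skewness -0.019
network: 89 nodes, 429 edges
aura of 'neg001': 83% negative / 17% positive neighbours -> negative
edge-endpoint tau 0.505 vs null mean -0.0271 (percentile 100)
```

All 90 planted words are classified; with association bias h = 0.6 the
planted-negative word `neg001` sits in a mostly negative neighborhood, and
the observed endpoint mixing (τ = 0.505) exceeds every one of the 50
attribute-and-degree-preserving null realisations (percentile 100) — the
signature of emotional homophily.

## Command line

The same pipeline is available as the `fmn` console script with subcommands
`simulate`, `clean`, `lexicon`, `build`, `aura`, `homophily`, `contrast`
and `run` (end-to-end with a reproducibility manifest):

```bash
fmn simulate --out survey/ --participants 60 --homophily 0.6 --seed 42
fmn run --associations survey/associations.tsv --ratings survey/ratings.tsv \
        --seed 42 --out results/
```

Exit codes: 0 success, 2 input/validation error, 3 statistical
precondition failure.

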