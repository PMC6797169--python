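"""Emotional-homophily statistics and attribute-preserving null models.

Valence attributes are mapped to arbitrary scores -m / 0 / +m (negative /
neutral / positive; m = 1 by default -- the rank-based statistics are
invariant to m).  Two mixing statistics quantify homophily:

* *edge-endpoint tau*: Kendall tau-b between the scores of link endpoints,
  with each undirected edge contributing both orientations so the result
  does not depend on an arbitrary edge ordering;
* *node-neighborhood tau*: Kendall tau-b between each word's own score and
  the unweighted mean score of its neighbors.

Observed values are compared against a configuration-model null ensemble
that fixes every node's degree and valence attribute while randomising
links through degree-preserving double-edge swaps (self-loops and
multi-edges rejected).  The ensemble reports the null mean tau, the mean
of per-realisation p-values, and the percentile of the observed tau within
the null distribution; only the percentile is recommended for inference.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from .errors import InputError, StatisticalError
from .lexicon import two_group_kruskal
from .network import compute_aura

ATTRIBUTE_SIGNS = {"negative": -1.0, "neutral": 0.0, "positive": 1.0}

EXACT_TAU_MAX_N = 8


@dataclass(frozen=True)
class HomophilyResult:
    """Observed mixing statistic plus its configuration-null ensemble."""

    statistic: str
    tau_observed: float
    p_observed: float
    null_taus: tuple[float, ...]
    null_p_values: tuple[float, ...]
    null_mean: float
    null_p_mean: float
    percentile_of_observed: float
    n_realisations: int
    seed: int
    swaps_per_edge: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(self.to_dict(), indent=2, ensure_ascii=False) + "\n",
            encoding="utf-8",
        )
        return path


@dataclass(frozen=True)
class AuraContrastResult:
    """KW contrast of an external measure between aura-defined word groups."""

    target_attribute: str
    aura_condition: str
    measure: str
    n_condition: int
    n_any: int
    statistic: float
    p_value: float
    direction: str

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Kendall tau
# ---------------------------------------------------------------------------


def kendall_tau(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b with an asymptotic or exact p-value.

    ``method="auto"`` enumerates the full permutation distribution when
    n <= 8 and falls back to the normal approximation otherwise;
    ``"asymptotic"`` and ``"exact"`` force a choice.  Tau-b is undefined
    when either vector is constant (zero tied-pair denominator); this is
    signalled as a :class:`StatisticalError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise StatisticalError("kendall_tau needs at least 2 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatisticalError("kendall_tau undefined: a vector is constant")
    if method not in ("auto", "asymptotic", "exact"):
        raise InputError(f"unknown method {method!r}")
    if method == "exact" and x.size > EXACT_TAU_MAX_N:
        raise InputError(
            f"exact enumeration supported for n <= {EXACT_TAU_MAX_N}, got n={x.size}"
        )
    if x.size == 2:
        # a single non-tied pair: tau is +/-1 and both orderings of y are
        # equally extreme, so the two-sided p is 1 regardless of method
        return float(np.sign((x[1] - x[0]) * (y[1] - y[0]))), 1.0
    result = sps.kendalltau(x, y, variant="b", method="asymptotic")
    tau = float(result.statistic)
    if method == "exact" or (method == "auto" and x.size <= EXACT_TAU_MAX_N):
        p = _exact_tau_p(x, y)
    else:
        p = float(result.pvalue)
    return tau, p


def _exact_tau_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p for tau by full enumeration of y-orderings.

    With x fixed and the multiset of y fixed, tau is monotone in the raw
    concordance score S, so permutations are compared on |S|.
    """
    n = x.size
    perms = np.array(list(itertools.permutations(range(n))))
    yp = y[perms]  # (n!, n)
    iu, ju = np.triu_indices(n, k=1)
    sx = np.sign(x[ju] - x[iu])  # (n_pairs,)
    sy = np.sign(yp[:, ju] - yp[:, iu])  # (n!, n_pairs)
    scores = sy @ sx
    observed = scores[0]  # identity permutation comes first
    return float(np.mean(np.abs(scores) >= abs(observed) - 1e-9))


# ---------------------------------------------------------------------------
# mixing statistics on a forma mentis network
# ---------------------------------------------------------------------------


def attribute_scores(graph: nx.Graph, m: float = 1.0) -> dict[str, float]:
    if m <= 0:
        raise InputError(f"score magnitude m must be positive, got {m}")
    return {
        node: m * ATTRIBUTE_SIGNS[data.get("valence", "neutral")]
        for node, data in graph.nodes(data=True)
    }


def edge_endpoint_tau(
    graph: nx.Graph,
    m: float = 1.0,
    symmetrized: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Kendall tau-b between the valence scores of link endpoints.

    Each undirected edge contributes both orientations by default, which
    makes the statistic independent of edge orientation and ordering.
    ``symmetrized=False`` uses one random orientation per edge (seeded via
    ``rng``), as a sensitivity check.
    """
    edges = list(graph.edges())
    if len(edges) < 2:
        raise StatisticalError("edge_endpoint_tau needs at least 2 edges")
    scores = attribute_scores(graph, m)
    if symmetrized:
        x = [scores[u] for u, v in edges] + [scores[v] for u, v in edges]
        y = [scores[v] for u, v in edges] + [scores[u] for u, v in edges]
    else:
        rng = rng or np.random.default_rng()
        flips = rng.integers(0, 2, size=len(edges))
        x, y = [], []
        for (u, v), flip in zip(edges, flips):
            a, b = (v, u) if flip else (u, v)
            x.append(scores[a])
            y.append(scores[b])
    try:
        return kendall_tau(x, y, method="asymptotic")
    except StatisticalError as exc:
        raise StatisticalError(
            "edge_endpoint_tau undefined: all linked words share one attribute"
        ) from exc


def node_neighborhood_tau(graph: nx.Graph, m: float = 1.0) -> tuple[float, float]:
    """Kendall tau-b between a word's score and its neighbors' mean score.

    Neighborhood means are unweighted (each neighbor counts once),
    consistent with the aura definition.  Isolated nodes are excluded; a
    network with no edges is an error.
    """
    scores = attribute_scores(graph, m)
    x, y = [], []
    for node in graph.nodes:
        neighbors = list(graph.neighbors(node))
        if not neighbors:
            continue
        x.append(scores[node])
        y.append(float(np.mean([scores[v] for v in neighbors])))
    if len(x) < 2:
        raise StatisticalError("node_neighborhood_tau needs >= 2 non-isolated nodes")
    try:
        return kendall_tau(x, y, method="asymptotic")
    except StatisticalError as exc:
        raise StatisticalError(
            "node_neighborhood_tau undefined: degenerate attribute distribution"
        ) from exc


# ---------------------------------------------------------------------------
# configuration-model null ensemble
# ---------------------------------------------------------------------------


def degree_preserving_swap(
    graph: nx.Graph,
    rng: np.random.Generator,
    swaps_per_edge: int = 10,
    max_tries_factor: int = 200,
) -> nx.Graph:
    """One null realisation: rewire links by degree-preserving double-edge swaps.

    Performs ``swaps_per_edge * |E|`` *accepted* swaps; proposals creating
    self-loops or multi-edges are rejected.  Node attributes and the degree
    sequence are preserved exactly; edge weights are reset to 1 (the mixing
    statistics ignore them).  A graph too constrained to swap raises a
    :class:`StatisticalError`.
    """
    edges = [list(e) for e in graph.edges()]
    m = len(edges)
    if m < 2:
        raise StatisticalError("rewiring needs at least 2 edges")
    edge_set = {frozenset(e) for e in edges}
    n_swaps = swaps_per_edge * m
    max_tries = max(10_000, max_tries_factor * n_swaps)

    accepted = 0
    tries = 0
    chunk = 1 << 14
    ptr = chunk
    pair_buf = flip_buf = None
    while accepted < n_swaps:
        if ptr >= chunk:
            pair_buf = rng.integers(0, m, size=(chunk, 2))
            flip_buf = rng.integers(0, 2, size=chunk)
            ptr = 0
        i, j = pair_buf[ptr]
        flip = flip_buf[ptr]
        ptr += 1
        tries += 1
        if tries > max_tries:
            raise StatisticalError(
                f"degree-preserving rewiring stalled: {accepted}/{n_swaps} swaps "
                f"after {tries} proposals (graph too dense or constrained)"
            )
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip:
            c, d = d, c
        if a == d or c == b:
            continue  # self-loop
        new1 = frozenset((a, d))
        new2 = frozenset((c, b))
        if new1 == new2 or new1 in edge_set or new2 in edge_set:
            continue  # multi-edge
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = [a, d]
        edges[j] = [c, b]
        accepted += 1

    rewired = nx.Graph()
    rewired.graph.update(graph.graph)
    rewired.graph["rewired"] = True
    rewired.add_nodes_from(graph.nodes(data=True))
    rewired.add_edges_from((u, v, {"weight": 1}) for u, v in edges)
    return rewired


_STATISTICS: dict[str, Callable] = {
    "edge_endpoint_tau": edge_endpoint_tau,
    "node_neighborhood_tau": node_neighborhood_tau,
}


def configuration_null_ensemble(
    graph: nx.Graph,
    statistic: str = "edge_endpoint_tau",
    n_realisations: int = 50,
    seed: int = 0,
    swaps_per_edge: int = 10,
    m: float = 1.0,
) -> HomophilyResult:
    """Observed mixing statistic vs its attribute-preserving null ensemble.

    Every realisation preserves the empirical degree sequence and the
    valence attribute of every word while randomising which words are
    linked.  The result is bit-reproducible for a fixed seed.
    """
    if statistic not in _STATISTICS:
        raise InputError(
            f"unknown statistic {statistic!r}; expected one of {sorted(_STATISTICS)}"
        )
    if n_realisations < 1:
        raise InputError("n_realisations must be >= 1")
    stat_fn = _STATISTICS[statistic]
    tau_obs, p_obs = stat_fn(graph, m=m)

    rng = np.random.default_rng(seed)
    null_taus = []
    null_ps = []
    for _ in range(n_realisations):
        realisation = degree_preserving_swap(graph, rng, swaps_per_edge=swaps_per_edge)
        tau_r, p_r = stat_fn(realisation, m=m)
        null_taus.append(tau_r)
        null_ps.append(p_r)
    null_arr = np.asarray(null_taus)
    below = int(np.sum(null_arr < tau_obs))
    equal = int(np.sum(null_arr == tau_obs))
    percentile = 100.0 * (below + 0.5 * equal) / n_realisations
    return HomophilyResult(
        statistic=statistic,
        tau_observed=tau_obs,
        p_observed=p_obs,
        null_taus=tuple(null_taus),
        null_p_values=tuple(null_ps),
        null_mean=float(null_arr.mean()),
        null_p_mean=float(np.mean(null_ps)),
        percentile_of_observed=percentile,
        n_realisations=n_realisations,
        seed=seed,
        swaps_per_edge=swaps_per_edge,
    )


# ---------------------------------------------------------------------------
# aura contrasts against external norms
# ---------------------------------------------------------------------------


def aura_contrast(
    graph: nx.Graph,
    norms,
    target_attribute: str = "negative",
    aura_condition: str = "negative",
    measure: str = "valence",
    aura_rule: str = "polarity",
) -> AuraContrastResult:
    """Contrast an external measure between aura subsets of same-valence words.

    Group A holds the words of ``target_attribute`` whose aura equals
    ``aura_condition``; group B holds words of ``target_attribute`` with
    *any* aura.  Both are intersected with the external norm table and
    compared by a two-group Kruskal-Wallis test on the external measure
    (``valence`` or ``arousal``).
    """
    if measure not in ("valence", "arousal"):
        raise InputError(f"measure must be 'valence' or 'arousal', got {measure!r}")
    table = norms.valence if measure == "valence" else norms.arousal
    candidates = [
        node
        for node, data in graph.nodes(data=True)
        if data.get("valence") == target_attribute and graph.degree(node) > 0
    ]
    any_aura = [w for w in candidates if w in table]
    if len(any_aura) < 2:
        raise StatisticalError(
            f"aura_contrast: only {len(any_aura)} {target_attribute} words overlap "
            f"the norm table (need >= 2)"
        )
    condition = [
        w
        for w in any_aura
        if compute_aura(graph, w, rule=aura_rule).aura == aura_condition
    ]
    if len(condition) < 2:
        raise StatisticalError(
            f"aura_contrast: only {len(condition)} {target_attribute} words with "
            f"{aura_condition} aura overlap the norm table (need >= 2)"
        )
    values_a = np.array([table[w] for w in condition], dtype=float)
    values_b = np.array([table[w] for w in any_aura], dtype=float)
    statistic, p_value = two_group_kruskal(values_a, values_b)
    med_a, med_b = float(np.median(values_a)), float(np.median(values_b))
    if med_a > med_b:
        direction = "condition > any"
    elif med_a < med_b:
        direction = "condition < any"
    else:
        direction = "none"
    return AuraContrastResult(
        target_attribute=target_attribute,
        aura_condition=aura_condition,
        measure=measure,
        n_condition=len(condition),
        n_any=len(any_aura),
        statistic=statistic,
        p_value=p_value,
        direction=direction,
    )
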