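"""Forma mentis network construction, filtering, and valence auras.

A forma mentis network is an undirected simple graph whose nodes are words,
whose edges are free associations, and whose edge weights count the
distinct participants who produced the association (in either cue-response
orientation).  Node attributes carry the population-level valence label
(positive / neutral / negative) from a :class:`~fmnet.lexicon.ValenceLexicon`;
words never rated default to neutral and are flagged ``unrated``.

The *valence aura* of a word is the valence composition of its immediate
neighborhood.  Two labelling rules are supported:

``polarity`` (default)
    negative if the word has more negative than positive neighbors,
    positive if more positive than negative, neutral on a tie; neutral
    neighbors do not enter the polarity comparison.
``majority``
    strict three-class majority over neighbor attributes; any tie for the
    maximum gives neutral.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import InputError
from .io import BLANK, ResponseForm
from .lexicon import ValenceLexicon

AURA_RULES = ("polarity", "majority")


@dataclass(frozen=True)
class AuraProfile:
    """Neighborhood valence composition of one word."""

    word: str
    frac_positive: float
    frac_neutral: float
    frac_negative: float
    aura: str
    degree: int


# ---------------------------------------------------------------------------
# construction and filtering
# ---------------------------------------------------------------------------


def build_network(
    forms: Sequence[ResponseForm],
    lexicon: ValenceLexicon | None = None,
    population: str | None = None,
) -> nx.Graph:
    """Build the unfiltered forma mentis network from cleaned forms.

    Every non-blank response r to cue c contributes the undirected edge
    {c, r}; the edge weight is the number of *distinct* participants who
    produced that pair in either orientation (repeats by one participant
    count once).  Responses equal to their cue are skipped (no self-loops).
    The cue-side provenance of each edge is kept in the string attribute
    ``cued_from`` but is ignored by all statistics.
    """
    if not forms:
        raise InputError("cannot build a network from zero forms")
    participants: dict[tuple[str, str], set[str]] = {}
    cue_sides: dict[tuple[str, str], set[str]] = {}
    for form in forms:
        for cue, responses in form.entries:
            for response in responses:
                if response == BLANK or response == cue:
                    continue
                pair = (cue, response) if cue <= response else (response, cue)
                participants.setdefault(pair, set()).add(form.participant_id)
                cue_sides.setdefault(pair, set()).add(cue)

    graph = nx.Graph()
    graph.graph["min_participants"] = 1
    if population is not None:
        graph.graph["population"] = population
    for (u, v), pids in participants.items():
        graph.add_edge(
            u,
            v,
            weight=len(pids),
            cued_from="|".join(sorted(cue_sides[(u, v)])),
        )
    for node in graph.nodes:
        rated = lexicon is not None and node in lexicon
        graph.nodes[node]["valence"] = (
            lexicon.attribute(node) if lexicon is not None else "neutral"
        )
        graph.nodes[node]["unrated"] = not rated
    return graph


def filter_network(graph: nx.Graph, min_participants: int = 2) -> nx.Graph:
    """Keep only associations supported by >= ``min_participants`` participants.

    Nodes left isolated are dropped.  Filtering is idempotent and composes
    by the maximum threshold; the resulting level is recorded in the graph
    metadata.
    """
    if min_participants < 1:
        raise InputError(f"min_participants must be >= 1, got {min_participants}")
    out = nx.Graph()
    out.graph.update(graph.graph)
    out.graph["min_participants"] = max(
        int(graph.graph.get("min_participants", 1)), min_participants
    )
    for u, v, data in graph.edges(data=True):
        if data.get("weight", 1) >= min_participants:
            out.add_edge(u, v, **data)
    for node in out.nodes:
        out.nodes[node].update(graph.nodes[node])
    out.graph["empty"] = out.number_of_edges() == 0
    return out


# ---------------------------------------------------------------------------
# valence auras
# ---------------------------------------------------------------------------


def compute_aura(
    graph: nx.Graph,
    word: str,
    rule: str = "polarity",
    weighted: bool = False,
) -> AuraProfile:
    """Valence aura of ``word``: neighbor fractions and a polarity label.

    Fractions are unweighted neighbor proportions by default (each neighbor
    counts once); ``weighted=True`` weighs neighbors by edge weight.
    """
    if rule not in AURA_RULES:
        raise InputError(f"unknown aura rule {rule!r}; expected one of {AURA_RULES}")
    if word not in graph:
        raise InputError(f"word {word!r} is not in the network")
    if graph.degree(word) == 0:
        raise InputError(f"word {word!r} is isolated; its aura is undefined")
    counts = {"positive": 0.0, "neutral": 0.0, "negative": 0.0}
    for neighbor in graph.neighbors(word):
        attr = graph.nodes[neighbor].get("valence", "neutral")
        counts[attr] += graph[word][neighbor].get("weight", 1) if weighted else 1.0
    total = sum(counts.values())
    frac = {k: v / total for k, v in counts.items()}

    if rule == "majority":
        top = max(counts.values())
        leaders = [attr for attr, c in counts.items() if c == top]
        aura = leaders[0] if len(leaders) == 1 else "neutral"
    else:  # polarity: positive vs negative head-to-head, tie -> neutral
        if counts["negative"] > counts["positive"]:
            aura = "negative"
        elif counts["positive"] > counts["negative"]:
            aura = "positive"
        else:
            aura = "neutral"
    return AuraProfile(
        word=word,
        frac_positive=frac["positive"],
        frac_neutral=frac["neutral"],
        frac_negative=frac["negative"],
        aura=aura,
        degree=graph.degree(word),
    )


def aura_table(
    graph: nx.Graph,
    words: Iterable[str],
    rule: str = "polarity",
    weighted: bool = False,
) -> pd.DataFrame:
    """Aura profiles for a list of words (e.g. the fixed cue words), in order."""
    rows = []
    for word in words:
        if word not in graph:
            raise InputError(f"word {word!r} is not in the network")
        profile = compute_aura(graph, word, rule=rule, weighted=weighted)
        rows.append(
            {
                "word": profile.word,
                "degree": profile.degree,
                "frac_positive": profile.frac_positive,
                "frac_neutral": profile.frac_neutral,
                "frac_negative": profile.frac_negative,
                "aura": profile.aura,
                "valence": graph.nodes[word].get("valence", "neutral"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

FORMATS = ("graphml", "edgelist", "nodes")


def export_network(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> Path:
    """Write the network as GraphML, a weighted TSV edge list, or a node CSV.

    GraphML round-trips the full object (node attributes, edge weights,
    graph metadata); the edge list carries topology + weights and the node
    CSV carries node attributes, so the pair of them also round-trips.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, path, encoding="utf-8")
    elif fmt == "edgelist":
        lines = ["source\ttarget\tweight"]
        for u, v, data in graph.edges(data=True):
            lines.append(f"{u}\t{v}\t{data.get('weight', 1)}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt == "nodes":
        rows = [
            {
                "word": node,
                "valence": data.get("valence", "neutral"),
                "unrated": data.get("unrated", False),
            }
            for node, data in graph.nodes(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")
    else:
        raise InputError(f"unknown export format {fmt!r}; expected one of {FORMATS}")
    return path


def import_network(path: str | Path, fmt: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`export_network`.

    The edge-list format restores topology and weights only; combine with
    :func:`read_node_table` / :func:`from_edgelist_and_nodes` to restore
    node attributes.
    """
    path = Path(path)
    if fmt == "graphml":
        graph = nx.read_graphml(path, node_type=str)
        # GraphML integers come back as ints, but make weights robust
        for _, _, data in graph.edges(data=True):
            if "weight" in data:
                data["weight"] = int(data["weight"])
        return graph
    if fmt == "edgelist":
        graph = nx.Graph()
        with Path(path).open(encoding="utf-8") as fh:
            header = fh.readline()
            if header.strip() != "source\ttarget\tweight":
                raise InputError(f"{path}: not a weighted edge list (bad header)")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise InputError(f"{path}:{lineno}: expected 3 fields")
                u, v, w = parts
                graph.add_edge(u, v, weight=int(w))
        return graph
    raise InputError(f"unknown import format {fmt!r}")


def read_node_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, encoding="utf-8")
    required = {"word", "valence", "unrated"}
    if not required.issubset(frame.columns):
        raise InputError(f"{path}: node table must have columns {sorted(required)}")
    return frame


def from_edgelist_and_nodes(edge_path: str | Path, node_path: str | Path) -> nx.Graph:
    """Rebuild a forma mentis network from its edge-list + node-table export."""
    graph = import_network(edge_path, fmt="edgelist")
    nodes = read_node_table(node_path)
    for _, row in nodes.iterrows():
        word = str(row["word"])
        if word not in graph:
            graph.add_node(word)
        graph.nodes[word]["valence"] = str(row["valence"])
        graph.nodes[word]["unrated"] = bool(row["unrated"])
    return graph
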