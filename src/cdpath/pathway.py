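"""Stratified first-order learning-pathway network and dominant path.

Knowledge states are stratified by level (number of mastered attributes,
0..K).  A first-order transition is an edge from state s to state t when s
is a subset of t and they differ by exactly one attribute — the acquisition
of a single new skill.  Restricting to the most frequent states keeps the
network readable; the dominant learning path is the source-to-sink chain
(from the all-zero to the all-one state) carrying the greatest total
student frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .estimation import PosteriorClassification
from .models import string_to_profile

logger = logging.getLogger("cdpath")

__all__ = [
    "StateFrequencyTable",
    "PathwayGraph",
    "tabulate_states",
    "stratify",
    "top_states",
    "build_graph",
    "dominant_path",
]


@dataclass(frozen=True)
class StateFrequencyTable:
    """Counts of examinees per observed knowledge state (string keyed)."""

    counts: dict
    total_n: int

    def __post_init__(self):
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("state counts must be >= 1")
        if sum(self.counts.values()) > self.total_n:
            raise ValueError("state counts exceed total_n")
        k = {len(s) for s in self.counts}
        if len(k) > 1:
            raise ValueError("states have inconsistent attribute counts")

    @property
    def n_states(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class PathwayGraph:
    """Level-layered first-order transition network over retained states."""

    graph: nx.DiGraph
    coverage: float
    total_n: int
    dominant: tuple[str, ...] = field(default=())

    @property
    def states(self) -> list[str]:
        return sorted(self.graph.nodes)

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "state": s,
                    "count": int(self.graph.nodes[s]["count"]),
                    "level": int(self.graph.nodes[s]["level"]),
                }
                for s in self.states
            ],
            "edges": [{"from": u, "to": v} for u, v in sorted(self.graph.edges)],
            "dominant_path": list(self.dominant),
            "coverage": self.coverage,
            "total_n": self.total_n,
        }

    def to_dot(self) -> str:
        lines = ["digraph pathway {", "  rankdir=BT;"]
        for s in self.states:
            n = self.graph.nodes[s]
            lines.append(f'  "{s}" [label="{s}\\n(n={n["count"]})"];')
        dom = set(zip(self.dominant, self.dominant[1:]))
        for u, v in sorted(self.graph.edges):
            style = ' [color=red, penwidth=2]' if (u, v) in dom else ""
            lines.append(f'  "{u}" -> "{v}"{style};')
        lines.append("}")
        return "\n".join(lines)


def tabulate_states(classification: PosteriorClassification) -> StateFrequencyTable:
    """Tally MAP knowledge states over the cohort."""
    states = classification.map_states
    if not states:
        raise ValueError("empty classification")
    counts: dict[str, int] = {}
    for s in states:
        counts[s] = counts.get(s, 0) + 1
    return StateFrequencyTable(counts=counts, total_n=len(states))


def stratify(states) -> dict:
    """Level of each state = number of mastered attributes (popcount)."""
    return {s: int(string_to_profile(s).sum()) for s in states}


def top_states(table: StateFrequencyTable, k: int = 17) -> tuple[dict, float]:
    """The k most frequent states and the fraction of examinees they cover.

    Ties at the rank boundary are broken toward the lower state index (the
    state string read as a binary number) and logged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if k < len(order) and order[k - 1][1] == order[k][1]:
        logger.info(
            "tie at top-%d boundary (count=%d); retained lower-index state %s",
            k, order[k - 1][1], order[k - 1][0],
        )
    retained = dict(order[:k])
    coverage = sum(retained.values()) / table.total_n
    return retained, coverage


def _is_first_order(s: str, t: str) -> bool:
    a, b = string_to_profile(s), string_to_profile(t)
    return bool(np.all(a <= b) and (b - a).sum() == 1)


def build_graph(retained: dict, total_n: int | None = None) -> PathwayGraph:
    """First-order subset edges among the retained states.

    ``retained`` maps state strings to examinee counts.
    """
    if not retained:
        raise ValueError("no states to build a graph from")
    levels = stratify(retained)
    g = nx.DiGraph()
    for s, c in retained.items():
        g.add_node(s, count=int(c), level=levels[s])
    states = sorted(retained)
    for s in states:
        for t in states:
            if levels[t] == levels[s] + 1 and _is_first_order(s, t):
                g.add_edge(s, t)
    n = total_n if total_n is not None else sum(retained.values())
    coverage = sum(retained.values()) / n
    return PathwayGraph(graph=g, coverage=coverage, total_n=n)


def dominant_path(pathway: PathwayGraph) -> tuple[str, ...]:
    """Source-to-sink path maximizing total node frequency.

    Dynamic program over the level-layered DAG from the all-zero state to
    the all-one state; ties are broken lexicographically by the path's
    state strings.  Raises if either terminal state is absent or no chain
    of first-order transitions connects them.
    """
    g = pathway.graph
    some_state = next(iter(g.nodes))
    k = len(some_state)
    source, sink = "0" * k, "1" * k
    missing = [s for s in (source, sink) if s not in g]
    if missing:
        raise ValueError(f"graph lacks terminal state(s): {missing}")
    # best[s] = (score, path tuple); process states in level order
    best: dict[str, tuple[int, tuple[str, ...]]] = {
        source: (g.nodes[source]["count"], (source,))
    }
    by_level = sorted(g.nodes, key=lambda s: (g.nodes[s]["level"], s))
    for t in by_level:
        if t == source:
            continue
        options = []
        for u in g.predecessors(t):
            if u in best:
                score, path = best[u]
                options.append((score + g.nodes[t]["count"], path + (t,)))
        if options:
            # highest score; among ties the lexicographically smallest path
            best[t] = min(options, key=lambda sp: (-sp[0], sp[1]))
    if sink not in best:
        reached = {g.nodes[s]["level"] for s in best}
        gap = sorted(set(range(k + 1)) - reached)
        raise ValueError(
            f"no first-order chain from {source} to {sink}; "
            f"no retained state reachable at level(s) {gap}"
        )
    return best[sink][1]
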