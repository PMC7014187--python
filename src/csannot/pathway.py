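"""Compound-level metabolic network and pathway distances.

Compounds are linked whenever they participate in the same biochemical
reaction (substrates and products pooled, no directionality), so a pathway
distance of N reactions means the shortest route between two compounds runs
through N-1 intermediate compounds. The all-pairs distance matrix over this
unweighted graph is the geometric backbone of context-support scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = ["build_network", "distance_matrix", "DistanceMatrix"]

#: sentinel for unreachable compound pairs (never contributes to any score)
UNREACHABLE = np.inf


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs shortest-path reaction counts between compounds.

    ``d[i, j]`` is the minimum number of reactions linking compounds
    ``ids[i]`` and ``ids[j]``; unreachable pairs hold ``inf``.
    """

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.ids)})

    def index_of(self, compound_id: str) -> int:
        return self._index[compound_id]

    def between(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids))
        df.to_csv(path, sep="\t", index_label="compound_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="compound_id")
        return cls(tuple(df.index.astype(str)), df.to_numpy(float))


def build_network(
    compounds: pd.DataFrame,
    reactions: pd.DataFrame,
    exclude: Iterable[str] = (),
) -> nx.Graph:
    """Build the undirected compound graph from reaction participation.

    Every pair of distinct participants (substrates and products pooled) of
    a reaction is joined by an edge; compounds in no reaction remain as
    isolated nodes. ``exclude`` lists currency-like hub compounds whose
    edges are suppressed (they stay in the graph as isolated nodes so the
    matrix keeps one row per compound).

    Raises
    ------
    KeyError
        If a reaction references a compound absent from the compound table;
        the message names the offending reaction.
    """
    known = set(compounds["compound_id"])
    excluded = set(exclude)
    graph = nx.Graph()
    graph.add_nodes_from(compounds["compound_id"])
    for _, row in reactions.iterrows():
        participants = list(dict.fromkeys([*row["substrates"], *row["products"]]))
        unknown = [c for c in participants if c not in known]
        if unknown:
            raise KeyError(
                f"reaction {row['reaction_id']} references unknown compound(s): {unknown}")
        linked = [c for c in participants if c not in excluded]
        graph.add_edges_from(combinations(linked, 2))
    return graph


def distance_matrix(
    network: nx.Graph, order: Sequence[str] | None = None
) -> DistanceMatrix:
    """All-pairs shortest-path reaction counts via BFS on the sparse adjacency."""
    nodes = list(order) if order is not None else list(network.nodes)
    n = len(nodes)
    if n == 0:
        return DistanceMatrix((), np.zeros((0, 0)))
    adj = nx.to_scipy_sparse_array(network, nodelist=nodes, format="csr")
    d = shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(nodes), d)
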