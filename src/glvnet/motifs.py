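"""Directed 3-node motif counting and significance against degree-preserving nulls.

Edge signs are ignored: motif topology is assessed on the unsigned
directed graph.  Counts are reported per weakly-connected triad
isomorphism class in the standard triad-census nomenclature; the fan-in
class (two edges converging on one node, ``021U``) is flagged because it
is the configuration the downstream analysis screens for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MotifReport",
    "CONNECTED_TRIADS",
    "FAN_IN_CLASS",
    "count_triad_motifs",
    "motif_significance",
    "build_digraph",
]

#: Triad classes on 3 mutually reachable (weakly connected) nodes; the
#: census classes 003, 012 and 102 contain an isolated node and are excluded.
CONNECTED_TRIADS = (
    "021D",
    "021U",
    "021C",
    "111D",
    "111U",
    "030T",
    "030C",
    "201",
    "120D",
    "120U",
    "120C",
    "210",
    "300",
)

#: Two directed edges pointing to the same node.
FAN_IN_CLASS = "021U"


@dataclass
class MotifReport:
    """Observed triad counts with null mean/sd and z-scores.

    ``table`` columns: motif_class, observed, null_mean, null_sd, z.
    ``z`` is NaN where the null ensemble is degenerate (sd = 0).
    """

    table: pd.DataFrame
    n_random: int

    def z_of(self, motif_class: str) -> float:
        return float(self.table.set_index("motif_class").loc[motif_class, "z"])


def build_digraph(edges: list[tuple[str, str]]) -> nx.DiGraph:
    """Simple directed graph from an edge list; self-loops are stripped."""
    g = nx.DiGraph()
    n_loops = 0
    for u, v in edges:
        if u == v:
            n_loops += 1
            continue
        g.add_edge(u, v)
    if n_loops:
        warnings.warn(f"stripped {n_loops} self-loop(s)", stacklevel=2)
    return g


def count_triad_motifs(
    edges: list[tuple[str, str]] | nx.DiGraph,
) -> dict[str, int]:
    """Count connected 3-node induced subgraphs per isomorphism class."""
    g = edges if isinstance(edges, nx.DiGraph) else build_digraph(edges)
    if any(u == v for u, v in g.edges):
        g = build_digraph(list(g.edges))
    census = nx.triadic_census(g)
    return {cls: int(census[cls]) for cls in CONNECTED_TRIADS}


def _null_sample(g: nx.DiGraph, swaps_per_edge: int, rng_seed: int) -> nx.DiGraph:
    """One degree-preserving randomization via pairwise directed edge swaps.

    The classic rewiring move: edges u->v and x->y become u->y and x->v,
    which conserves every node's in- and out-degree exactly; moves that
    would create a self-loop or a duplicate edge are rejected.  Falls
    back to a configuration-model draw (with a warning) when the graph
    admits no legal swaps at all.
    """
    rng = np.random.default_rng(rng_seed)
    edges = list(g.edges())
    edge_set = set(edges)
    m = len(edges)
    nswap = max(1, swaps_per_edge * m)
    max_tries = nswap * 20
    swapped = tries = 0
    while swapped < nswap and tries < max_tries:
        batch = rng.integers(0, m, size=(4096, 2))
        for i, j in batch:
            tries += 1
            if swapped >= nswap or tries >= max_tries:
                break
            if i == j:
                continue
            u, v = edges[i]
            x, y = edges[j]
            if v == y or u == x:
                continue  # swap would be a no-op or duplicate a head/tail
            if u == y or x == v:
                continue  # would create a self-loop
            if (u, y) in edge_set or (x, v) in edge_set:
                continue
            edge_set -= {(u, v), (x, y)}
            edge_set |= {(u, y), (x, v)}
            edges[i], edges[j] = (u, y), (x, v)
            swapped += 1
    if swapped == 0 and m > 1:
        warnings.warn(
            "graph admits no legal edge swaps; using configuration-model sampling",
            stacklevel=2,
        )
        nodes = list(g.nodes)
        din = [d for _, d in g.in_degree(nodes)]
        dout = [d for _, d in g.out_degree(nodes)]
        for attempt in range(200):  # rejection sampling keeps degrees exact
            cm = nx.directed_configuration_model(
                din, dout, seed=rng_seed * 1000 + attempt
            )
            simple_edges = {(u, v) for u, v in cm.edges() if u != v}
            if len(simple_edges) == m:
                h = nx.DiGraph()
                h.add_nodes_from(range(len(nodes)))
                h.add_edges_from(simple_edges)
                return nx.relabel_nodes(h, dict(enumerate(nodes)))
        return g.copy()
    h = nx.DiGraph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from(edges)
    return h


def motif_significance(
    edges: list[tuple[str, str]] | nx.DiGraph,
    n_random: int = 1000,
    seed: int = 0,
    swaps_per_edge: int = 100,
) -> MotifReport:
    """z-scores of observed triad counts against a rewired null ensemble.

    The null preserves every node's in- and out-degree (directed edge
    swaps, ``swaps_per_edge`` swap attempts per edge).  z = (observed -
    null mean) / null sd; classes whose null count never varies are
    reported with z = NaN.
    """
    if n_random < 10:
        raise ValueError("n_random must be >= 10")
    g = edges if isinstance(edges, nx.DiGraph) else build_digraph(edges)
    observed = count_triad_motifs(g)
    rng = np.random.default_rng(seed)
    null_counts = {cls: np.empty(n_random) for cls in CONNECTED_TRIADS}
    for r in range(n_random):
        h = _null_sample(g, swaps_per_edge, int(rng.integers(0, 2**31 - 1)))
        counts = count_triad_motifs(h)
        for cls in CONNECTED_TRIADS:
            null_counts[cls][r] = counts[cls]
    rows = []
    for cls in CONNECTED_TRIADS:
        mean = float(null_counts[cls].mean())
        sd = float(null_counts[cls].std(ddof=0))
        z = (observed[cls] - mean) / sd if sd > 0 else float("nan")
        rows.append(
            {
                "motif_class": cls,
                "observed": observed[cls],
                "null_mean": mean,
                "null_sd": sd,
                "z": z,
                "fan_in": cls == FAN_IN_CLASS,
            }
        )
    return MotifReport(table=pd.DataFrame(rows), n_random=n_random)
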