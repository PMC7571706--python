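"""Mutation-bias and composition-bias statistics.

Both biases are measured on the unit interval by the same statistic,

    bias = Ti / (Ti + Tv/2),

where Ti and Tv are transition and transversion rates (mutation bias) or
counts (composition bias). The value 0.5 is the null expectation of one
transition per two transversions — the ratio forced by the alphabet, since
every site has one transition and two transversion alternatives. Values
below 0.5 indicate enrichment for transversions, above 0.5 for transitions.

Composition bias is evaluated over whole landscapes (all edges of the
dominant genotype network) and over accessible mutational paths from
low-affinity genotypes to the global peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .genotype_space import TRANSITION, TRANSVERSION
from .landscape import Landscape


class UnreachablePeakError(ValueError):
    """The global peak cannot be reached from any start genotype."""


@dataclass(frozen=True)
class BiasValue:
    value: float
    ti: float
    tv: float

    def __float__(self) -> float:
        return self.value


def bias(ti: float, tv: float) -> BiasValue:
    """Ti / (Ti + Tv/2); scale invariant, so rates and counts are interchangeable."""
    if ti < 0 or tv < 0:
        raise ValueError("Ti and Tv must be nonnegative")
    if ti == 0 and tv == 0:
        raise ValueError("Ti and Tv cannot both be zero")
    return BiasValue(value=ti / (ti + tv / 2), ti=ti, tv=tv)


def landscape_composition_bias(L: Landscape) -> BiasValue:
    """Composition bias over all undirected edges of the dominant network."""
    if not L.edges:
        raise ValueError(f"{L.tf_name}: landscape has no edges")
    ti = sum(1 for _, _, cls in L.edges if cls == TRANSITION)
    tv = len(L.edges) - ti
    return bias(ti, tv)


@dataclass
class AccessibleGraph:
    """Directed graph of accessible steps toward the global peak.

    strict mode: edge i->j iff b_j - b_i > delta (acyclic — scores strictly
    increase along edges). relaxed mode: edge i->j iff b_j - b_i >= -delta
    (steps that do not *decrease* affinity beyond the noise threshold; may
    contain cycles). Starts are the bottom fraction q of genotypes by score.
    """

    landscape: Landscape
    graph: nx.DiGraph
    mode: str
    starts: tuple[str, ...]
    target: str

    @property
    def delta(self) -> float:
        return self.landscape.delta


def accessible_graph(L: Landscape, mode: str = "strict", q: float = 0.10) -> AccessibleGraph:
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"mode must be 'strict' or 'relaxed', got {mode!r}")
    G = nx.DiGraph()
    G.add_nodes_from(L.genotypes)
    b, d = L.scores, L.delta
    for i, j, cls in L.edges:
        for u, v in ((i, j), (j, i)):
            diff = b[v] - b[u]
            if (diff > d) if mode == "strict" else (diff >= -d):
                G.add_edge(L.genotypes[u], L.genotypes[v], mclass=cls)
    starts = tuple(L.genotypes[i] for i in L.bottom_fraction(q))
    if not starts:
        raise ValueError("empty start set")
    return AccessibleGraph(landscape=L, graph=G, mode=mode, starts=starts, target=L.peak)


def _path_edges(AG: AccessibleGraph) -> list[tuple[str, str, str]]:
    """Edges lying on at least one start -> peak path of the accessible graph."""
    G = AG.graph
    fwd = set(AG.starts)
    for s in AG.starts:
        fwd |= nx.descendants(G, s)
    if AG.target not in fwd:
        raise UnreachablePeakError(
            f"{AG.landscape.tf_name}: global peak unreachable from every start")
    bwd = nx.ancestors(G, AG.target) | {AG.target}
    return [(u, v, d["mclass"]) for u, v, d in G.edges(data=True)
            if u in fwd and u in bwd and v in bwd]


def path_composition_bias(AG: AccessibleGraph, semantics: str = "edge_set") -> BiasValue:
    """Composition bias of accessible mutational paths to the global peak.

    edge_set semantics counts each edge that lies on at least one start->peak
    path once. path_weighted semantics weights edges by their expected number
    of traversals under the unbiased (alpha = 0.5) origin-fixation chain,
    conditioned on absorption at the global peak with a uniform start mixture;
    the two agree exactly on single-path graphs.
    """
    if semantics == "edge_set":
        edges = _path_edges(AG)
        ti = sum(1 for _, _, cls in edges if cls == TRANSITION)
        tv = len(edges) - ti
        return bias(ti, tv)
    if semantics == "path_weighted":
        from .origin_fixation import build_matrix, conditioned_chain

        L = AG.landscape
        M = build_matrix(L, alpha=0.5, use_delta=(AG.mode == "strict"))
        start_idx = [L.index[s] for s in AG.starts]
        w, Pt, visits = conditioned_chain(M, start_idx)
        ti = tv = 0.0
        for i, row in Pt.items():
            for j, p in row.items():
                cls = L.edge_class[(i, j)]
                flux = visits[i] * p
                if cls == TRANSITION:
                    ti += flux
                else:
                    tv += flux
        return bias(ti, tv)
    raise ValueError(f"unknown semantics {semantics!r}")


def step_gain_by_class(AG: AccessibleGraph) -> pd.DataFrame:
    """Affinity gain of accessible steps, by mutation class and distance to peak.

    For each edge u -> v on a start->peak path, records the percentage affinity
    increase 100*(b_v - b_u)/b_u together with the mutation class and the
    mutational distance of u to the global peak along accessible paths.
    Strict accessible graphs only (gains are then all positive).
    """
    if AG.mode != "strict":
        raise ValueError("step gains are defined on the strict accessible graph")
    L = AG.landscape
    try:
        edges = _path_edges(AG)
    except UnreachablePeakError:
        return pd.DataFrame(columns=["distance", "mclass", "gain_pct"])
    # distance to peak measured backwards along accessible edges
    dist = nx.shortest_path_length(AG.graph.reverse(copy=False), source=AG.target)
    rows = [
        {"distance": dist[u], "mclass": cls,
         "gain_pct": 100.0 * (L.score_of(v) - L.score_of(u)) / L.score_of(u)}
        for u, v, cls in edges if u in dist
    ]
    return pd.DataFrame(rows, columns=["distance", "mclass", "gain_pct"])
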