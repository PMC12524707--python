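"""Hub ranking by a six-metric topological centrality ensemble.

Nodes of an interaction network (edges already thresholded on
confidence, treated as unweighted) are scored by Degree, Maximal Clique
Centrality (MCC), Maximum Neighborhood Component (MNC), Edge Percolation
Component (EPC), harmonic Closeness and Radiality.  Per metric, nodes
are ranked descending with average ranks on ties; the composite
centrality score is the arithmetic mean of the six ranks (lower = more
central).  Hub genes are the best-scoring members of a candidate list
(the GMT-associated module intersected with up-regulated genes).

Metric definitions:

* Degree(v): number of neighbors.
* MCC(v): sum over maximal cliques C containing v of (|C|-1)!
  (Bron-Kerbosch with pivoting); 0 for isolated nodes.
* MNC(v): size of the largest connected component of the subgraph
  induced by the open neighborhood N(v).
* EPC(v): mean over seeded Bernoulli edge-retention trials (retain
  probability ``epc_retain``) of the fraction of other nodes reachable
  from v.  With retain=1 this is exactly fractional reachability.
* Closeness(v): harmonic sum of 1/d(v, w); unreachable nodes contribute 0.
* Radiality(v): (1/(n-1)) * sum over reachable w of (diam_c + 1 - d(v,w)),
  with diam_c the diameter of v's connected component.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import InteractionGraph

logger = logging.getLogger(__name__)

__all__ = [
    "compute_centralities",
    "composite_rank",
    "select_hubs",
    "build_compound_network",
]

METRICS = ["degree", "mcc", "mnc", "epc", "closeness", "radiality"]


def _mcc(g: nx.Graph) -> dict:
    scores = {v: 0.0 for v in g.nodes}
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    return scores


def _mnc(g: nx.Graph) -> dict:
    scores = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        if not nbrs:
            scores[v] = 0.0
            continue
        sub = g.subgraph(nbrs)
        scores[v] = float(max(len(c) for c in nx.connected_components(sub)))
    return scores


def _epc(g: nx.Graph, trials: int, retain: float, rng: np.random.Generator) -> dict:
    n = g.number_of_nodes()
    nodes = list(g.nodes)
    totals = {v: 0.0 for v in nodes}
    if n < 2:
        return totals
    edges = list(g.edges)
    for _ in range(trials):
        if retain >= 1.0:
            kept = edges
        else:
            mask = rng.random(len(edges)) < retain
            kept = [e for e, m in zip(edges, mask) if m]
        h = nx.Graph()
        h.add_nodes_from(nodes)
        h.add_edges_from(kept)
        for comp in nx.connected_components(h):
            share = (len(comp) - 1) / (n - 1)
            for v in comp:
                totals[v] += share
    return {v: t / trials for v, t in totals.items()}


def _closeness_radiality(g: nx.Graph) -> tuple[dict, dict]:
    n = g.number_of_nodes()
    closeness = {v: 0.0 for v in g.nodes}
    radiality = {v: 0.0 for v in g.nodes}
    if n < 2:
        return closeness, radiality
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) == 1:
            continue
        sp = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(d for row in sp.values() for d in row.values())
        for v in comp:
            dists = [d for w, d in sp[v].items() if w != v]
            closeness[v] = float(sum(1.0 / d for d in dists))
            radiality[v] = float(sum(diam + 1 - d for d in dists)) / (n - 1)
    return closeness, radiality


def compute_centralities(
    ig: InteractionGraph,
    epc_trials: int = 1000,
    epc_retain: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """All six centrality metrics per node, plus per-metric ranks and the score.

    Returns a frame indexed by node with the metric columns, rank columns
    (``rank_<metric>``, descending with average ties) and ``score`` =
    mean of the six ranks.
    """
    g = ig.graph
    if g.number_of_nodes() < 2:
        raise ValueError("graph needs >=2 nodes")
    rng = np.random.default_rng(seed)
    closeness, radiality = _closeness_radiality(g)
    table = pd.DataFrame(
        {
            "degree": {v: float(d) for v, d in g.degree()},
            "mcc": _mcc(g),
            "mnc": _mnc(g),
            "epc": _epc(g, epc_trials, epc_retain, rng),
            "closeness": closeness,
            "radiality": radiality,
        }
    )
    table = table.loc[sorted(table.index, key=str)]
    for metric in METRICS:
        table[f"rank_{metric}"] = rankdata(-table[metric].to_numpy(), method="average")
    table["score"] = table[[f"rank_{m}" for m in METRICS]].mean(axis=1)
    table.index.name = "node"
    return table


def composite_rank(table: pd.DataFrame) -> list[str]:
    """Nodes sorted by composite centrality score ascending, ties by node id."""
    order = np.lexsort((table.index.to_numpy(), table["score"].to_numpy()))
    return list(table.index[order])


def select_hubs(table: pd.DataFrame, candidate_genes, k: int) -> list[str]:
    """The k best-scoring nodes among the candidates (deterministic order).

    Candidates absent from the graph are dropped with a warning; if fewer
    than k remain, all of them are returned (with a warning).
    """
    candidates = [str(c).upper() for c in candidate_genes]
    present = [c for c in candidates if c in table.index]
    missing = sorted(set(candidates) - set(present))
    if missing:
        logger.warning("%d candidate genes not in graph: %s", len(missing), missing[:10])
    if not present:
        return []
    sub = table.loc[present]
    ranked = composite_rank(sub)
    if k > len(ranked):
        logger.warning("requested %d hubs but only %d candidates in graph", k, len(ranked))
        return ranked
    return ranked[:k]


def build_compound_network(
    compound_edges: InteractionGraph,
    gene_graph: InteractionGraph,
    hub_genes,
) -> InteractionGraph:
    """Union chemical-protein-gene network for ranking compounds among hubs.

    Keeps every compound node (tagged ``compound``) with its surviving
    compound-target edges, the hub genes and the gene-gene edges among
    hubs and targets.  Compounds whose every edge fell below the
    confidence threshold remain as isolated nodes.
    """
    hubs = {str(h).upper() for h in hub_genes}
    g = nx.Graph()
    compounds = [v for v, kind in compound_edges.graph.nodes(data="kind") if kind == "compound"]
    g.add_nodes_from(compounds, kind="compound")
    for u, v, conf in compound_edges.graph.edges(data="confidence"):
        g.add_edge(u, v, confidence=conf)
    for v in g.nodes:
        if g.nodes[v].get("kind") is None:
            g.nodes[v]["kind"] = "protein"
    g.add_nodes_from(hubs, kind="gene")
    keep = set(g.nodes) | hubs
    for u, v, conf in gene_graph.graph.edges(data="confidence"):
        if u in keep and v in keep:
            g.add_edge(u, v, confidence=conf)
            for w in (u, v):
                if g.nodes[w].get("kind") is None:
                    g.nodes[w]["kind"] = "gene"
    return InteractionGraph(g)
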