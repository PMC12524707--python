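"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and written without the package's
own helpers (and, for the graph oracles, without networkx): literal
loops over the mathematical definitions.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize_scalar


# ---------------------------------------------------------------------------
# ssGSEA running sum
# ---------------------------------------------------------------------------


def ssgsea_es_brute(values: dict[str, float], genes: set[str], alpha: float) -> float:
    order = sorted(values, key=lambda g: (-values[g], g))
    n = len(order)
    weights = {g: (n - i) ** alpha for i, g in enumerate(order)}  # position i+1
    sum_in = sum(weights[g] for g in order if g in genes)
    n_out = n - sum(1 for g in order if g in genes)
    es = 0.0
    cum_in = 0.0
    cum_out = 0
    for g in order:
        if g in genes:
            cum_in += weights[g]
        else:
            cum_out += 1
        es += cum_in / sum_in - cum_out / n_out
    return es


# ---------------------------------------------------------------------------
# topological overlap
# ---------------------------------------------------------------------------


def tom_brute(X: np.ndarray, beta: float) -> np.ndarray:
    n = X.shape[0]
    a = np.abs(np.corrcoef(X)) ** beta
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


# ---------------------------------------------------------------------------
# graph centralities (pure python, adjacency sets)
# ---------------------------------------------------------------------------


def _bfs_dist(adj: dict, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _components(adj: dict):
    seen = set()
    for v in adj:
        if v in seen:
            continue
        comp = set(_bfs_dist(adj, v))
        seen |= comp
        yield comp


def centralities_brute(nodes, edges):
    """All six metrics by literal definition; EPC as exact reachability (retain=1)."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    n = len(nodes)

    degree = {v: float(len(adj[v])) for v in nodes}

    # maximal cliques by subset enumeration
    mcc = {v: 0.0 for v in nodes}
    node_list = list(nodes)
    for r in range(2, n + 1):
        for subset in itertools.combinations(node_list, r):
            s = set(subset)
            if not all(b in adj[a] for a, b in itertools.combinations(subset, 2)):
                continue
            if any(all(w in adj[u] for u in s) for w in nodes if w not in s):
                continue  # extendable: not maximal
            for v in subset:
                mcc[v] += math.factorial(r - 1)

    mnc = {}
    for v in nodes:
        nbrs = adj[v]
        if not nbrs:
            mnc[v] = 0.0
            continue
        sub = {u: adj[u] & nbrs for u in nbrs}
        mnc[v] = float(max(len(c) for c in _components(sub)))

    closeness = {}
    radiality = {}
    comps = list(_components(adj))
    diam_of = {}
    for comp in comps:
        diam = 0
        for v in comp:
            d = _bfs_dist({u: adj[u] for u in comp}, v)
            diam = max(diam, max(d.values()))
        for v in comp:
            diam_of[v] = diam
    for v in nodes:
        d = _bfs_dist(adj, v)
        others = {w: dd for w, dd in d.items() if w != v}
        closeness[v] = sum(1.0 / dd for dd in others.values())
        radiality[v] = (
            sum(diam_of[v] + 1 - dd for dd in others.values()) / (n - 1) if n > 1 else 0.0
        )

    epc = {}
    for v in nodes:
        epc[v] = (len(_bfs_dist(adj, v)) - 1) / (n - 1) if n > 1 else 0.0

    return {
        "degree": degree, "mcc": mcc, "mnc": mnc, "epc": epc,
        "closeness": closeness, "radiality": radiality,
    }


def epc_exact(nodes, edges, retain: float):
    """Exact expected reachability fraction by enumerating all edge subsets."""
    nodes = list(nodes)
    edges = list(edges)
    n = len(nodes)
    out = {v: 0.0 for v in nodes}
    for kept_mask in itertools.product([False, True], repeat=len(edges)):
        prob = 1.0
        adj = {v: set() for v in nodes}
        for (u, v), kept in zip(edges, kept_mask):
            prob *= retain if kept else (1 - retain)
            if kept:
                adj[u].add(v)
                adj[v].add(u)
        for v in nodes:
            out[v] += prob * (len(_bfs_dist(adj, v)) - 1) / (n - 1)
    return out


# ---------------------------------------------------------------------------
# Cox partial likelihood (Efron ties) + 1-d maximizer
# ---------------------------------------------------------------------------


def cox_efron_loglik(time, event, x, beta: float) -> float:
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    theta = np.exp(beta * x)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        at_risk = time >= t
        d = int(dead.sum())
        sum_dead_x = x[dead].sum()
        sum_risk = theta[at_risk].sum()
        sum_dead = theta[dead].sum()
        ll += beta * sum_dead_x
        for j in range(d):
            ll -= np.log(sum_risk - (j / d) * sum_dead)
    return ll


def cox_beta_brute(time, event, x) -> float:
    res = minimize_scalar(
        lambda b: -cox_efron_loglik(time, event, x, b), bounds=(-5, 5), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)
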