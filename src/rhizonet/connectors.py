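"""Degree-preserving null model and connector-taxon detection.

A connector taxon bridges otherwise separate network modules: it has
few links (low degree) but lies on many shortest paths (high
betweenness).  Statistical detection compares each node's observed
betweenness against its null distribution over Maslov-Sneppen
degree-preserving rewirings of the network, combined with percentile
criteria evaluated on the observed network itself:

* null criterion: observed betweenness exceeds the 95th percentile of
  the node's null sample (empirical p < 0.05);
* betweenness criterion: observed betweenness > 75th percentile of all
  observed betweenness values;
* degree criterion: degree < 25th percentile of all observed degrees.

All three must hold (strict inequalities; percentiles by linear
interpolation between order statistics).  Node labels are carried
through the rewiring — swaps move edges, never labels — so each node's
null distribution is well defined.  Betweenness is raw (unnormalised)
in both the observed and null graphs, computed on the unweighted
skeleton; edge signs play no role here.
"""

from __future__ import annotations

import warnings

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["betweenness", "maslov_sneppen", "detect_connectors"]


def betweenness(net: nx.Graph) -> dict:
    """Raw shortest-path betweenness for every node.

    Unordered pairs (s, t) are counted once, with fractional credit
    shared across equal-length shortest paths (Brandes accumulation).
    Disconnected graphs are fine: pairs in different components simply
    contribute no paths.  Computed through igraph's C implementation;
    the null model evaluates this thousands of times per network.
    """
    nodes = list(net.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    g = ig.Graph(
        n=len(nodes), edges=[(index[u], index[v]) for u, v in net.edges()]
    )
    values = g.betweenness(directed=False)
    return dict(zip(nodes, (float(b) for b in values)))


def maslov_sneppen(net: nx.Graph, swaps_per_edge: int = 10, seed=None) -> nx.Graph:
    """Randomise a graph by repeated degree-preserving double-edge swaps.

    Picks two edges (a, b), (c, d) and rewires to (a, d), (c, b),
    accepting only swaps that create neither self-loops nor parallel
    edges, until ``swaps_per_edge * E`` swaps have succeeded.  An
    attempt cap of 100x the swap budget guarantees termination on
    graphs whose degree sequence admits few rewirings (a triangle comes
    back unchanged).  Edge attributes are discarded: the null model is
    topology-only.
    """
    nodes = list(net.nodes())
    edges = [tuple(e) for e in net.edges()]
    n_edges = len(edges)
    if n_edges < 2:
        warnings.warn("graph has fewer than 2 edges; returned unchanged", stacklevel=2)
        out = nx.Graph()
        out.add_nodes_from(nodes)
        out.add_edges_from(edges)
        return out
    rng = np.random.default_rng(seed)
    target = int(swaps_per_edge) * n_edges
    max_attempts = 100 * target
    edge_set = {frozenset(e) for e in edges}
    successes = 0
    attempts = 0
    # draws are batched: the swap loop runs tens of thousands of times
    # inside the null model
    batch = max(1024, 4 * max(target, 1))
    draws = rng.integers(0, n_edges, size=(batch, 2))
    flips = rng.integers(0, 2, size=batch)
    cursor = 0
    while successes < target and attempts < max_attempts:
        if cursor >= batch:
            draws = rng.integers(0, n_edges, size=(batch, 2))
            flips = rng.integers(0, 2, size=batch)
            cursor = 0
        i, j = draws[cursor]
        flip = flips[cursor]
        cursor += 1
        attempts += 1
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip:
            c, d = d, c
        # proposed rewiring: (a, b), (c, d) -> (a, d), (c, b)
        if a == d or c == b:
            continue
        new1, new2 = frozenset((a, d)), frozenset((c, b))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = (a, d)
        edges[j] = (c, b)
        successes += 1
    out = nx.Graph()
    out.add_nodes_from(nodes)
    out.add_edges_from(edges)
    return out


def detect_connectors(
    net: nx.Graph,
    n_random: int = 1000,
    alpha: float = 0.05,
    seed=None,
    swaps_per_edge: int = 10,
) -> pd.DataFrame:
    """Statistical connector detection against a degree-preserving null.

    Returns one row per node with its degree, raw betweenness, the 95th
    percentile of its null betweenness sample, the empirical p-value
    (1 + #{B_null >= B_obs}) / (1 + n_random), the three boolean
    criteria and their conjunction ``is_connector``.
    """
    n = net.number_of_nodes()
    if n < 5:
        raise ValueError("connector detection requires at least 5 nodes")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    nodes = list(net.nodes())
    b_obs = betweenness(net)
    degrees = dict(net.degree())

    rng = np.random.default_rng(seed)
    null = np.empty((n_random, n))
    for r in range(n_random):
        randomized = maslov_sneppen(net, swaps_per_edge=swaps_per_edge, seed=rng)
        b_null = betweenness(randomized)
        null[r] = [b_null[v] for v in nodes]

    b_vec = np.array([b_obs[v] for v in nodes])
    k_vec = np.array([degrees[v] for v in nodes], dtype=float)
    q_null = np.percentile(null, 100 * (1 - alpha), axis=0)
    exceed = (null >= b_vec[None, :] - 1e-12).sum(axis=0)
    emp_p = (1 + exceed) / (1 + n_random)
    q75_b = np.percentile(b_vec, 75)
    q25_k = np.percentile(k_vec, 25)

    meets_null = b_vec > q_null
    meets_b = b_vec > q75_b
    meets_k = k_vec < q25_k
    report = pd.DataFrame(
        {
            "degree": k_vec.astype(int),
            "betweenness": b_vec,
            "null_betweenness_q95": q_null,
            "empirical_p": emp_p,
            "meets_null_criterion": meets_null,
            "meets_betweenness_criterion": meets_b,
            "meets_degree_criterion": meets_k,
            "is_connector": meets_null & meets_b & meets_k,
        },
        index=pd.Index(nodes, name="taxon"),
    )
    return report
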