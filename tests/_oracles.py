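"""Independent brute-force oracles used across the test suite.

Each function re-derives a quantity from first principles (explicit
enumeration or the textbook formula written the long way) so the
package implementations are checked against a second, independent
route.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
from scipy import stats


# -- alpha diversity --------------------------------------------------------

def brute_alpha(counts: np.ndarray) -> dict:
    counts = np.asarray(counts, dtype=int)
    nz = counts[counts > 0]
    n = int(nz.sum())
    s = len(nz)
    f1 = int((nz == 1).sum())
    f2 = int((nz == 2).sum())
    p = nz / n
    h = -sum(pi * math.log(pi) for pi in p)
    out = {
        "sobs": s,
        "shannon": h,
        "pielou": 1.0 if s == 1 else h / math.log(s),
        "simpson": 1.0 if n == 1 else sum(int(x) * (int(x) - 1) for x in nz) / (n * (n - 1)),
        "coverage": 1 - f1 / n,
        "chao1": s + f1 * (f1 - 1) / (2 * (f2 + 1)),
    }
    return out


def brute_ace(counts: np.ndarray, cutoff: int = 10) -> float:
    nz = np.asarray(counts, dtype=int)
    nz = nz[nz > 0]
    rare = nz[nz <= cutoff]
    abund = nz[nz > cutoff]
    if len(rare) == 0:
        return float(len(abund))
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c = 1 - f1 / n_rare
    if c == 0:
        return brute_alpha(counts)["chao1"]
    num = sum(k * (k - 1) * int((rare == k).sum()) for k in range(1, cutoff + 1))
    g2 = max((len(rare) / c) * num / (n_rare * (n_rare - 1)) - 1, 0.0)
    return len(abund) + len(rare) / c + (f1 / c) * g2


# -- correlation ------------------------------------------------------------

def brute_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of mid-rank transformed vectors."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def brute_bh(p: np.ndarray) -> np.ndarray:
    """Classic step-up BH written the slow, obvious way."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for pos in range(m - 1, -1, -1):
        k = pos + 1
        val = min(prev, p[order[pos]] * m / k)
        adj[order[pos]] = val
        prev = val
    return np.minimum(adj, 1.0)


# -- graphs -----------------------------------------------------------------

def brute_betweenness(G: nx.Graph) -> dict:
    """Exhaustive shortest-path enumeration, one count per unordered pair."""
    b = {v: 0.0 for v in G.nodes()}
    for s, t in itertools.combinations(G.nodes(), 2):
        if not nx.has_path(G, s, t):
            continue
        paths = list(nx.all_shortest_paths(G, s, t))
        for path in paths:
            for v in path[1:-1]:
                b[v] += 1.0 / len(paths)
    return b


# -- permutation tests ------------------------------------------------------

def brute_permanova_f(D: np.ndarray, labels) -> float:
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    groups = sorted(set(labels), key=str)
    a = len(groups)
    ss_t = sum(D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_w += sum(
            D[i, j] ** 2 for qi, i in enumerate(idx) for j in idx[qi + 1 :]
        ) / len(idx)
    ss_a = ss_t - ss_w
    return (ss_a / (a - 1)) / (ss_w / (n - a))


def brute_anosim_r(D: np.ndarray, labels) -> float:
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    dists = np.array([D[i, j] for i, j in pairs])
    ranks = stats.rankdata(dists)
    within = np.array([labels[i] == labels[j] for i, j in pairs])
    m = len(pairs)
    return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2))


def brute_unifrac(newick: str, a: set, b: set) -> float:
    """Branch tally on a parsed tree, denominator = total length below
    the LCA of all present taxa."""
    from skbio import TreeNode

    tree = TreeNode.read([newick])
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    union = set(a) | set(b)
    lca = tree.lca(sorted(union))
    unique = total = 0.0
    for node in lca.traverse(include_self=False):
        tips = {t.name for t in node.tips(include_self=True)}
        in_a, in_b = bool(tips & a), bool(tips & b)
        total += node.length
        if in_a != in_b:
            unique += node.length
    return unique / total if total else 0.0


# -- rank statistics --------------------------------------------------------

def brute_kruskal_h(values_by_group: dict) -> float:
    pooled = np.concatenate([np.asarray(v, float) for v in values_by_group.values()])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for v in values_by_group.values():
        k = len(v)
        r = ranks[start : start + k]
        start += k
        h += k * (r.mean() - (n + 1) / 2) ** 2
    h *= 12 / (n * (n + 1))
    _, t = np.unique(pooled, return_counts=True)
    return h / (1 - ((t**3 - t).sum()) / (n**3 - n))


def brute_dunn_z(values_by_group: dict, g1, g2) -> float:
    pooled = np.concatenate([np.asarray(v, float) for v in values_by_group.values()])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    sizes = {}
    start = 0
    for g, v in values_by_group.items():
        k = len(v)
        mean_ranks[g] = ranks[start : start + k].mean()
        sizes[g] = k
        start += k
    _, t = np.unique(pooled, return_counts=True)
    ties = float((t**3 - t).sum())
    var = n * (n + 1) / 12 - ties / (12 * (n - 1))
    return (mean_ranks[g1] - mean_ranks[g2]) / math.sqrt(
        var * (1 / sizes[g1] + 1 / sizes[g2])
    )
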