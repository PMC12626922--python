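"""Between-sample dissimilarities, ordination and permutation tests.

Covers the beta-diversity stage of the pipeline: the abundance-weighted
Jaccard (Ruzicka) index for fungal communities, unweighted UniFrac on a
rooted phylogeny for bacterial communities, principal coordinates
analysis, and PERMANOVA / ANOSIM permutation tests with the add-one
p-value convention (p is never 0 and never below 1/(n_perm+1)).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix, TreeNode

from .io import FeatureTable

__all__ = [
    "abund_jaccard",
    "unweighted_unifrac",
    "distance_matrix",
    "pcoa",
    "permanova",
    "anosim",
    "OrdinationResult",
    "PermutationTestResult",
]


# ---------------------------------------------------------------------------
# dissimilarities
# ---------------------------------------------------------------------------

def abund_jaccard(x, y, variant: str = "ruzicka") -> float:
    """Abundance-weighted Jaccard dissimilarity between two samples.

    The default ``ruzicka`` variant is 1 - sum(min)/sum(max), a direct
    quantitative generalisation of Jaccard.  ``chao`` gives the
    Chao-Chazdon probabilistic abundance-based Jaccard estimator, which
    corrects for unseen shared species.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("both vectors are all-zero")
    if variant == "ruzicka":
        return float(1.0 - np.minimum(x, y).sum() / np.maximum(x, y).sum())
    if variant == "chao":
        return _chao_jaccard(x, y)
    raise ValueError(f"unknown variant: {variant!r}")


def _chao_jaccard(x: np.ndarray, y: np.ndarray) -> float:
    shared = (x > 0) & (y > 0)
    if not shared.any():
        return 1.0
    n, m = x.sum(), y.sum()

    def u_hat(a, b, na, nb):
        # probability mass of a's shared species, corrected for unseen ones
        f1 = int(((b[shared] == 1)).sum())
        f2 = int(((b[shared] == 2)).sum())
        base = (a[shared] / na).sum()
        corr = ((nb - 1) / nb) * (f1 / (2.0 * max(f2, 1))) * (
            (a[shared] / na * (b[shared] == 1)).sum()
        )
        return min(base + corr, 1.0)

    u = u_hat(x, y, n, m)
    v = u_hat(y, x, m, n)
    if u == 0 or v == 0:
        return 1.0
    return float(1.0 - (u * v) / (u + v - u * v))


def unweighted_unifrac(tree: TreeNode, a, b, mode: str = "strict") -> float:
    """Unweighted UniFrac between two presence sets on a rooted tree.

    Numerator: branch length covered by exactly one of the two samples
    (a branch is covered by a sample when any descendant tip is present
    in it).  Denominator: the total branch length below the lowest common
    ancestor of all present taxa, so branches above that LCA never
    contribute.  ``mode='lenient'`` prunes taxa missing from the tree
    with a warning instead of raising.
    """
    a, b = set(a), set(b)
    tips = {t.name for t in tree.tips()}
    missing = (a | b) - tips
    if missing:
        if mode == "strict":
            raise ValueError(f"taxa absent from tree: {sorted(missing)}")
        warnings.warn(f"pruning taxa absent from tree: {sorted(missing)}", stacklevel=2)
        a -= missing
        b -= missing
    if not a or not b:
        raise ValueError("both presence sets must be non-empty")
    union = a | b
    if a == b:
        return 0.0
    if len(union) == 1:
        return 0.0
    lca = tree.lca(sorted(union))
    covered_a: dict[int, bool] = {}
    covered_b: dict[int, bool] = {}
    unique = 0.0
    total = 0.0
    for node in lca.postorder(include_self=False):
        if node.is_tip():
            in_a, in_b = node.name in a, node.name in b
        else:
            in_a = any(covered_a[id(c)] for c in node.children)
            in_b = any(covered_b[id(c)] for c in node.children)
        covered_a[id(node)] = in_a
        covered_b[id(node)] = in_b
        length = node.length or 0.0
        total += length
        if in_a != in_b:
            unique += length
    if total == 0:
        return 0.0
    return unique / total


def distance_matrix(
    table: FeatureTable,
    metric: str = "abund_jaccard",
    tree: TreeNode | None = None,
    **kwargs,
) -> DistanceMatrix:
    """All-pairs sample dissimilarity matrix for a feature table.

    ``metric`` is ``abund_jaccard`` (on the count vectors as given) or
    ``unifrac`` (unweighted, on presence/absence; requires ``tree``).
    """
    ids = table.sample_ids
    counts = table.counts
    n = len(ids)
    D = np.zeros((n, n))
    if metric == "unifrac":
        if tree is None:
            raise ValueError("unifrac requires a rooted tree")
        sets = [
            {t for t, c in zip(table.taxon_ids, row) if c > 0} for row in counts
        ]
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = unweighted_unifrac(tree, sets[i], sets[j], **kwargs)
    elif metric == "abund_jaccard":
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = abund_jaccard(counts[i], counts[j], **kwargs)
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    return DistanceMatrix(D, ids)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """PCoA embedding: coordinates on positive-eigenvalue axes.

    ``eigenvalues`` holds the full descending spectrum of the
    double-centered matrix, negative values included (no Cailliez or
    Lingoes correction); ``proportion_explained`` is computed over the
    positive eigenvalues only.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Eigendecomposition of the Gower-centered matrix -1/2 J D^2 J; axes
    are ordered by descending eigenvalue and only positive-eigenvalue
    axes receive coordinates.
    """
    D = dm.data
    n = D.shape[0]
    if n < 3:
        raise ValueError("PCoA requires at least 3 samples")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(1.0, abs(eigvals[0]))
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    axes = [f"PC{i + 1}" for i in range(int(positive.sum()))]
    prop = eigvals[positive] / eigvals[positive].sum()
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

@dataclass
class PermutationTestResult:
    method: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: object = None


def _check_groups(dm: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, pd.Series):
        groups = groups.loc[list(dm.ids)]
    labels = np.asarray(groups, dtype=object)
    if labels.shape[0] != len(dm.ids):
        raise ValueError("groups length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"singleton groups: {small}")
    return labels


def _permanova_f(D2: np.ndarray, perms: np.ndarray, uniq: np.ndarray) -> np.ndarray:
    """Pseudo-F for each row of permuted labels (vectorised).

    SS_T = sum_{i<j} d_ij^2 / N; SS_W = sum_g sum_{i<j in g} d_ij^2 / n_g;
    F = (SS_A/(a-1)) / (SS_W/(N-a)).
    """
    n = D2.shape[0]
    a = uniq.size
    ss_t = D2.sum() / (2.0 * n)
    ss_w = np.zeros(perms.shape[0])
    for g in uniq:
        ind = (perms == g).astype(float)
        n_g = ind[0].sum()
        ss_w += np.einsum("pi,ij,pj->p", ind, D2, ind) / (2.0 * n_g)
    ss_a = ss_t - ss_w
    return (ss_a / (a - 1)) / (ss_w / (n - a))


def permanova(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed=None,
    exhaustive: bool = False,
) -> PermutationTestResult:
    """One-way PERMANOVA on a distance matrix.

    Permutations shuffle group labels over samples; p uses the add-one
    convention (1 + #{F_perm >= F_obs}) / (1 + n_perm).  With
    ``exhaustive=True`` all N! label orders are enumerated (N <= 9) and
    p is the exact fraction of orders with F >= F_obs.
    """
    labels = _check_groups(dm, groups)
    D2 = dm.data**2
    if not np.any(D2):
        raise ValueError("degenerate all-zero distance matrix")
    uniq = np.unique(labels)
    f_obs = float(_permanova_f(D2, labels[None, :], uniq)[0])
    n = labels.size
    if exhaustive:
        if n > 9:
            raise ValueError("exhaustive enumeration limited to 9 samples")
        perms = np.array(
            [labels[list(p)] for p in itertools.permutations(range(n))], dtype=object
        )
        f_perm = _permanova_f(D2, perms, uniq)
        p = float((f_perm >= f_obs - 1e-12).mean())
        return PermutationTestResult("permanova", f_obs, p, math.factorial(n), seed)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(labels) for _ in range(n_perm)], dtype=object)
    f_perm = _permanova_f(D2, perms, uniq)
    p = (1 + int((f_perm >= f_obs - 1e-12).sum())) / (1 + n_perm)
    return PermutationTestResult("permanova", f_obs, p, n_perm, seed)


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> np.ndarray:
    """ANOSIM R for each row of a boolean within-group pair mask."""
    m = ranks.size
    n_w = within.sum(axis=1)
    n_b = m - n_w
    r_w = (ranks[None, :] * within).sum(axis=1) / n_w
    r_b = (ranks[None, :] * ~within).sum(axis=1) / n_b
    return (r_b - r_w) / (m / 2.0)


def anosim(
    dm: DistanceMatrix, groups, n_perm: int = 999, seed=None
) -> PermutationTestResult:
    """ANOSIM: rank-based test of between- vs within-group distances.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairs; ties get average ranks.  Permutation p as in
    :func:`permanova`.
    """
    labels = _check_groups(dm, groups)
    condensed = squareform(dm.data, checks=False)
    ranks = rankdata(condensed)
    n = labels.size
    iu, ju = np.triu_indices(n, k=1)
    r_obs = float(_anosim_r(ranks, (labels[iu] == labels[ju])[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(labels) for _ in range(n_perm)], dtype=object)
    within = perms[:, iu] == perms[:, ju]
    r_perm = _anosim_r(ranks, within)
    p = (1 + int((r_perm >= r_obs - 1e-12).sum())) / (1 + n_perm)
    return PermutationTestResult("anosim", r_obs, p, n_perm, seed)
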