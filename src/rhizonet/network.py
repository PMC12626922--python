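"""Taxon co-occurrence networks from Spearman correlations.

The pipeline here is the one used for whole-study and per-treatment
microbial networks: aggregate ASVs to genus, keep the most abundant
genera, correlate relative abundances with Spearman's rho, control the
false-discovery rate over all taxon pairs with Benjamini-Hochberg, and
keep edges with |rho| >= 0.6 and adjusted p < 0.05.  Edges carry rho,
the adjusted p-value and a sign; topology summaries report graph density
and the positive-edge fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable, SampleMetadata, TaxonomyMap

__all__ = [
    "aggregate_to_genus",
    "top_taxa",
    "spearman_matrix",
    "bh_adjust",
    "build_network",
    "topology",
    "per_group_networks",
    "CorrelationResult",
    "TopologySummary",
]


# ---------------------------------------------------------------------------
# table preparation
# ---------------------------------------------------------------------------

def aggregate_to_genus(
    table: FeatureTable,
    taxonomy: TaxonomyMap,
    rank: str = "genus",
    strict: bool = True,
) -> FeatureTable:
    """Sum ASV counts into genus-level (or other rank) groups.

    ASVs unassigned at ``rank`` pool under ``unclassified_<name>`` where
    ``<name>`` is their deepest resolved coarser rank.  Total counts are
    conserved exactly.  Missing taxonomy entries raise in strict mode and
    pool under ``unassigned`` otherwise.
    """
    labels = []
    for taxon in table.taxon_ids:
        if taxon not in taxonomy:
            if strict:
                raise KeyError(f"taxon {taxon!r} missing from taxonomy")
            labels.append("unassigned")
        else:
            labels.append(taxonomy.label_at(taxon, rank))
    grouped = table.data.T.groupby(pd.Series(labels, index=table.taxon_ids)).sum().T
    return FeatureTable(grouped)


def top_taxa(table: FeatureTable, n: int) -> FeatureTable:
    """Keep the ``n`` taxa with highest mean relative abundance.

    Ties at the boundary break lexicographically by taxon id (smaller id
    kept).  The subset retains original counts and column order.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > table.n_taxa:
        raise ValueError(f"n={n} exceeds number of taxa ({table.n_taxa})")
    mean_rel = table.relative_abundance().mean(axis=0)
    ranking = sorted(table.taxon_ids, key=lambda t: (-mean_rel[t], t))
    keep = set(ranking[:n])
    ordered = [t for t in table.taxon_ids if t in keep]
    return table.select_taxa(ordered)


# ---------------------------------------------------------------------------
# correlation + FDR
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """All-pairs Spearman correlations with BH-adjusted p-values.

    ``rho``, ``p`` and ``p_adj`` are symmetric DataFrames over
    ``taxon_ids``; entries involving zero-variance (constant) taxa are
    NaN and the diagonal is excluded from the adjustment family.
    """

    taxon_ids: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    n_samples: int
    constant_taxa: list[str] = field(default_factory=list)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Returns adjusted p-values in the original order: p_(k) * m / k with a
    cumulative minimum from the largest p down, clipped at 1.  NaN
    entries are excluded from the family and returned as NaN.
    """
    arr = np.asarray(p_values, dtype=float)
    flat = arr.ravel()
    mask = ~np.isnan(flat)
    vals = flat[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    out = np.full(flat.shape, np.nan)
    if m:
        order = np.argsort(vals, kind="mergesort")
        ranked = vals[order] * m / np.arange(1, m + 1)
        adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
        adjusted = np.minimum(adjusted, 1.0)
        restored = np.empty(m)
        restored[order] = adjusted
        out[mask] = restored
    return out.reshape(arr.shape)


def spearman_matrix(relative_abundances: pd.DataFrame | FeatureTable) -> CorrelationResult:
    """Spearman correlation matrix over taxa with BH-corrected p-values.

    rho is the Pearson correlation of mid-rank (average-rank) transformed
    columns; two-sided p comes from the t approximation with n-2 degrees
    of freedom.  |rho| = 1 yields p = 0 (the t statistic is infinite);
    see the methods note for the caveat.  The BH family is the upper
    triangle of defined pairs only.  Constant taxa get NaN rows/columns
    and are listed in ``constant_taxa``.
    """
    if isinstance(relative_abundances, FeatureTable):
        relative_abundances = relative_abundances.relative_abundance()
    df = relative_abundances
    n, k = df.shape
    if n < 4:
        raise ValueError("Spearman networks require at least 4 samples")
    values = df.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 0, values)
    centered = ranks - ranks.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    unit = centered / safe
    rho = unit.T @ unit
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))
    rho = np.clip(rho, -1.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, np.nan)

    iu = np.triu_indices(k, k=1)
    p_adj = np.full((k, k), np.nan)
    adj_upper = bh_adjust(p[iu])
    p_adj[iu] = adj_upper
    p_adj.T[iu] = adj_upper

    taxa = list(df.columns)
    return CorrelationResult(
        taxon_ids=taxa,
        rho=pd.DataFrame(rho, index=taxa, columns=taxa),
        p=pd.DataFrame(p, index=taxa, columns=taxa),
        p_adj=pd.DataFrame(p_adj, index=taxa, columns=taxa),
        n_samples=n,
        constant_taxa=[t_ for t_, c in zip(taxa, constant) if c],
    )


# ---------------------------------------------------------------------------
# network construction and topology
# ---------------------------------------------------------------------------

def build_network(
    corr: CorrelationResult,
    rho_min: float = 0.6,
    alpha: float = 0.05,
    inclusive: bool = True,
    use_adjusted: bool = True,
    keep_constant: bool = False,
    taxonomy: TaxonomyMap | None = None,
) -> nx.Graph:
    """Threshold a correlation matrix into an undirected signed network.

    Edge (i, j) exists iff |rho_ij| >= ``rho_min`` (strict > with
    ``inclusive=False``) and the (BH-adjusted by default) p-value is
    below ``alpha``.  Zero-variance taxa are dropped unless
    ``keep_constant`` retains them as isolated nodes.  If ``taxonomy``
    is given, nodes are annotated with their phylum.
    """
    if not 0 <= rho_min <= 1:
        raise ValueError("rho_min must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    net = nx.Graph()
    nodes = list(corr.taxon_ids)
    if not keep_constant:
        nodes = [t for t in nodes if t not in set(corr.constant_taxa)]
    for t in nodes:
        attrs = {}
        if taxonomy is not None and t in taxonomy:
            phylum = taxonomy.lineage(t).get("phylum")
            if phylum:
                attrs["phylum"] = phylum
        net.add_node(t, **attrs)
    rho = corr.rho.to_numpy()
    pmat = (corr.p_adj if use_adjusted else corr.p).to_numpy()
    index = {t: i for i, t in enumerate(corr.taxon_ids)}
    for a_i, u in enumerate(nodes):
        for v in nodes[a_i + 1 :]:
            i, j = index[u], index[v]
            r = rho[i, j]
            pv = pmat[i, j]
            if np.isnan(r) or np.isnan(pv):
                continue
            strong = abs(r) >= rho_min if inclusive else abs(r) > rho_min
            if strong and pv < alpha:
                net.add_edge(u, v, rho=float(r), p_adj=float(pv), sign="+" if r > 0 else "-")
    return net


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    graph_density: float
    positive_edge_fraction: float
    negative_edge_fraction: float
    mean_degree: float
    degree_sequence: list[int]


def topology(net: nx.Graph) -> TopologySummary:
    """Node/edge counts, density 2E/(N(N-1)) and signed-edge fractions.

    The positive fraction is 0 for an edgeless graph by convention; an
    edge counts as positive when its ``sign`` attribute is ``'+'`` (or,
    lacking the attribute, when rho > 0).
    """
    n = net.number_of_nodes()
    e = net.number_of_edges()
    density = 2.0 * e / (n * (n - 1)) if n >= 2 else 0.0
    pos = sum(
        1
        for _, _, d in net.edges(data=True)
        if d.get("sign", "+" if d.get("rho", 0) > 0 else "-") == "+"
    )
    pos_frac = pos / e if e else 0.0
    degrees = sorted((d for _, d in net.degree()), reverse=True)
    mean_deg = 2.0 * e / n if n else 0.0
    return TopologySummary(
        n_nodes=n,
        n_edges=e,
        graph_density=density,
        positive_edge_fraction=pos_frac,
        negative_edge_fraction=(1.0 - pos_frac) if e else 0.0,
        mean_degree=mean_deg,
        degree_sequence=degrees,
    )


def per_group_networks(
    table: FeatureTable,
    metadata: SampleMetadata,
    top_n: int = 100,
    rho_min: float = 0.6,
    alpha: float = 0.05,
    min_samples: int = 4,
    taxonomy: TaxonomyMap | None = None,
    **network_kwargs,
) -> dict[str, tuple[nx.Graph, TopologySummary]]:
    """Independent co-occurrence network per treatment group.

    Runs top_taxa -> Spearman -> BH -> thresholding -> topology on each
    group's samples separately.  Spearman p-values over fewer than 4
    samples are meaningless, so groups below ``min_samples`` raise; note
    that a 3-replicate design therefore needs either pooling or a
    relaxed ``min_samples`` with the caveat documented.
    """
    results: dict[str, tuple[nx.Graph, TopologySummary]] = {}
    for group in metadata.group_labels:
        samples = metadata.samples_in(group)
        if len(samples) == 0:
            raise ValueError(f"group {group!r} has no samples")
        if len(samples) < min_samples:
            raise ValueError(
                f"group {group!r} has {len(samples)} samples; "
                f"need at least {min_samples} for per-group correlation"
            )
        sub = table.select_samples(samples)
        sub = top_taxa(sub, min(top_n, sub.n_taxa))
        corr = spearman_matrix(sub)
        net = build_network(
            corr, rho_min=rho_min, alpha=alpha, taxonomy=taxonomy, **network_kwargs
        )
        results[group] = (net, topology(net))
    return results
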