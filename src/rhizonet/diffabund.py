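"""Non-parametric differential abundance across treatment groups.

Per-taxon Kruskal-Wallis omnibus test on relative abundances with
Benjamini-Hochberg correction across taxa, followed by Dunn's pairwise
post-hoc test (BH over the pairwise family within each taxon) wherever
the corrected omnibus p falls below the significance threshold.  Both
statistics use the standard tie corrections.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable, SampleMetadata, TaxonomyMap
from .network import aggregate_to_genus, bh_adjust

__all__ = ["kruskal_wallis", "dunn_posthoc", "taxa_scan", "KWResult"]


def _validate_groups(values_by_group: dict) -> dict:
    if len(values_by_group) < 2:
        raise ValueError("need at least 2 groups")
    clean = {}
    for g, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {g!r} is empty")
        clean[g] = arr
    if sum(a.size for a in clean.values()) < 3:
        raise ValueError("need at least 3 observations in total")
    return clean


def kruskal_wallis(values_by_group: dict) -> tuple[float, float]:
    """Kruskal-Wallis H and chi-square p-value.

    H = [12/(N(N+1))] sum n_i (Rbar_i - Rbar)^2, divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N); p from chi-square with
    g - 1 degrees of freedom.  All-identical data give H = 0, p = 1
    (rather than an error).
    """
    groups = _validate_groups(values_by_group)
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    n = pooled.size
    ranks = stats.rankdata(pooled)
    grand_mean = (n + 1) / 2.0
    h = 0.0
    start = 0
    for arr in groups.values():
        r = ranks[start : start + arr.size]
        start += arr.size
        h += arr.size * (r.mean() - grand_mean) ** 2
    h *= 12.0 / (n * (n + 1))
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - ((t_counts**3 - t_counts).sum()) / (n**3 - n)
    h /= tie_corr
    df = len(groups) - 1
    p = float(stats.chi2.sf(h, df))
    return float(h), p


def dunn_posthoc(values_by_group: dict, adjust: str = "bh") -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled ranks, BH-corrected.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T/(12(N-1)))(1/n_i + 1/n_j)]
    with T = sum(t^3 - t) over tie groups; two-sided normal p-values,
    adjusted across the pairwise family (``adjust='none'`` to skip).
    """
    groups = _validate_groups(values_by_group)
    pooled = np.concatenate(list(groups.values()))
    n = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g, arr in groups.items():
        mean_ranks[g] = ranks[start : start + arr.size].mean()
        sizes[g] = arr.size
        start += arr.size
    _, t_counts = np.unique(pooled, return_counts=True)
    ties = float((t_counts**3 - t_counts).sum())
    var_term = n * (n + 1) / 12.0 - ties / (12.0 * (n - 1))
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        denom = np.sqrt(var_term * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = 0.0 if denom == 0 else (mean_ranks[g1] - mean_ranks[g2]) / denom
        p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append({"group_i": g1, "group_j": g2, "z": float(z), "p": p})
    out = pd.DataFrame(rows)
    if adjust == "bh":
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    elif adjust == "none":
        out["p_adj"] = out["p"]
    else:
        raise ValueError(f"unknown adjustment: {adjust!r}")
    return out


@dataclass
class KWResult:
    taxon: str
    h: float
    df: int
    p: float
    p_adj: float = np.nan
    pairwise: pd.DataFrame | None = field(default=None, repr=False)


def taxa_scan(
    table: FeatureTable,
    metadata: SampleMetadata,
    taxonomy: TaxonomyMap | None = None,
    level: str | None = None,
    alpha: float = 0.05,
) -> list[KWResult]:
    """Kruskal-Wallis scan over taxa with BH across taxa.

    Tests per-taxon relative abundances across groups; the omnibus
    p-values are BH-corrected across taxa, and Dunn's post-hoc runs
    only for taxa with corrected omnibus p below ``alpha``.  Pass
    ``taxonomy`` and ``level='genus'`` to aggregate first.
    """
    if len(metadata.group_labels) < 2:
        raise ValueError("need at least 2 groups")
    if taxonomy is not None and level is not None:
        table = aggregate_to_genus(table, taxonomy, rank=level)
    rel = table.relative_abundance().loc[metadata.sample_ids]
    group_index = {g: metadata.samples_in(g) for g in metadata.group_labels}
    results = []
    for taxon in rel.columns:
        by_group = {g: rel.loc[ids, taxon].to_numpy() for g, ids in group_index.items()}
        h, p = kruskal_wallis(by_group)
        results.append(KWResult(taxon=taxon, h=h, df=len(group_index) - 1, p=p))
    adj = bh_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
        if r.p_adj < alpha:
            by_group = {
                g: rel.loc[ids, r.taxon].to_numpy() for g, ids in group_index.items()
            }
            r.pairwise = dunn_posthoc(by_group)
    return results
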