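"""Taxa-environment correlation networks.

Spearman correlations between the most abundant genera and the soil
physicochemical covariates (pH, EC, SOM, AN, AP, AK, enzyme activities),
with one joint Benjamini-Hochberg correction over all genus x covariate
pairs, rendered as a bipartite network of the significant pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable, SampleMetadata
from .network import bh_adjust, top_taxa

__all__ = ["env_correlations", "coverage_check", "EnvNetworkResult"]


@dataclass
class EnvNetworkResult:
    """Genus-covariate correlation table plus the bipartite network.

    ``table`` has one row per genus x covariate pair (rho, p, p_adj,
    significant); ``network`` contains only significant cross edges,
    with node attribute ``kind`` in {'genus', 'covariate'}.  The
    positive/negative fractions are taken over the significant pairs.
    """

    table: pd.DataFrame
    network: nx.Graph
    positive_fraction: float
    negative_fraction: float
    coverage: float


def coverage_check(table: FeatureTable, top_n: int) -> float:
    """Fraction of all reads captured by the ``top_n`` most abundant taxa.

    Warns when the captured fraction is 0.5 or less (the analysis is
    meant to cover the majority of the community).
    """
    top_n = min(top_n, table.n_taxa)
    sub = top_taxa(table, top_n)
    frac = float(sub.counts.sum() / table.counts.sum())
    if frac <= 0.5:
        warnings.warn(
            f"top {top_n} taxa capture only {frac:.1%} of total counts", stacklevel=2
        )
    return frac


def env_correlations(
    genus_table: FeatureTable,
    metadata: SampleMetadata,
    top_n: int = 50,
    rho_min: float = 0.6,
    alpha: float = 0.05,
) -> EnvNetworkResult:
    """Correlate top genera with environmental covariates.

    Spearman rho per genus x covariate pair on relative abundances,
    two-sided p from the t approximation, BH across all pairs jointly.
    A pair is significant when |rho| > ``rho_min`` (strict, matching the
    'r > 0.6' convention) and p_adj < ``alpha``.
    """
    if metadata.covariates.shape[1] == 0:
        raise ValueError("metadata has no numeric covariates")
    if genus_table.n_samples < 4:
        raise ValueError("need at least 4 samples")
    if metadata.covariates.isna().any().any():
        raise ValueError("missing covariate values")
    if top_n > genus_table.n_taxa:
        warnings.warn(
            f"only {genus_table.n_taxa} genera available; using all", stacklevel=2
        )
        top_n = genus_table.n_taxa
    coverage = coverage_check(genus_table, top_n)
    sub = top_taxa(genus_table, top_n)
    rel = sub.relative_abundance().loc[metadata.sample_ids]
    covars = metadata.covariates

    rows = []
    for genus in rel.columns:
        for cov in covars.columns:
            rho, p = stats.spearmanr(rel[genus].to_numpy(), covars[cov].to_numpy())
            rows.append({"genus": genus, "covariate": cov, "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (
        (out["rho"].abs() > rho_min) & (out["p_adj"] < alpha) & out["rho"].notna()
    )

    net = nx.Graph()
    for genus in rel.columns:
        net.add_node(genus, kind="genus")
    for cov in covars.columns:
        net.add_node(cov, kind="covariate")
    sig = out[out["significant"]]
    for _, row in sig.iterrows():
        net.add_edge(
            row["genus"],
            row["covariate"],
            rho=float(row["rho"]),
            p_adj=float(row["p_adj"]),
            sign="+" if row["rho"] > 0 else "-",
        )
    n_sig = len(sig)
    pos = int((sig["rho"] > 0).sum())
    return EnvNetworkResult(
        table=out,
        network=net,
        positive_fraction=pos / n_sig if n_sig else 0.0,
        negative_fraction=(n_sig - pos) / n_sig if n_sig else 0.0,
        coverage=coverage,
    )
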