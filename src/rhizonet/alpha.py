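"""Rarefaction and within-sample (alpha) diversity estimators.

All estimators operate on a vector of non-negative integer counts for one
sample; zero-count taxa are ignored.  Notation follows the standard
richness literature: S_obs observed taxa, N total reads, F1/F2 singleton
and doubleton counts, H Shannon entropy (in nats), D the unbiased Simpson
dominance estimator, J Pielou's evenness.

Conventions (documented because the source formulas leave them open):

* Chao1 is the bias-corrected form ``S_obs + F1(F1-1) / (2(F2+1))`` so a
  zero doubleton count never divides by zero.
* Simpson is the unbiased dominance ``sum n_i(n_i-1) / (N(N-1))`` (values
  near 0 mean high diversity), not 1-D.
* Pielou for a single-taxon sample is returned as 1.0 (limit convention).
* ACE uses the conventional rare/abundant cutoff of 10; when its sample
  coverage is zero (every rare taxon a singleton) it falls back to Chao1
  with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FeatureTable

__all__ = [
    "rarefy",
    "rarefy_table",
    "sobs",
    "shannon",
    "pielou",
    "simpson",
    "goods_coverage",
    "chao1",
    "ace",
    "alpha_table",
    "AlphaRecord",
]


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if arr.size == 0 or not np.issubdtype(arr.dtype, np.number):
        raise ValueError("counts must be a non-empty numeric vector")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    arr = np.asarray(np.round(arr), dtype=np.int64)
    if arr.sum() == 0:
        raise ValueError("counts sum to zero")
    return arr


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy(counts, depth: int, seed=None) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement.

    A single multivariate-hypergeometric draw; the output sums exactly to
    ``depth`` and never exceeds the input in any taxon.
    """
    arr = _as_counts(counts)
    depth = int(depth)
    if depth <= 0:
        raise ValueError("depth must be positive")
    total = int(arr.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total count {total}")
    if depth == total:
        return arr.copy()
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(arr, depth)


def rarefy_table(table: FeatureTable, depth: int, seed=None) -> FeatureTable:
    """Rarefy every sample of a feature table to a common depth.

    One independent draw per sample (fixed-depth normalisation, not an
    average over repeated draws).  Fails if any sample is shallower than
    ``depth``.
    """
    rng = np.random.default_rng(seed)
    rows = [rarefy(row, depth, seed=rng) for row in table.counts]
    return FeatureTable(
        pd.DataFrame(np.vstack(rows), index=table.sample_ids, columns=table.taxon_ids)
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def sobs(counts) -> int:
    """Observed richness: number of taxa with at least one read."""
    return int((_as_counts(counts) > 0).sum())


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i, in nats."""
    arr = _as_counts(counts)
    p = arr[arr > 0] / arr.sum()
    return float(-(p * np.log(p)).sum())


def pielou(counts) -> float:
    """Evenness J = H / ln S_obs; returns 1.0 for a single-taxon sample."""
    s = sobs(counts)
    if s == 1:
        return 1.0
    return shannon(counts) / float(np.log(s))


def simpson(counts) -> float:
    """Unbiased Simpson dominance D = sum n_i(n_i-1) / (N(N-1))."""
    arr = _as_counts(counts)
    n = int(arr.sum())
    if n == 1:
        return 1.0
    return float((arr * (arr - 1)).sum() / (n * (n - 1)))


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N, the chance the next read is a seen taxon."""
    arr = _as_counts(counts)
    f1 = int((arr == 1).sum())
    return 1.0 - f1 / int(arr.sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness S_obs + F1(F1-1)/(2(F2+1))."""
    arr = _as_counts(counts)
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    return float(sobs(arr) + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator with rare cutoff ``rare_cutoff``.

    S_ACE = S_abund + S_rare/C + (F1/C) * gamma^2, where C = 1 - F1/N_rare
    and gamma^2 is the (non-negative) rare-taxon coefficient of variation.
    Falls back to Chao1 with a warning when C = 0.
    """
    arr = _as_counts(counts)
    arr = arr[arr > 0]
    rare = arr[arr <= rare_cutoff]
    s_abund = int((arr > rare_cutoff).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        warnings.warn("ACE coverage is zero; falling back to Chao1", stacklevel=2)
        return chao1(counts)
    ks = np.arange(1, rare_cutoff + 1)
    fk = np.array([(rare == k).sum() for k in ks])
    gamma2 = (s_rare / c_ace) * (ks * (ks - 1) * fk).sum() / (n_rare * (n_rare - 1.0)) - 1.0
    gamma2 = max(gamma2, 0.0)
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2)


# ---------------------------------------------------------------------------
# per-sample table
# ---------------------------------------------------------------------------

@dataclass
class AlphaRecord:
    sample_id: str
    sobs: int
    chao1: float
    ace: float
    shannon: float
    simpson: float
    pielou: float
    coverage: float


def alpha_table(table: FeatureTable, depth: int | None = None, seed=None) -> pd.DataFrame:
    """Alpha-diversity summary per sample, optionally after rarefaction.

    Parameters
    ----------
    depth : int, optional
        If given, every sample is first rarefied to this depth (one seeded
        draw per sample).  ``None`` computes indices on the raw counts.
    """
    if depth is not None:
        table = rarefy_table(table, depth, seed=seed)
    records = []
    for sample_id, row in zip(table.sample_ids, table.counts):
        records.append(
            AlphaRecord(
                sample_id=sample_id,
                sobs=sobs(row),
                chao1=chao1(row),
                ace=ace(row),
                shannon=shannon(row),
                simpson=simpson(row),
                pielou=pielou(row),
                coverage=goods_coverage(row),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in records]).set_index("sample_id")
    return df
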