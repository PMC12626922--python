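"""Synthetic dose-gradient amplicon studies with known ground truth.

The generator emulates a five-treatment (control plus four inoculant
doses), three-replicate rhizosphere survey: overdispersed sequencing
counts whose inter-taxon Spearman structure, per-group enrichment
effects and taxon-environment couplings are all planted and returned as
ground truth, so every downstream stage (networks, connector detection,
differential abundance, environment correlations) can be tested for
recovery without any sequencing data.

Counts are drawn by Gaussian-copula rank coupling: a latent multivariate
normal with correlation chosen so the copula's population Spearman
matches the target (Pearson = 2 sin(pi rho_s / 6)), pushed through
negative-binomial marginal quantiles whose means are per-sample closed
(compositional) baseline abundances scaled by the group effects.
Environment covariates are monotone functions of the designated taxa's
latent values plus noise - latent values, not counts, so the coupling
stays monotone under sequencing-depth variation.

All randomness flows from a single root seed via ``Generator.spawn``
substreams (baselines, latent field, environment, in that order), so a
spec is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .connectors import betweenness
from .io import FeatureTable, SampleMetadata, TaxonomyMap

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "synthesize",
    "planted_connector_graph",
    "default_study_spec",
]

_PHYLA = (
    "Proteobacteria",
    "Firmicutes",
    "Actinobacteriota",
    "Acidobacteriota",
    "Chloroflexi",
    "Bacteroidota",
)


@dataclass
class SyntheticSpec:
    """Full parameterisation of a simulated dose-gradient amplicon study.

    Parameters
    ----------
    n_groups, n_replicates
        Treatment design; defaults are the five-group (CK, T1-T4),
        three-replicate layout of a dose-gradient field trial.
    n_taxa
        Number of taxa (ASV-level units) simulated.
    sequencing_depth
        Mean reads per sample before compositional noise.
    modules
        Correlated blocks as ``(size, rho)`` tuples assigned to
        consecutive taxon indices starting at 0; taxa outside modules
        are independent.
    planted_connectors
        Taxon indices wired as bridges between correlation modules:
        connector ``i`` in the list correlates at ``connector_rho``
        with every member of modules ``i`` and ``i+1`` (cyclically),
        i.e. it loads on both modules' common factors.  Correlation
        transitivity caps ``connector_rho`` at sqrt(module rho / 2);
        see the methods note for why exactly-degree-2 bridges cannot
        exist in a valid correlation matrix.
    group_effects
        ``{group: {taxon_index: multiplicative fold-change}}``; values
        must be positive.
    env_couplings
        ``{covariate_name: (taxon_index, sign)}`` with sign +-1; the
        covariate is a monotone function of that taxon's latent value.
    overdispersion
        Negative-binomial size parameter r (variance = mu + mu^2/r).
    """

    n_groups: int = 5
    n_replicates: int = 3
    n_taxa: int = 60
    sequencing_depth: int = 42409
    modules: tuple = ()
    planted_connectors: tuple = ()
    connector_rho: float = 0.65
    group_effects: dict = field(default_factory=dict)
    env_couplings: dict = field(default_factory=dict)
    env_noise: float = 0.3
    overdispersion: float = 10.0
    latent_correlation: np.ndarray | None = None
    group_labels: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.n_groups < 1:
            raise ValueError("need at least 1 group")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing depth must be positive")
        if self.group_labels is None:
            if self.n_groups == 5:
                self.group_labels = ("CK", "T1", "T2", "T3", "T4")
            else:
                self.group_labels = tuple(f"G{i + 1}" for i in range(self.n_groups))
        if len(self.group_labels) != self.n_groups:
            raise ValueError("group_labels length must equal n_groups")
        for g, effects in self.group_effects.items():
            if g not in self.group_labels:
                raise ValueError(f"group_effects references unknown group {g!r}")
            if any(v <= 0 for v in effects.values()):
                raise ValueError("group effects must be positive multipliers")

    # -- target Spearman structure ----------------------------------------
    def module_indices(self) -> list[list[int]]:
        out, start = [], 0
        for size, _rho in self.modules:
            out.append(list(range(start, start + size)))
            start += size
        if start > self.n_taxa:
            raise ValueError("modules exceed n_taxa")
        return out

    def target_spearman(self) -> np.ndarray:
        """Target Spearman matrix: module blocks plus connector links."""
        if self.latent_correlation is not None:
            R = np.asarray(self.latent_correlation, dtype=float)
            if R.shape != (self.n_taxa, self.n_taxa):
                raise ValueError("latent_correlation has wrong shape")
            if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
                raise ValueError("latent_correlation must be symmetric, unit diagonal")
            if np.linalg.eigvalsh(R).min() < -1e-8:
                raise ValueError("target correlation matrix is not positive semi-definite")
            return R
        R = np.eye(self.n_taxa)
        mods = self.module_indices()
        for idx, (_size, rho) in zip(mods, self.modules):
            for a in idx:
                for b in idx:
                    if a != b:
                        R[a, b] = rho
        for c_pos, taxon in enumerate(self.planted_connectors):
            if not mods or len(mods) < 2:
                raise ValueError("connectors require at least 2 modules")
            m1 = mods[c_pos % len(mods)]
            m2 = mods[(c_pos + 1) % len(mods)]
            for member in m1 + m2:
                R[taxon, member] = R[member, taxon] = self.connector_rho
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ValueError("target correlation matrix is not positive semi-definite")
        return R


@dataclass
class SyntheticDataset:
    table: FeatureTable
    metadata: SampleMetadata
    taxonomy: TaxonomyMap
    ground_truth: dict


def _latent_pearson(spearman: np.ndarray) -> np.ndarray:
    """Gaussian-copula Pearson correlation whose Spearman equals the target."""
    P = 2.0 * np.sin(np.pi * spearman / 6.0)
    np.fill_diagonal(P, 1.0)
    # numerical guard: project tiny negative eigenvalues away
    vals, vecs = np.linalg.eigh((P + P.T) / 2)
    vals = np.clip(vals, 1e-10, None)
    P = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(P))
    return P / np.outer(d, d)


def synthesize(spec: SyntheticSpec, seed=None) -> SyntheticDataset:
    """Draw one study from a :class:`SyntheticSpec`.

    ``seed`` overrides ``spec.seed``; identical spec and seed give
    identical counts, metadata and ground truth.
    """
    root = np.random.default_rng(spec.seed if seed is None else seed)
    rng_base, rng_latent, rng_env = root.spawn(3)

    n_samples = spec.n_groups * spec.n_replicates
    taxa = [f"ASV_{i:04d}" for i in range(spec.n_taxa)]
    sample_ids = [
        f"{g}_{r + 1}" for g in spec.group_labels for r in range(spec.n_replicates)
    ]
    groups = [g for g in spec.group_labels for _ in range(spec.n_replicates)]

    R = spec.target_spearman()
    P = _latent_pearson(R)
    L = np.linalg.cholesky(P + 1e-12 * np.eye(spec.n_taxa))
    Z = (L @ rng_latent.standard_normal((spec.n_taxa, n_samples))).T
    U = np.clip(stats.norm.cdf(Z), 1e-12, 1 - 1e-12)

    baselines = rng_base.lognormal(mean=0.0, sigma=1.2, size=spec.n_taxa)
    counts = np.zeros((n_samples, spec.n_taxa), dtype=np.int64)
    r_disp = spec.overdispersion
    for s, g in enumerate(groups):
        eff = np.ones(spec.n_taxa)
        for taxon_idx, fold in spec.group_effects.get(g, {}).items():
            eff[taxon_idx] = fold
        weights = baselines * eff
        mu = spec.sequencing_depth * weights / weights.sum()
        p_nb = r_disp / (r_disp + mu)
        counts[s] = stats.nbinom.ppf(U[s], r_disp, p_nb).astype(np.int64)
        if counts[s].sum() == 0:  # pathological tiny-depth guard
            counts[s, int(np.argmax(mu))] = 1

    table = FeatureTable(pd.DataFrame(counts, index=sample_ids, columns=taxa))

    covariates = {}
    for name, (taxon_idx, sign) in spec.env_couplings.items():
        noise = rng_env.standard_normal(n_samples)
        covariates[name] = sign * (Z[:, taxon_idx] + spec.env_noise * noise)
    metadata = SampleMetadata(
        groups=pd.Series(groups, index=sample_ids),
        covariates=pd.DataFrame(covariates, index=sample_ids),
    )

    lineage = pd.DataFrame(
        {
            "kingdom": ["Bacteria"] * spec.n_taxa,
            "phylum": [_PHYLA[i % len(_PHYLA)] for i in range(spec.n_taxa)],
            "genus": [f"Genus_{i:04d}" for i in range(spec.n_taxa)],
        },
        index=pd.Index(taxa, name="taxon_id"),
    )
    taxonomy = TaxonomyMap(lineage)

    mods = spec.module_indices() if spec.latent_correlation is None else []
    true_edges = []
    for idx, (_size, rho) in zip(mods, spec.modules):
        for a_i, a in enumerate(idx):
            for b in idx[a_i + 1 :]:
                true_edges.append((taxa[a], taxa[b], "+" if rho > 0 else "-"))
    for c_pos, taxon_idx in enumerate(spec.planted_connectors):
        m1 = mods[c_pos % len(mods)]
        m2 = mods[(c_pos + 1) % len(mods)]
        for member in m1 + m2:
            true_edges.append(
                (taxa[taxon_idx], taxa[member], "+" if spec.connector_rho > 0 else "-")
            )
    ground_truth = {
        "modules": [[taxa[i] for i in idx] for idx in mods],
        "edges": true_edges,
        "connectors": [taxa[i] for i in spec.planted_connectors],
        "enriched": {
            g: [taxa[i] for i, v in eff.items() if v > 1]
            for g, eff in spec.group_effects.items()
        },
        "suppressed": {
            g: [taxa[i] for i, v in eff.items() if v < 1]
            for g, eff in spec.group_effects.items()
        },
        "env_couplings": {
            name: (taxa[i], sign) for name, (i, sign) in spec.env_couplings.items()
        },
    }
    return SyntheticDataset(table, metadata, taxonomy, ground_truth)


def default_study_spec(seed: int = 0) -> SyntheticSpec:
    """The default simulated study: a 5-group x 3-replicate dose gradient.

    Three positively correlated modules (rho 0.9) joined by one
    connector taxon, dose-responsive enrichment peaking at the middle
    dose (T2) with matching suppression of a "pathogen-like" block, and
    the nine soil covariates each coupled monotonically to one taxon.
    """
    enrich = {"T1": 2.0, "T2": 5.0, "T3": 4.0, "T4": 3.0}
    suppress = {"T1": 0.7, "T2": 0.2, "T3": 0.3, "T4": 0.5}
    group_effects = {
        g: {**{i: enrich[g] for i in range(0, 5)}, **{i: suppress[g] for i in range(18, 23)}}
        for g in ("T1", "T2", "T3", "T4")
    }
    env_couplings = {
        "pH": (40, -1),
        "EC": (0, 1),
        "SOM": (1, 1),
        "AN": (2, 1),
        "AP": (3, 1),
        "AK": (4, 1),
        "ALP": (6, 1),
        "urease": (7, 1),
        "sucrase": (18, -1),
    }
    return SyntheticSpec(
        n_taxa=60,
        modules=((6, 0.9), (6, 0.9), (6, 0.9)),
        planted_connectors=(30,),
        group_effects=group_effects,
        env_couplings=env_couplings,
        seed=seed,
    )


def planted_connector_graph(
    n_modules: int, module_size: int, seed=None
) -> nx.Graph:
    """Dense modules chained by degree-2 bridge nodes, as a ground truth.

    Modules are complete graphs on ``module_size`` nodes; consecutive
    modules are joined by one bridge node attached to a random node of
    each.  Construction verifies that every bridge satisfies the
    observed-network connector criteria (betweenness > 75th percentile,
    degree < 25th percentile, both strict) and raises if the parameters
    are too small to guarantee them.  Bridge node names are listed in
    ``graph.graph['bridges']`` and carry ``role='bridge'``.
    """
    if n_modules < 2:
        raise ValueError("need at least 2 modules")
    if module_size < 4:
        raise ValueError("module_size must be at least 4")
    rng = np.random.default_rng(seed)
    G = nx.Graph()
    members: list[list[str]] = []
    for m in range(n_modules):
        nodes = [f"M{m}_N{j}" for j in range(module_size)]
        members.append(nodes)
        for node in nodes:
            G.add_node(node, role="module")
        for a_i, a in enumerate(nodes):
            for b in nodes[a_i + 1 :]:
                G.add_edge(a, b)
    bridges = []
    for m in range(n_modules - 1):
        bridge = f"B{m}"
        left = members[m][rng.integers(module_size)]
        right = members[m + 1][rng.integers(module_size)]
        G.add_node(bridge, role="bridge")
        G.add_edge(bridge, left)
        G.add_edge(bridge, right)
        bridges.append(bridge)
    G.graph["bridges"] = bridges

    b = betweenness(G)
    degs = dict(G.degree())
    b_vals = np.array([b[v] for v in G.nodes()])
    k_vals = np.array([degs[v] for v in G.nodes()], dtype=float)
    q75 = np.percentile(b_vals, 75)
    q25 = np.percentile(k_vals, 25)
    for bridge in bridges:
        if not (b[bridge] > q75 and degs[bridge] < q25):
            raise ValueError(
                "parameters too small: bridges do not satisfy the "
                "percentile connector criteria"
            )
    if not nx.is_connected(G):  # pragma: no cover - construction guarantees it
        raise RuntimeError("constructed graph is not connected")
    return G
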