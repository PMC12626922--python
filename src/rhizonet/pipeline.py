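"""End-to-end pipeline orchestration and run configuration.

A :class:`RunConfig` gathers every tunable constant of the analysis as
a named default (rarefaction depths per marker, correlation and
significance thresholds, permutation and randomisation counts, top-N
cuts, seed); :func:`run_pipeline` executes the stages in dependency
order — alpha diversity, beta diversity with PERMANOVA/ANOSIM, the
pooled co-occurrence network with connector detection, per-group
networks where the design allows, the taxa-environment network,
Kruskal-Wallis differential abundance and the Venn partition — writing
plain-text outputs plus a machine-readable manifest with per-stage
checksums.  The pipeline is purely functional over files: no stage
mutates another stage's inputs, and identical config + seed yields
byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .alpha import alpha_table
from .beta import anosim, distance_matrix, pcoa, permanova
from .connectors import detect_connectors
from .diffabund import taxa_scan
from .envnet import env_correlations
from .io import (
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
    read_feature_table,
    read_metadata,
    read_newick,
    read_taxonomy,
    write_network,
)
from .network import (
    aggregate_to_genus,
    build_network,
    per_group_networks,
    spearman_matrix,
    top_taxa,
    topology,
)
from .partition import partition, presence_by_group

logger = logging.getLogger("rhizonet")

#: fixed-depth normalisation used for the two markers
DEPTH_BACTERIAL = 38278
DEPTH_FUNGAL = 22075


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All inputs and tunable constants for one pipeline run."""

    table: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    tree: str | None = None
    out_dir: str = "rhizonet_out"
    marker: str = "bacterial"
    depth: int | str | None = "auto"  # int, "auto" (min sample total) or None (skip)
    beta_metric: str = "abund_jaccard"
    rho_min: float = 0.6
    alpha: float = 0.05
    n_perm: int = 999
    n_random: int = 1000
    top_n_network: int = 100
    top_n_env: int = 50
    min_count: int = 1
    per_group_min_samples: int = 4
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def resolve_depth(self, table: FeatureTable) -> int | None:
        if self.depth is None:
            return None
        if self.depth == "auto":
            return int(table.counts.sum(axis=1).min())
        if self.depth == "marker":
            return DEPTH_BACTERIAL if self.marker == "bacterial" else DEPTH_FUNGAL
        return int(self.depth)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig,
    table: FeatureTable | None = None,
    taxonomy: TaxonomyMap | None = None,
    metadata: SampleMetadata | None = None,
    tree=None,
) -> dict:
    """Run every stage and return the manifest dictionary.

    Inputs may be passed as objects or read from the paths in
    ``config``; outputs land in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "settings": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "rhizonet": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
        },
        "stages": {},
    }
    outputs: dict[str, Path] = {}

    def stage(name):
        logger.info("stage %s (seed=%s)", name, config.seed)

    # ---- load ------------------------------------------------------------
    try:
        stage("load")
        if table is None:
            if config.table is None:
                raise ValueError("no feature table given")
            table = read_feature_table(config.table)
        if taxonomy is None and config.taxonomy is not None:
            taxonomy = read_taxonomy(config.taxonomy)
        if metadata is None:
            if config.metadata is None:
                raise ValueError("no sample metadata given")
            metadata = read_metadata(config.metadata)
        if tree is None and config.tree is not None:
            tree = read_newick(config.tree)
    except Exception as exc:
        raise PipelineError("load", exc) from exc

    # ---- alpha -----------------------------------------------------------
    try:
        stage("alpha")
        depth = config.resolve_depth(table)
        alpha_df = alpha_table(table, depth=depth, seed=config.seed)
        path = out / "alpha.csv"
        alpha_df.to_csv(path)
        outputs["alpha"] = path
        manifest["stages"]["alpha"] = {"depth": depth}
    except Exception as exc:
        raise PipelineError("alpha", exc) from exc

    # ---- beta ------------------------------------------------------------
    try:
        stage("beta")
        dm = distance_matrix(table, metric=config.beta_metric, tree=tree)
        ord_res = pcoa(dm)
        path = out / "pcoa.csv"
        ord_res.coordinates.to_csv(path)
        outputs["pcoa"] = path
        groups = metadata.groups
        perm = permanova(dm, groups, n_perm=config.n_perm, seed=config.seed)
        ano = anosim(dm, groups, n_perm=config.n_perm, seed=config.seed)
        manifest["stages"]["beta"] = {
            "metric": config.beta_metric,
            "permanova_F": perm.statistic,
            "permanova_p": perm.p_value,
            "anosim_R": ano.statistic,
            "anosim_p": ano.p_value,
            "proportion_explained": list(map(float, ord_res.proportion_explained[:2])),
        }
    except Exception as exc:
        raise PipelineError("beta", exc) from exc

    # ---- co-occurrence network ------------------------------------------
    try:
        stage("network")
        genus_table = (
            aggregate_to_genus(table, taxonomy) if taxonomy is not None else table
        )
        pooled = top_taxa(genus_table, min(config.top_n_network, genus_table.n_taxa))
        corr = spearman_matrix(pooled)
        net = build_network(
            corr, rho_min=config.rho_min, alpha=config.alpha, taxonomy=taxonomy
        )
        topo = topology(net)
        path = out / "network.graphml"
        write_network(net, path, format="graphml")
        outputs["network"] = path
        topo_rows = [{"group": "pooled", **dataclasses.asdict(topo)}]
        per_group = {}
        group_sizes = {g: len(metadata.samples_in(g)) for g in metadata.group_labels}
        if min(group_sizes.values()) >= config.per_group_min_samples:
            per_group = per_group_networks(
                genus_table,
                metadata,
                top_n=config.top_n_network,
                rho_min=config.rho_min,
                alpha=config.alpha,
                min_samples=config.per_group_min_samples,
                taxonomy=taxonomy,
            )
            for g, (g_net, g_topo) in per_group.items():
                g_path = out / f"network_{g}.graphml"
                write_network(g_net, g_path, format="graphml")
                outputs[f"network_{g}"] = g_path
                topo_rows.append({"group": g, **dataclasses.asdict(g_topo)})
        else:
            logger.warning(
                "per-group networks skipped: smallest group has %d samples "
                "(< %d required for meaningful Spearman p-values)",
                min(group_sizes.values()),
                config.per_group_min_samples,
            )
        topo_df = pd.DataFrame(topo_rows).drop(columns=["degree_sequence"])
        path = out / "topology.csv"
        topo_df.to_csv(path, index=False)
        outputs["topology"] = path
        manifest["stages"]["network"] = {
            "n_nodes": topo.n_nodes,
            "n_edges": topo.n_edges,
            "graph_density": topo.graph_density,
            "positive_edge_fraction": topo.positive_edge_fraction,
            "per_group": sorted(per_group),
        }
    except Exception as exc:
        raise PipelineError("network", exc) from exc

    # ---- connectors ------------------------------------------------------
    try:
        stage("connectors")
        if net.number_of_nodes() >= 5 and net.number_of_edges() >= 2:
            report = detect_connectors(
                net, n_random=config.n_random, seed=config.seed
            )
            path = out / "connectors.csv"
            report.to_csv(path)
            outputs["connectors"] = path
            manifest["stages"]["connectors"] = {
                "n_connectors": int(report["is_connector"].sum()),
                "n_random": config.n_random,
            }
        else:
            logger.warning("connector detection skipped: network too small")
            manifest["stages"]["connectors"] = {"skipped": "network too small"}
    except Exception as exc:
        raise PipelineError("connectors", exc) from exc

    # ---- environment network --------------------------------------------
    try:
        stage("envnet")
        if metadata.covariates.shape[1] > 0:
            env = env_correlations(
                genus_table,
                metadata,
                top_n=config.top_n_env,
                rho_min=config.rho_min,
                alpha=config.alpha,
            )
            path = out / "envcorr.csv"
            env.table.to_csv(path, index=False)
            outputs["envcorr"] = path
            path = out / "envnet.graphml"
            write_network(env.network, path, format="graphml")
            outputs["envnet"] = path
            manifest["stages"]["envnet"] = {
                "n_significant": int(env.table["significant"].sum()),
                "positive_fraction": env.positive_fraction,
                "coverage": env.coverage,
            }
        else:
            manifest["stages"]["envnet"] = {"skipped": "no covariates"}
    except Exception as exc:
        raise PipelineError("envnet", exc) from exc

    # ---- differential abundance -----------------------------------------
    try:
        stage("diffabund")
        results = taxa_scan(genus_table, metadata, alpha=config.alpha)
        rows = [
            {"taxon": r.taxon, "H": r.h, "df": r.df, "p": r.p, "p_adj": r.p_adj}
            for r in results
        ]
        path = out / "kw_results.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        outputs["kw_results"] = path
        pair_rows = []
        for r in results:
            if r.pairwise is not None:
                for _, pr in r.pairwise.iterrows():
                    pair_rows.append({"taxon": r.taxon, **pr.to_dict()})
        if pair_rows:
            path = out / "dunn_results.csv"
            pd.DataFrame(pair_rows).to_csv(path, index=False)
            outputs["dunn_results"] = path
        manifest["stages"]["diffabund"] = {
            "n_significant": sum(r.p_adj < config.alpha for r in results)
        }
    except Exception as exc:
        raise PipelineError("diffabund", exc) from exc

    # ---- Venn partition --------------------------------------------------
    try:
        stage("venn")
        sets = presence_by_group(table, metadata, min_count=config.min_count)
        part = partition(sets)
        path = out / "partition.csv"
        part.to_dataframe().to_csv(path, index=False)
        outputs["partition"] = path
        treatments = [g for g in part.groups if g != "CK"]
        manifest["stages"]["venn"] = {
            "core": len(part.core()),
            "unique": {g: len(part.unique_to(g)) for g in part.groups},
        }
        if treatments and "CK" in part.groups:
            manifest["stages"]["venn"]["shared_treatments_only"] = len(
                part.shared_exclusively(treatments)
            )
    except Exception as exc:
        raise PipelineError("venn", exc) from exc

    manifest["checksums"] = {name: _sha256(p) for name, p in sorted(outputs.items())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
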