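"""Readers and writers for the pipeline's domain objects.

Feature tables (samples x taxa counts), taxonomy maps, sample metadata,
rooted phylogenies and correlation networks all enter and leave the
package through this module, so every downstream stage can assume
validated containers.

Formats are deliberately plain text: TSV for tabular data, dense
BIOM-style JSON as an optional feature-table reader, Newick for trees,
and GraphML or a TSV edge list for networks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

#: taxonomic ranks recognised by :class:`TaxonomyMap`, coarsest first
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

class FeatureTable:
    """Samples x taxa table of non-negative integer counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by sample identifier, columns by taxon identifier.
        Values must be non-negative integers; every sample must have a
        positive total count.
    """

    def __init__(self, data: pd.DataFrame):
        if data.size == 0:
            raise ValueError("feature table is empty")
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample identifiers: {dup}")
        if data.columns.duplicated().any():
            dup = data.columns[data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxon identifiers: {dup}")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if not np.isfinite(values).all():
            raise ValueError("counts must be finite")
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        counts = np.asarray(np.round(values), dtype=np.int64)
        if (counts.sum(axis=1) == 0).any():
            empty = data.index[counts.sum(axis=1) == 0].tolist()
            raise ValueError(f"samples with zero total count: {empty}")
        self.data = pd.DataFrame(
            counts,
            index=data.index.astype(str),
            columns=data.columns.astype(str),
        )

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample closure: each row divided by its total count."""
        return self.data.div(self.data.sum(axis=1), axis=0)

    def select_samples(self, sample_ids) -> "FeatureTable":
        sub = self.data.loc[list(sample_ids)]
        return FeatureTable(sub)

    def select_taxa(self, taxon_ids) -> "FeatureTable":
        sub = self.data[list(taxon_ids)]
        return FeatureTable(sub)

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"FeatureTable({self.n_samples} samples x {self.n_taxa} taxa)"


def read_feature_table(path, orientation: str = "samples_as_rows") -> FeatureTable:
    """Load a feature table from TSV or dense BIOM-style JSON.

    TSV input has one header row and one identifier column; ``orientation``
    declares whether rows are samples or taxa (auto-detection is refused:
    it is ambiguous for square tables).  Dense BIOM JSON carries its own
    orientation (rows are observations/taxa) and ignores the flag.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        return _feature_table_from_biom_json(text)
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "taxa_as_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return FeatureTable(df)


def _feature_table_from_biom_json(text: str) -> FeatureTable:
    doc = json.loads(text)
    if doc.get("matrix_type") != "dense":
        raise ValueError("only dense BIOM-style JSON is supported")
    taxa = [row["id"] for row in doc["rows"]]
    samples = [col["id"] for col in doc["columns"]]
    data = np.asarray(doc["data"])
    if data.shape != (len(taxa), len(samples)):
        raise ValueError("BIOM data shape does not match row/column ids")
    df = pd.DataFrame(data.T, index=samples, columns=taxa)
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

@dataclass
class TaxonomyMap:
    """Mapping from taxon identifier to a ranked lineage.

    ``assignments`` is a DataFrame indexed by taxon id with columns drawn
    from :data:`RANKS`; missing/unassigned ranks are NaN or empty strings.
    Taxon identifiers are opaque: genus-level aggregation always goes
    through this map, never through identifier parsing.
    """

    assignments: pd.DataFrame

    def __post_init__(self):
        df = self.assignments
        if df.index.duplicated().any():
            raise ValueError("duplicate taxon identifiers in taxonomy")
        unknown = [c for c in df.columns if c not in RANKS]
        if unknown:
            raise ValueError(f"unknown taxonomy ranks: {unknown}")
        if len(df.columns) > len(RANKS):
            raise ValueError("lineage longer than supported rank set")
        self.assignments = df.astype("string")

    def __contains__(self, taxon_id) -> bool:
        return taxon_id in self.assignments.index

    def lineage(self, taxon_id: str) -> dict:
        row = self.assignments.loc[taxon_id]
        return {r: (None if pd.isna(v) or v == "" else str(v)) for r, v in row.items()}

    def label_at(self, taxon_id: str, rank: str = "genus") -> str:
        """Name at ``rank``, or ``unclassified_<deepest resolved name>``.

        ASVs unassigned at the requested rank pool under the next-resolved
        coarser rank; a fully unassigned lineage yields
        ``"unclassified_unclassified"``.
        """
        lin = self.lineage(taxon_id)
        if lin.get(rank):
            return lin[rank]
        upto = RANKS[: RANKS.index(rank)]
        for coarser in reversed(upto):
            if lin.get(coarser):
                return f"unclassified_{lin[coarser]}"
        return "unclassified_unclassified"


def read_taxonomy(path) -> TaxonomyMap:
    """Read a TSV taxonomy table.

    Accepts either one column per rank (named after :data:`RANKS`) or a
    single semicolon-separated lineage column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    cols_lower = {c.lower(): c for c in df.columns}
    rank_cols = [cols_lower[r] for r in RANKS if r in cols_lower]
    if rank_cols:
        out = df[rank_cols]
        out.columns = [c.lower() for c in out.columns]
        return TaxonomyMap(out)
    if df.shape[1] == 1:
        parts = df.iloc[:, 0].str.split(";", expand=True)
        parts = parts.apply(lambda s: s.str.strip())
        parts.columns = list(RANKS[: parts.shape[1]])
        return TaxonomyMap(parts)
    raise ValueError("taxonomy file has neither rank columns nor a lineage column")


def write_taxonomy(taxonomy: TaxonomyMap, path) -> None:
    taxonomy.assignments.to_csv(path, sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMetadata:
    """Per-sample treatment group plus numeric environmental covariates."""

    groups: pd.Series
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.groups = self.groups.astype(str)
        self.groups.index = self.groups.index.astype(str)
        if self.groups.index.duplicated().any():
            raise ValueError("duplicate sample identifiers in metadata")
        if self.covariates is None or self.covariates.size == 0:
            self.covariates = pd.DataFrame(index=self.groups.index)
        else:
            self.covariates.index = self.covariates.index.astype(str)
            if not self.covariates.index.equals(self.groups.index):
                self.covariates = self.covariates.loc[self.groups.index]
            values = self.covariates.to_numpy(dtype=float)
            if not np.isfinite(values).all():
                raise ValueError("covariates must be finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups.index)

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def read_metadata(path, group_col: str = "group") -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if group_col not in df.columns:
        raise ValueError(f"metadata is missing the group column {group_col!r}")
    groups = df[group_col].astype(str)
    covars = df.drop(columns=[group_col]).select_dtypes(include=[np.number])
    return SampleMetadata(groups=groups, covariates=covars)


def write_metadata(metadata: SampleMetadata, path, group_col: str = "group") -> None:
    out = pd.concat([metadata.groups.rename(group_col), metadata.covariates], axis=1)
    out.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# phylogenies
# ---------------------------------------------------------------------------

def read_newick(path_or_str) -> TreeNode:
    """Parse a rooted Newick tree; missing branch lengths default to 0.

    Raises on duplicate leaf labels or negative branch lengths.  Unlabeled
    internal nodes, zero-length branches and polytomies are all allowed.
    """
    src = str(path_or_str)
    if Path(src).exists():
        src = Path(src).read_text()
    tree = TreeNode.read([src])
    names = [leaf.name for leaf in tree.tips()]
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate leaf labels: {dup}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        elif node.length < 0:
            raise ValueError("negative branch length")
    if tree.length is None:
        tree.length = 0.0
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

_EDGE_ATTRS = ("rho", "p_adj", "sign")


def write_network(net: nx.Graph, path, format: str = "graphml") -> None:
    """Serialise a co-occurrence network.

    ``graphml`` preserves everything via networkx.  ``edge_list`` writes a
    TSV with one row per edge (source, target, rho, p_adj, sign); isolated
    nodes are appended as rows with an empty target so the node set
    round-trips.
    """
    if format == "graphml":
        nx.write_graphml(net, str(path))
        return
    if format != "edge_list":
        raise ValueError(f"unknown network format: {format!r}")
    rows = []
    for u, v, attrs in net.edges(data=True):
        rows.append(
            {
                "source": u,
                "target": v,
                "rho": attrs.get("rho", ""),
                "p_adj": attrs.get("p_adj", ""),
                "sign": attrs.get("sign", ""),
            }
        )
    for node in nx.isolates(net):
        rows.append({"source": node, "target": "", "rho": "", "p_adj": "", "sign": ""})
    pd.DataFrame(rows, columns=["source", "target", "rho", "p_adj", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def read_network(path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        return nx.read_graphml(str(path))
    if format != "edge_list":
        raise ValueError(f"unknown network format: {format!r}")
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    net = nx.Graph()
    for _, row in df.iterrows():
        if pd.isna(row["target"]) or row["target"] == "":
            net.add_node(row["source"])
        else:
            net.add_edge(
                row["source"],
                row["target"],
                rho=float(row["rho"]),
                p_adj=float(row["p_adj"]),
                sign=str(row["sign"]),
            )
    return net
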