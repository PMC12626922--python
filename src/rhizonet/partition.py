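"""Set-partition ("Venn") accounting of ASV presence across groups.

Assigns every ASV to exactly one region — its exact presence pattern
over treatment groups — and answers the standard Venn queries: the core
(present in all groups), group-unique ASVs, and ASVs shared exclusively
among a given subset of groups (e.g. present in every inoculant
treatment but absent from the control).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import FeatureTable, SampleMetadata

__all__ = ["presence_by_group", "partition", "PartitionCounts"]


def presence_by_group(
    table: FeatureTable, metadata: SampleMetadata, min_count: int = 1
) -> dict[str, set]:
    """ASVs present per group: summed count over the group's samples >= min_count.

    Presence is pooled across a group's replicates.
    """
    if min_count < 1:
        raise ValueError("min_count must be at least 1")
    out: dict[str, set] = {}
    for group in metadata.group_labels:
        samples = metadata.samples_in(group)
        sums = table.data.loc[samples].sum(axis=0)
        out[group] = set(sums.index[sums >= min_count])
    return out


@dataclass
class PartitionCounts:
    """Disjoint regions of the group presence diagram.

    ``regions`` maps each non-empty presence pattern (a frozenset of
    group labels) to the set of ASVs found in exactly those groups.
    """

    groups: list[str]
    regions: dict[frozenset, set]

    @property
    def counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def total(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def core(self) -> set:
        """ASVs present in every group."""
        return set(self.regions.get(frozenset(self.groups), set()))

    def unique_to(self, group: str) -> set:
        """ASVs present in ``group`` and nowhere else."""
        return set(self.regions.get(frozenset([group]), set()))

    def shared_exclusively(self, groups) -> set:
        """ASVs present in exactly the given groups and absent elsewhere."""
        return set(self.regions.get(frozenset(groups), set()))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(sorted(k)), "n_asvs": len(v)}
            for k, v in sorted(self.regions.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows)


def partition(group_sets: dict[str, set]) -> PartitionCounts:
    """Partition the union of group ASV sets by exact presence pattern.

    Regions are disjoint and exhaustive: their counts sum to the number
    of distinct ASVs present in at least one group.
    """
    if len(group_sets) < 2:
        raise ValueError("need at least 2 groups")
    groups = list(group_sets)
    regions: dict[frozenset, set] = {}
    universe = set().union(*group_sets.values())
    for asv in universe:
        pattern = frozenset(g for g in groups if asv in group_sets[g])
        regions.setdefault(pattern, set()).add(asv)
    return PartitionCounts(groups=groups, regions=regions)
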