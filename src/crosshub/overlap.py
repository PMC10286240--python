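"""Group-wise DEG set merging and k-of-n Venn overlap."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .dge import DEGTable


@dataclass(frozen=True)
class GeneSetGroup:
    """Deduplicated union of significant genes across a group's studies."""

    group_id: str
    genes: frozenset[str]
    source_studies: tuple[str, ...] = ()


@dataclass(frozen=True)
class VennPartition:
    """Exclusive regions over n gene-set groups.

    ``regions`` maps every nonempty subset of group ids (as a frozenset)
    to the genes belonging to exactly that subset; regions are pairwise
    disjoint and together cover the union of all groups.
    """

    regions: Mapping[frozenset[str], frozenset[str]]
    n_groups: int

    def region(self, *group_ids: str) -> frozenset[str]:
        return self.regions[frozenset(group_ids)]

    def counts(self) -> dict[frozenset[str], int]:
        return {key: len(genes) for key, genes in self.regions.items()}


def merge_group(
    tables: Sequence[DEGTable], group_id: str = ""
) -> GeneSetGroup:
    """Union of significant genes over one group's DEG tables."""
    if not tables:
        raise ValueError("merge_group requires at least one DEG table")
    genes: set[str] = set()
    for table in tables:
        genes |= table.significant_genes()
    return GeneSetGroup(
        group_id=group_id or tables[0].study_id,
        genes=frozenset(genes),
        source_studies=tuple(t.study_id for t in tables),
    )


def venn_partition(groups: Sequence[GeneSetGroup]) -> VennPartition:
    """All 2^n - 1 exclusive regions for 2-6 groups."""
    if not 2 <= len(groups) <= 6:
        raise ValueError("venn_partition supports 2 to 6 groups")
    ids = [g.group_id for g in groups]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate group ids")
    by_id = {g.group_id: g.genes for g in groups}
    membership: dict[str, frozenset[str]] = {}
    for gene in set().union(*by_id.values()):
        membership[gene] = frozenset(i for i in ids if gene in by_id[i])
    regions: dict[frozenset[str], frozenset[str]] = {}
    for r in range(1, len(ids) + 1):
        for subset in combinations(ids, r):
            key = frozenset(subset)
            regions[key] = frozenset(
                gene for gene, mem in membership.items() if mem == key
            )
    return VennPartition(regions=regions, n_groups=len(ids))


def k_of_n_genes(groups: Sequence[GeneSetGroup], k: int) -> frozenset[str]:
    """Genes present in at least ``k`` of the ``n`` groups.

    Membership ignores regulation direction: a gene counted up in one
    group and down in another still accumulates both memberships.
    """
    n = len(groups)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    counts: dict[str, int] = {}
    for group in groups:
        for gene in group.genes:
            counts[gene] = counts.get(gene, 0) + 1
    return frozenset(g for g, c in counts.items() if c >= k)
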