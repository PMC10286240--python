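"""Hub-gene-centered regulator layers: miRNA, TF, and drug joins.

Each layer is a strictly bipartite regulator -> hub-gene network. miRNA
rows carry a predictive score and only rows with score strictly above
the reliability cutoff (default 80) are retained; TF and drug rows pass
through the filter untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .network import (
    REGULATOR_METHODS,
    InteractionNetwork,
    build_network,
    compute_rankings,
    top_k,
)

KIND_MIRNA = "miRNA"
KIND_TF = "TF"
KIND_DRUG = "drug"
REGULATOR_KINDS = (KIND_MIRNA, KIND_TF, KIND_DRUG)

DEFAULT_MIN_SCORE = 80.0
DEFAULT_MIN_TARGETS = 4
DEFAULT_TOP_N = 40


@dataclass(frozen=True)
class RegulatorTargetTable:
    """Rows of (regulator, kind, target, score); score optional for TF/drug."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"regulator", "kind", "target", "score"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"regulator table missing columns: {sorted(missing)}")
        bad_kinds = set(self.frame["kind"]) - set(REGULATOR_KINDS)
        if bad_kinds:
            raise ValueError(f"unknown regulator kinds: {sorted(bad_kinds)}")
        mirna = self.frame[self.frame["kind"] == KIND_MIRNA]
        scores = mirna["score"].astype(float)
        if scores.isna().any():
            raise ValueError("miRNA rows must carry a score")
        if ((scores < 0) | (scores > 100)).any():
            raise ValueError("miRNA scores must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.frame)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.frame[self.frame["kind"] == kind]


@dataclass(frozen=True)
class BipartiteNetwork:
    """Regulator -> gene edges; the gene side is restricted to a hub set."""

    regulators: frozenset[str]
    genes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.regulators & self.genes:
            raise ValueError("network is not bipartite: shared identifiers")
        for reg, gene in self.edges:
            if reg not in self.regulators or gene not in self.genes:
                raise ValueError(f"edge endpoints unknown: ({reg}, {gene})")

    def degree(self, regulator: str) -> int:
        return sum(1 for reg, _ in self.edges if reg == regulator)

    def edge_list(self) -> list[tuple[str, str]]:
        return sorted(self.edges)


def filter_reliable_targets(
    table: RegulatorTargetTable,
    min_score: float = DEFAULT_MIN_SCORE,
    strict: bool = True,
) -> RegulatorTargetTable:
    """Drop miRNA rows at or below ``min_score`` (strict comparison by
    default, so a score of exactly 80 is removed); other kinds pass."""
    frame = table.frame
    is_mirna = frame["kind"] == KIND_MIRNA
    scores = frame["score"].astype(float)
    passing = scores > min_score if strict else scores >= min_score
    keep = ~is_mirna | passing
    return RegulatorTargetTable(frame=frame[keep].reset_index(drop=True))


def hub_regulator_network(
    table: RegulatorTargetTable, hubs: Iterable[str], kind: str
) -> BipartiteNetwork:
    """Bipartite layer restricted to hub-gene targets.

    Regulators left with no surviving edge are dropped entirely.
    """
    if kind not in REGULATOR_KINDS:
        raise ValueError(f"unknown regulator kind {kind!r}")
    hubs = frozenset(hubs)
    rows = table.of_kind(kind)
    edges = {
        (str(reg), str(target))
        for reg, target in zip(rows["regulator"], rows["target"])
        if target in hubs
    }
    regulators = frozenset(reg for reg, _ in edges)
    genes = frozenset(gene for _, gene in edges)
    return BipartiteNetwork(regulators=regulators, genes=genes, edges=frozenset(edges))


def regulators_by_min_targets(
    net: BipartiteNetwork, min_targets: int = DEFAULT_MIN_TARGETS
) -> frozenset[str]:
    """Regulators hitting at least ``min_targets`` distinct hub genes."""
    if min_targets < 1:
        raise ValueError("min_targets must be >= 1")
    counts: dict[str, int] = {}
    for reg, _ in net.edges:
        counts[reg] = counts.get(reg, 0) + 1
    return frozenset(r for r, c in counts.items() if c >= min_targets)


def consensus_hub_regulators(
    net: BipartiteNetwork,
    methods: Sequence[str] = REGULATOR_METHODS,
    top_n: int = DEFAULT_TOP_N,
    min_methods: int = 3,
) -> frozenset[str]:
    """Regulators appearing among the top-n nodes of >= min_methods rankings.

    Centralities are computed on the bipartite graph viewed as a plain
    undirected graph (regulators and hub genes both as vertices); the
    top-n window is taken over all nodes and then restricted to the
    regulator side.
    """
    if min_methods > len(methods):
        raise ValueError("min_methods exceeds the number of methods")
    if not net.edges:
        return frozenset()
    simple = build_network(
        ((reg, gene, 1.0) for reg, gene in net.edges), threshold=0.0
    )
    support: dict[str, int] = {}
    for ranking in compute_rankings(simple, methods):
        for node in top_k(ranking, top_n):
            if node in net.regulators:
                support[node] = support.get(node, 0) + 1
    return frozenset(r for r, c in support.items() if c >= min_methods)


def drug_gene_join(
    table: RegulatorTargetTable, hubs: Iterable[str]
) -> BipartiteNetwork:
    """Plain drug x hub-gene join with duplicate rows collapsed."""
    return hub_regulator_network(table, hubs, KIND_DRUG)


def regulator_summary(
    net: BipartiteNetwork, consensus: frozenset[str], kind: str
) -> pd.DataFrame:
    """Per-regulator hub-target counts and consensus membership flags."""
    rows = [
        {
            "regulator": reg,
            "kind": kind,
            "n_hub_targets": net.degree(reg),
            "consensus_member": reg in consensus,
        }
        for reg in sorted(net.regulators)
    ]
    return pd.DataFrame(
        rows, columns=["regulator", "kind", "n_hub_targets", "consensus_member"]
    )
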