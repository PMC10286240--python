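"""Synthetic inputs with planted ground truth for every pipeline stage.

Every generator is deterministic under its seed. Gene identifiers are
synthetic symbols ("G000001", ...). The expression generator supports
two noise models keyed by platform kind: Gaussian log2 intensities for
array-like studies (optionally with two probes per gene, to exercise
duplicate collapse) and negative-binomial counts with per-sample size
factors for sequencing-like studies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import NAMESPACES, AnnotationTable, AnnotationTerm
from .network import InteractionNetwork, build_network
from .regulatory import KIND_DRUG, KIND_MIRNA, KIND_TF, RegulatorTargetTable
from .study import ARRAY, COUNTS, ExpressionStudy

MIN_TOTAL_SAMPLES = 8  # cohort inclusion floor
DEFAULT_DISPERSION = 0.1  # NB variance = mu + alpha * mu^2
SIZE_FACTOR_RANGE = (0.5, 2.0)
PLANTED_SCORE_RANGE = (0.7, 1.0)
BACKGROUND_SCORE_RANGE = (0.15, 0.9)


def gene_universe(n_genes: int) -> list[str]:
    """Synthetic gene symbols G000001..G<n>."""
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    return [f"G{i:06d}" for i in range(1, n_genes + 1)]


@dataclass(frozen=True)
class StudyDesign:
    """Design metadata for one synthetic cohort."""

    disease_label: str
    tissue_label: str
    platform_kind: str
    n_case: int
    n_control: int
    seed: int

    def __post_init__(self) -> None:
        if self.platform_kind not in (ARRAY, COUNTS):
            raise ValueError(f"unknown platform kind {self.platform_kind!r}")
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("sample sizes must be positive")
        if self.n_case + self.n_control < MIN_TOTAL_SAMPLES:
            raise ValueError(
                f"cohort needs >= {MIN_TOTAL_SAMPLES} samples in total"
            )

    @property
    def group_id(self) -> str:
        return f"{self.disease_label}-{self.tissue_label}"


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted by the generators, for recovery tests."""

    de_genes_by_group: Mapping[str, frozenset[str]] = field(default_factory=dict)
    shared_genes: frozenset[str] = frozenset()
    hub_genes: frozenset[str] = frozenset()
    regulator_truth: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.de_genes_by_group:
            union: set[str] = set()
            for genes in self.de_genes_by_group.values():
                union |= genes
            if not self.shared_genes <= union:
                raise ValueError("shared_genes must lie in the planted DE union")


def generate_expression_study(
    design: StudyDesign,
    genes: Sequence[str],
    de_genes: Iterable[str],
    effect_log2fc: float,
    dispersion_or_sd: float,
    study_id: str | None = None,
    duplicate_probes: bool = False,
    base_log2_mean: float = 7.0,
    base_count_log_mean: float = 5.0,
) -> ExpressionStudy:
    """One cohort matrix with the planted effect on ``de_genes``.

    Array kind draws Gaussian log2 intensities around a gene-wise
    baseline and shifts the case mean by ``effect_log2fc`` on the planted
    genes (``dispersion_or_sd`` is the per-observation SD). Counts kind
    draws negative-binomial counts (``dispersion_or_sd`` is the NB
    dispersion alpha) with per-sample size factors drawn log-uniform in
    [0.5, 2] and the case mean multiplied by ``2**effect_log2fc`` on the
    planted genes.
    """
    genes = list(genes)
    de_set = set(de_genes)
    outside = de_set - set(genes)
    if outside:
        raise ValueError(f"de_genes outside the universe: {sorted(outside)[:5]}")
    if dispersion_or_sd <= 0:
        raise ValueError("dispersion_or_sd must be positive")
    rng = np.random.default_rng(design.seed)
    n_genes = len(genes)
    n1, n0 = design.n_case, design.n_control
    samples = [f"case_{i+1}" for i in range(n1)] + [
        f"ctrl_{i+1}" for i in range(n0)
    ]
    effect = np.array(
        [effect_log2fc if g in de_set else 0.0 for g in genes], dtype=float
    )

    if design.platform_kind == ARRAY:
        base = rng.normal(base_log2_mean, 1.0, size=n_genes)
        means = np.concatenate(
            [
                np.tile((base + effect)[:, None], (1, n1)),
                np.tile(base[:, None], (1, n0)),
            ],
            axis=1,
        )
        if duplicate_probes:
            means = np.repeat(means, 2, axis=0)
            index = [
                f"{g}_p{j}" for g in genes for j in (1, 2)
            ]
            probe_genes = pd.Series(
                [g for g in genes for _ in (1, 2)], index=index
            )
        else:
            index = list(genes)
            probe_genes = None
        matrix = rng.normal(means, dispersion_or_sd)
        values = pd.DataFrame(matrix, index=index, columns=samples)
    else:
        base = np.exp(rng.normal(base_count_log_mean, 1.0, size=n_genes))
        low, high = SIZE_FACTOR_RANGE
        size_factors = np.exp(
            rng.uniform(math.log(low), math.log(high), size=n1 + n0)
        )
        mu = np.outer(base, size_factors)
        mu[:, :n1] *= np.power(2.0, effect)[:, None]
        alpha = dispersion_or_sd
        # numpy's NB is (n, p) with mean n(1-p)/p: n = 1/alpha, p = n/(n+mu)
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + mu)
        matrix = rng.negative_binomial(n_param, p_param)
        values = pd.DataFrame(matrix, index=list(genes), columns=samples)
        probe_genes = None

    return ExpressionStudy(
        study_id=study_id or f"{design.group_id}-{design.seed}",
        values=values,
        case_samples=tuple(samples[:n1]),
        control_samples=tuple(samples[n1:]),
        kind=design.platform_kind,
        probe_genes=probe_genes,
    )


def generate_ppi_with_planted_hubs(
    n_genes: int = 350,
    n_hubs: int = 20,
    clique_size: int = 4,
    background_edge_prob: float = 0.005,
    seed: int = 0,
    genes: Sequence[str] | None = None,
    cliques_per_hub: int = 4,
) -> tuple[InteractionNetwork, PlantedTruth]:
    """Graph with hub vertices shared by overlapping planted cliques.

    Each hub is the unique shared member of ``cliques_per_hub`` (>= 2)
    cliques of ``clique_size`` vertices; clique membership is assigned
    deterministically from the front of the gene list. Remaining edges
    are Erdos-Renyi at ``background_edge_prob``. Planted edges get
    scores in [0.7, 1.0]; background edges in [0.15, 0.9].
    """
    if clique_size < 4:
        raise ValueError("clique_size must be >= 4")
    if cliques_per_hub < 2:
        raise ValueError("each hub needs at least two overlapping cliques")
    if not 0.0 <= background_edge_prob < 1.0:
        raise ValueError("background_edge_prob must lie in [0, 1)")
    if genes is None:
        genes = gene_universe(n_genes)
    else:
        genes = list(genes)
        if len(genes) != n_genes:
            raise ValueError("len(genes) must equal n_genes")
    per_hub = 1 + cliques_per_hub * (clique_size - 1)
    if n_hubs * clique_size > n_genes or n_hubs * per_hub > n_genes:
        raise ValueError(
            f"infeasible sizes: {n_hubs} hubs x {cliques_per_hub} cliques of "
            f"{clique_size} need {n_hubs * per_hub} vertices, have {n_genes}"
        )
    rng = np.random.default_rng(seed)
    hubs: list[str] = []
    planted_edges: dict[tuple[str, str], float] = {}
    cursor = 0
    lo, hi = PLANTED_SCORE_RANGE
    for _ in range(n_hubs):
        block = genes[cursor : cursor + per_hub]
        cursor += per_hub
        hub = block[0]
        hubs.append(hub)
        members = block[1:]
        for c in range(cliques_per_hub):
            clique = [hub] + members[
                c * (clique_size - 1) : (c + 1) * (clique_size - 1)
            ]
            for a, b in itertools.combinations(clique, 2):
                key = (a, b) if a < b else (b, a)
                if key not in planted_edges:
                    planted_edges[key] = float(rng.uniform(lo, hi))
    edges = [(a, b, s) for (a, b), s in sorted(planted_edges.items())]
    if background_edge_prob > 0:
        er_seed = int(rng.integers(0, 2**31 - 1))
        er = nx.fast_gnp_random_graph(
            n_genes, background_edge_prob, seed=er_seed
        )
        blo, bhi = BACKGROUND_SCORE_RANGE
        for i, j in sorted(er.edges()):
            a, b = genes[i], genes[j]
            key = (a, b) if a < b else (b, a)
            if key in planted_edges:
                continue
            edges.append((key[0], key[1], float(rng.uniform(blo, bhi))))
    net = build_network(edges, threshold=0.0, vertices=genes)
    truth = PlantedTruth(hub_genes=frozenset(hubs))
    return net, truth


def generate_annotation(
    genes: Sequence[str],
    n_terms: int,
    genes_per_term: tuple[int, int] = (5, 30),
    enriched_terms: Mapping[str, Iterable[str]] | None = None,
    seed: int = 0,
) -> AnnotationTable:
    """Random term catalogue with optional verbatim planted terms.

    Random terms are partitioned round-robin over the three GO
    namespaces; planted terms keep their given gene sets and take a
    namespace from an optional "NS|name" prefix (default BP).
    """
    if not genes:
        raise ValueError("empty gene universe")
    rng = np.random.default_rng(seed)
    lo, hi = genes_per_term
    hi = min(hi, len(genes))
    if n_terms > 0 and not 1 <= lo <= hi:
        raise ValueError("invalid genes_per_term range")
    terms: list[AnnotationTerm] = []
    for name, members in sorted((enriched_terms or {}).items()):
        if "|" in name:
            namespace, bare = name.split("|", 1)
        else:
            namespace, bare = "BP", name
        if namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {namespace!r}")
        terms.append(
            AnnotationTerm(
                term=bare,
                namespace=namespace,
                description="planted term",
                genes=frozenset(members),
            )
        )
    go_namespaces = ("BP", "CC", "MF")
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        terms.append(
            AnnotationTerm(
                term=f"T{i+1:05d}",
                namespace=go_namespaces[i % 3],
                description="random term",
                genes=frozenset(genes[j] for j in members),
            )
        )
    return AnnotationTable(terms=tuple(terms))


def generate_regulator_targets(
    genes: Sequence[str],
    n_regulators: int,
    score_range: tuple[float, float] = (50.0, 100.0),
    planted_hub_regulators: Mapping[str, Iterable[str]] | None = None,
    decoy_targets_per_regulator: tuple[int, int] = (1, 3),
    kind: str = KIND_MIRNA,
    seed: int = 0,
) -> tuple[RegulatorTargetTable, PlantedTruth]:
    """Regulator -> target rows with planted high-confidence pairs.

    Planted pairs score strictly above 80; decoy rows draw targets
    uniformly from the universe and scores uniformly from
    ``score_range``.
    """
    if not genes:
        raise ValueError("empty gene universe")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    truth: dict[str, frozenset[str]] = {}
    for reg, targets in sorted((planted_hub_regulators or {}).items()):
        targets = sorted(set(targets))
        truth[reg] = frozenset(targets)
        for t in targets:
            rows.append(
                {
                    "regulator": reg,
                    "kind": kind,
                    "target": t,
                    "score": float(rng.uniform(80.5, 99.5)),
                }
            )
    lo, hi = score_range
    dlo, dhi = decoy_targets_per_regulator
    for i in range(n_regulators):
        reg = f"{kind}-decoy-{i+1:03d}"
        n_targets = int(rng.integers(dlo, dhi + 1))
        picks = rng.choice(len(genes), size=n_targets, replace=False)
        for j in picks:
            rows.append(
                {
                    "regulator": reg,
                    "kind": kind,
                    "target": genes[int(j)],
                    "score": float(rng.uniform(lo, hi)),
                }
            )
    frame = pd.DataFrame(
        rows, columns=["regulator", "kind", "target", "score"]
    )
    return (
        RegulatorTargetTable(frame=frame),
        PlantedTruth(regulator_truth=truth),
    )


# --- full pipeline scenario ------------------------------------------------


@dataclass
class Scenario:
    """Everything the pipeline consumes, plus the planted truth."""

    studies: list[ExpressionStudy]
    study_groups: dict[str, str]  # study_id -> group label
    group_diseases: dict[str, str]  # group label -> disease label
    annotation: AnnotationTable
    network: InteractionNetwork
    regulators: RegulatorTargetTable
    truth: PlantedTruth
    planted_terms: frozenset[str]
    genes: list[str]
    seed: int


def generate_scenario(
    seed: int = 0,
    n_genes: int = 600,
    n_shared: int = 40,
    n_specific: int = 25,
    n_hubs: int = 5,
    clique_size: int = 4,
    cliques_per_hub: int = 2,
    background_edge_prob: float = 0.004,
    effect_log2fc: float = 2.0,
    array_sd: float = 0.3,
    dispersion: float = DEFAULT_DISPERSION,
    n_random_terms: int = 60,
    n_planted_terms: int = 5,
    n_decoy_regulators: int = 30,
) -> Scenario:
    """Coherent two-disease x two-tissue scenario.

    Four cohorts (one per disease x tissue group; arrays for disease A,
    counts for disease B) share ``n_shared`` planted DE genes, each group
    adds ``n_specific`` private DE genes, the PPI plants its hub cliques
    inside the shared genes, the annotation plants common enriched terms
    drawn from the shared genes, and regulator/drug tables target the
    planted hubs.
    """
    rng = np.random.default_rng(seed)
    genes = gene_universe(n_genes)
    shared = genes[:n_shared]
    per_hub = 1 + cliques_per_hub * (clique_size - 1)
    if n_hubs * per_hub > n_shared:
        raise ValueError("shared gene block too small for the planted cliques")

    group_specs = [
        ("A", "PBMC", ARRAY),
        ("A", "Tissue", ARRAY),
        ("B", "PBMC", COUNTS),
        ("B", "Tissue", COUNTS),
    ]
    de_by_group: dict[str, frozenset[str]] = {}
    studies: list[ExpressionStudy] = []
    study_groups: dict[str, str] = {}
    group_diseases: dict[str, str] = {}
    offset = n_shared
    for idx, (disease, tissue, kind) in enumerate(group_specs):
        specific = genes[offset : offset + n_specific]
        offset += n_specific
        de_genes = frozenset(shared) | frozenset(specific)
        design = StudyDesign(
            disease_label=disease,
            tissue_label=tissue,
            platform_kind=kind,
            n_case=10 if kind == ARRAY else 8,
            n_control=10 if kind == ARRAY else 8,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        study = generate_expression_study(
            design,
            genes,
            de_genes,
            effect_log2fc=effect_log2fc,
            dispersion_or_sd=array_sd if kind == ARRAY else dispersion,
            study_id=f"study_{idx+1}_{design.group_id}",
            duplicate_probes=(kind == ARRAY and idx == 0),
        )
        studies.append(study)
        group = design.group_id
        study_groups[study.study_id] = group
        group_diseases[group] = disease
        de_by_group[group] = de_genes

    network, net_truth = generate_ppi_with_planted_hubs(
        n_genes=n_genes,
        n_hubs=n_hubs,
        clique_size=clique_size,
        background_edge_prob=background_edge_prob,
        seed=int(rng.integers(0, 2**31 - 1)),
        genes=genes,
        cliques_per_hub=cliques_per_hub,
    )

    planted_terms: dict[str, list[str]] = {}
    namespaces = ("BP", "CC", "MF")
    for i in range(n_planted_terms):
        picks = rng.choice(n_shared, size=min(20, n_shared), replace=False)
        name = f"{namespaces[i % 3]}|PLANTED{i+1:02d}"
        planted_terms[name] = [genes[j] for j in sorted(picks)]
    annotation = generate_annotation(
        genes,
        n_terms=n_random_terms,
        enriched_terms=planted_terms,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    hub_list = sorted(net_truth.hub_genes)
    planted_regs = {
        f"miR-planted-{i+1:02d}": hub_list for i in range(3)
    }
    reg_table, reg_truth = generate_regulator_targets(
        genes,
        n_regulators=n_decoy_regulators,
        planted_hub_regulators=planted_regs,
        kind=KIND_MIRNA,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    tf_rows = pd.DataFrame(
        {
            "regulator": ["TF-planted-01"] * len(hub_list)
            + ["TF-planted-02"] * min(3, len(hub_list)),
            "kind": KIND_TF,
            "target": hub_list + hub_list[: min(3, len(hub_list))],
            "score": np.nan,
        }
    )
    drug_rows = pd.DataFrame(
        {
            "regulator": [f"drug-{i+1:02d}" for i in range(4) for _ in hub_list[:2]],
            "kind": KIND_DRUG,
            "target": hub_list[:2] * 4,
            "score": np.nan,
        }
    )
    regulators = RegulatorTargetTable(
        frame=pd.concat(
            [reg_table.frame, tf_rows, drug_rows], ignore_index=True
        )
    )

    truth = PlantedTruth(
        de_genes_by_group={g: s for g, s in de_by_group.items()},
        shared_genes=frozenset(shared),
        hub_genes=net_truth.hub_genes,
        regulator_truth=reg_truth.regulator_truth,
    )
    return Scenario(
        studies=studies,
        study_groups=study_groups,
        group_diseases=group_diseases,
        annotation=annotation,
        network=network,
        regulators=regulators,
        truth=truth,
        planted_terms=frozenset(
            name.split("|", 1)[1] for name in planted_terms
        ),
        genes=genes,
        seed=seed,
    )
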