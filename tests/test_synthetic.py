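from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import exact_hypergeom_tail

from crosshub.enrichment import EnrichmentQuery, hypergeom_tail
from crosshub.network import mcc_centrality, top_k
from crosshub.regulatory import (
    filter_reliable_targets,
    hub_regulator_network,
    regulators_by_min_targets,
)
from crosshub.study import ARRAY, COUNTS
from crosshub.synthetic import (
    PlantedTruth,
    StudyDesign,
    gene_universe,
    generate_annotation,
    generate_expression_study,
    generate_ppi_with_planted_hubs,
    generate_regulator_targets,
    generate_scenario,
)


def design(kind=ARRAY, n_case=10, n_control=10, seed=0):
    return StudyDesign("A", "PBMC", kind, n_case, n_control, seed)


# --- StudyDesign / PlantedTruth invariants ---------------------------------


def test_design_enforces_sample_floor():
    with pytest.raises(ValueError, match=">= 8"):
        StudyDesign("A", "PBMC", ARRAY, 4, 3, 0)


def test_design_rejects_nonpositive_sizes():
    with pytest.raises(ValueError):
        StudyDesign("A", "PBMC", ARRAY, 0, 10, 0)


@given(st.integers(min_value=-5, max_value=20), st.integers(min_value=-5, max_value=20))
def test_design_validation_property(n_case, n_control):
    valid = n_case > 0 and n_control > 0 and n_case + n_control >= 8
    if valid:
        StudyDesign("A", "PBMC", ARRAY, n_case, n_control, 0)
    else:
        with pytest.raises(ValueError):
            StudyDesign("A", "PBMC", ARRAY, n_case, n_control, 0)


def test_planted_truth_containment_enforced():
    with pytest.raises(ValueError, match="shared_genes"):
        PlantedTruth(
            de_genes_by_group={"g1": frozenset({"a"})},
            shared_genes=frozenset({"b"}),
        )


# --- expression generator ---------------------------------------------------


def test_null_effect_means_no_shift():
    genes = gene_universe(100)
    study = generate_expression_study(
        design(seed=5), genes, set(), effect_log2fc=2.0, dispersion_or_sd=0.2
    )
    case = study.values[list(study.case_samples)].to_numpy()
    ctrl = study.values[list(study.control_samples)].to_numpy()
    diffs = case.mean(axis=1) - ctrl.mean(axis=1)
    assert np.abs(diffs).max() < 0.5  # pure noise at sd 0.2, n=10

def test_planted_shift_recovered_by_group_mean_difference():
    genes = gene_universe(60)
    study = generate_expression_study(
        design(seed=42), genes, {"G000007"}, effect_log2fc=2.0,
        dispersion_or_sd=0.1,
    )
    case = study.values[list(study.case_samples)]
    ctrl = study.values[list(study.control_samples)]
    diff = case.loc["G000007"].mean() - ctrl.loc["G000007"].mean()
    assert abs(diff - 2.0) < 0.15


def test_expression_determinism_array_and_counts():
    genes = gene_universe(40)
    for kind, disp in ((ARRAY, 0.3), (COUNTS, 0.1)):
        a = generate_expression_study(
            design(kind=kind, seed=9), genes, {"G000001"}, 2.0, disp
        )
        b = generate_expression_study(
            design(kind=kind, seed=9), genes, {"G000001"}, 2.0, disp
        )
        pd.testing.assert_frame_equal(a.values, b.values)


def test_counts_are_nonnegative_integers():
    genes = gene_universe(30)
    study = generate_expression_study(
        design(kind=COUNTS, seed=3, n_case=8, n_control=8), genes, set(), 1.0, 0.1
    )
    values = study.values.to_numpy()
    assert (values >= 0).all()
    assert np.array_equal(values, np.round(values))


def test_de_genes_outside_universe_rejected():
    with pytest.raises(ValueError, match="universe"):
        generate_expression_study(
            design(), gene_universe(10), {"NOPE"}, 2.0, 0.1
        )


def test_nonpositive_dispersion_rejected():
    with pytest.raises(ValueError, match="positive"):
        generate_expression_study(
            design(), gene_universe(10), set(), 2.0, 0.0
        )


# --- PPI generator ----------------------------------------------------------


def test_zero_background_is_exactly_overlapping_cliques():
    net, truth = generate_ppi_with_planted_hubs(
        n_genes=7, n_hubs=1, clique_size=4, background_edge_prob=0.0,
        seed=0, cliques_per_hub=2,
    )
    assert truth.hub_genes == {"G000001"}
    hub = "G000001"
    clique_a = {hub, "G000002", "G000003", "G000004"}
    clique_b = {hub, "G000005", "G000006", "G000007"}
    expected = set()
    for clique in (clique_a, clique_b):
        for a in clique:
            for b in clique:
                if a < b:
                    expected.add((a, b))
    observed = {(u, v) for u, v, _ in net.edge_list()}
    assert observed == expected
    assert all(s >= 0.7 for _, _, s in net.edge_list())


def test_planted_hubs_rank_top20_by_mcc_at_seed_one():
    net, truth = generate_ppi_with_planted_hubs(
        n_genes=200, n_hubs=5, clique_size=5, background_edge_prob=0.02,
        seed=1, cliques_per_hub=2,
    )
    ranking = mcc_centrality(net)
    assert truth.hub_genes <= set(top_k(ranking, 20))


def test_zero_hubs_gives_empty_truth():
    net, truth = generate_ppi_with_planted_hubs(
        n_genes=50, n_hubs=0, clique_size=4, background_edge_prob=0.05, seed=2
    )
    assert truth.hub_genes == frozenset()
    assert len(net.vertices) == 50


def test_infeasible_sizes_rejected():
    with pytest.raises(ValueError, match="infeasible"):
        generate_ppi_with_planted_hubs(
            n_genes=10, n_hubs=3, clique_size=4, background_edge_prob=0.0, seed=0
        )


def test_ppi_determinism():
    a, _ = generate_ppi_with_planted_hubs(seed=5)
    b, _ = generate_ppi_with_planted_hubs(seed=5)
    assert a.edge_list() == b.edge_list()


def test_hub_truth_contained_in_vertices():
    net, truth = generate_ppi_with_planted_hubs(
        n_genes=60, n_hubs=2, clique_size=4, background_edge_prob=0.1, seed=8,
        cliques_per_hub=2,
    )
    assert truth.hub_genes <= net.vertices


# --- annotation generator ---------------------------------------------------


def test_annotation_deterministic():
    genes = gene_universe(100)
    a = generate_annotation(genes, n_terms=20, seed=4)
    b = generate_annotation(genes, n_terms=20, seed=4)
    assert a == b


def test_annotation_zero_terms_empty():
    assert len(generate_annotation(gene_universe(10), n_terms=0, seed=0)) == 0


def test_annotation_requires_genes():
    with pytest.raises(ValueError, match="empty"):
        generate_annotation([], n_terms=5, seed=0)


def test_annotation_namespaces_partitioned():
    table = generate_annotation(gene_universe(50), n_terms=9, seed=1)
    assert {t.namespace for t in table.terms} == {"BP", "CC", "MF"}


def test_injected_term_recovered_by_enrichment_oracle():
    genes = gene_universe(200)
    planted = frozenset(genes[:25])
    table = generate_annotation(
        genes, n_terms=30, enriched_terms={"BP|SIGNAL": planted}, seed=6
    )
    term = table.by_term()["SIGNAL"]
    assert term.genes == planted
    # querying the planted genes themselves: oracle tail must be < 0.01
    query = EnrichmentQuery(N=200, M=25, n=25, k=25)
    oracle_p = float(exact_hypergeom_tail(200, 25, 25, 25))
    assert oracle_p < 0.01
    assert hypergeom_tail(query) == pytest.approx(oracle_p, rel=1e-9)


# --- regulator generator ----------------------------------------------------


def test_planted_regulator_survives_score_and_degree_filters():
    hubs = ["G000001", "G000002", "G000003", "G000004"]
    table, truth = generate_regulator_targets(
        gene_universe(100), n_regulators=10,
        planted_hub_regulators={"miR-X": hubs}, seed=0,
    )
    assert truth.regulator_truth == {"miR-X": frozenset(hubs)}
    reliable = filter_reliable_targets(table, min_score=80, strict=True)
    net = hub_regulator_network(reliable, hubs, "miRNA")
    assert regulators_by_min_targets(net, min_targets=4) == {"miR-X"}


def test_no_planting_no_regulator_passes_degree_filter():
    # decoys draw at most 3 targets each, so degree >= 4 is impossible
    table, _ = generate_regulator_targets(
        gene_universe(50), n_regulators=20, seed=3
    )
    net = hub_regulator_network(table, gene_universe(50), "miRNA")
    assert regulators_by_min_targets(net, min_targets=4) == frozenset()


def test_regulator_determinism():
    a, _ = generate_regulator_targets(gene_universe(30), 5, seed=7)
    b, _ = generate_regulator_targets(gene_universe(30), 5, seed=7)
    pd.testing.assert_frame_equal(a.frame, b.frame)


def test_planted_scores_strictly_above_80():
    table, _ = generate_regulator_targets(
        gene_universe(20), n_regulators=0,
        planted_hub_regulators={"miR-Y": ["G000001", "G000002"]}, seed=1,
    )
    assert (table.frame["score"] > 80).all()


# --- scenario ----------------------------------------------------------------


def test_scenario_truth_invariants():
    scenario = generate_scenario(seed=11, n_genes=400)
    truth = scenario.truth
    union = set()
    for genes in truth.de_genes_by_group.values():
        union |= genes
    assert truth.shared_genes <= union
    assert truth.hub_genes <= scenario.network.vertices
    assert truth.hub_genes <= truth.shared_genes
    assert len(scenario.studies) == 4
    assert set(scenario.group_diseases.values()) == {"A", "B"}


def test_scenario_deterministic():
    a = generate_scenario(seed=2, n_genes=300)
    b = generate_scenario(seed=2, n_genes=300)
    assert a.network.edge_list() == b.network.edge_list()
    pd.testing.assert_frame_equal(a.studies[0].values, b.studies[0].values)
    pd.testing.assert_frame_equal(a.regulators.frame, b.regulators.frame)
    assert a.annotation == b.annotation
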