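from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crosshub.dge import (
    DEGRecord,
    DEGTable,
    bh_adjust,
    classify_direction,
    collapse_duplicates,
    deg_summary,
    median_of_ratios,
    moderated_t_dge,
    negbin_wald_dge,
)
from crosshub.errors import DegenerateInputError
from crosshub.study import ARRAY, COUNTS, ExpressionStudy
from crosshub.synthetic import StudyDesign, gene_universe, generate_expression_study


def make_array_study(case, ctrl, index=None, probe_genes=None):
    case = np.asarray(case, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    cols = [f"c{i}" for i in range(case.shape[1])] + [
        f"n{i}" for i in range(ctrl.shape[1])
    ]
    values = pd.DataFrame(
        np.hstack([case, ctrl]),
        index=index or [f"g{i}" for i in range(case.shape[0])],
        columns=cols,
    )
    return ExpressionStudy(
        study_id="t",
        values=values,
        case_samples=tuple(cols[: case.shape[1]]),
        control_samples=tuple(cols[case.shape[1] :]),
        kind=ARRAY,
        probe_genes=probe_genes,
    )


# --- BH ---------------------------------------------------------------------


def test_bh_single_value_unchanged():
    assert bh_adjust([0.03]) == pytest.approx([0.03])


def test_bh_hand_example_step_up():
    # step-up: adjusted = min over j>=i of p_(j) * m / j = 0.04 for all
    out = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_all_ones():
    assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])


def test_bh_matches_statsmodels_oracle(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(20):
        p = rng.uniform(0, 1, size=int(rng.integers(1, 200)))
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(expected, rel=1e-12)


def test_bh_permutation_invariant(rng):
    p = rng.uniform(0, 1, size=100)
    perm = rng.permutation(100)
    adjusted = bh_adjust(p)
    assert bh_adjust(p[perm]) == pytest.approx(adjusted[perm])


def test_bh_min_not_below_min_raw(rng):
    p = rng.uniform(0, 1, size=50)
    assert bh_adjust(p).min() >= p.min()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


def test_bh_empty():
    assert bh_adjust([]).size == 0


# --- direction rule ---------------------------------------------------------


def test_direction_boundaries():
    assert classify_direction(0.9, 0.04) == "not_significant"
    assert classify_direction(1.2, 0.04) == "up"
    assert classify_direction(1.0, 0.04) == "up"
    assert classify_direction(-1.0, 0.04) == "down"
    assert classify_direction(2.0, 0.05) == "not_significant"


# --- moderated t ------------------------------------------------------------


def test_identical_groups_no_degs(rng):
    values = rng.normal(7, 1, size=(40, 5))
    study = make_array_study(values, values)
    table = moderated_t_dge(study)
    assert all(r.log_fc == 0 for r in table.records)
    assert deg_summary(table) == (0, 0, 0)


def test_planted_gene_called_up(small_array_study):
    table = moderated_t_dge(small_array_study)
    rec = {r.gene: r for r in table.records}["G000001"]
    assert rec.direction == "up"
    # independent Welch-t oracle on the same data
    case = small_array_study.values[list(small_array_study.case_samples)]
    ctrl = small_array_study.values[list(small_array_study.control_samples)]
    welch = stats.ttest_ind(
        case.loc["G000001"], ctrl.loc["G000001"], equal_var=False
    )
    assert welch.pvalue < 1e-6
    assert rec.p_value < 1e-3


def test_moderated_reduces_to_pooled_t_when_d0_zero(rng):
    case = rng.normal(5, 1, size=(30, 6))
    ctrl = rng.normal(5, 1, size=(30, 6))
    study = make_array_study(case, ctrl)
    table = moderated_t_dge(study, d0_override=0.0)
    n1 = n2 = 6
    df = n1 + n2 - 2
    for i, rec in enumerate(
        sorted(table.records, key=lambda r: r.gene)
    ):
        # records are sorted by gene name g00..g29 lexicographically
        pass
    by_gene = {r.gene: r for r in table.records}
    for i in range(30):
        x, y = case[i], ctrl[i]
        s2 = ((x.var(ddof=1) * (n1 - 1)) + (y.var(ddof=1) * (n2 - 1))) / df
        t = (x.mean() - y.mean()) / np.sqrt(s2 * (1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(abs(t), df)
        assert by_gene[f"g{i}"].p_value == pytest.approx(p, rel=1e-10)


def test_null_p_values_uniform_ks():
    rng = np.random.default_rng(99)
    case = rng.normal(0, 1, size=(2000, 8))
    ctrl = rng.normal(0, 1, size=(2000, 8))
    table = moderated_t_dge(make_array_study(case, ctrl))
    p = np.array([r.p_value for r in table.records])
    ks = stats.kstest(p, "uniform").statistic
    assert ks < 0.05


def test_moderated_t_requires_two_per_group(rng):
    case = rng.normal(size=(5, 1))
    ctrl = rng.normal(size=(5, 4))
    with pytest.raises(ValueError, match="two samples"):
        moderated_t_dge(make_array_study(case, ctrl))


def test_degenerate_all_zero_variance():
    case = np.ones((10, 4))
    ctrl = np.ones((10, 4))
    with pytest.raises(DegenerateInputError):
        moderated_t_dge(make_array_study(case, ctrl))


# --- NB Wald ----------------------------------------------------------------


def test_median_of_ratios_two_sample_scaling(rng):
    base = rng.integers(50, 500, size=(30, 1)).astype(float)
    counts = np.hstack([base, 2 * base])
    sf = median_of_ratios(counts)
    assert sf[1] / sf[0] == pytest.approx(2.0, rel=1e-12)


def test_median_of_ratios_requires_reference():
    counts = np.array([[0, 5], [3, 0]], dtype=float)
    with pytest.raises(DegenerateInputError):
        median_of_ratios(counts)


def make_counts_study(seed, de=(), lfc=2.0, n_genes=300, n=8):
    design = StudyDesign("B", "PBMC", COUNTS, n, n, seed)
    return generate_expression_study(
        design, gene_universe(n_genes), set(de), effect_log2fc=lfc,
        dispersion_or_sd=0.1, study_id=f"counts_{seed}",
    )


def test_planted_fourfold_logfc_recovered():
    errors = []
    for seed in range(10):
        study = make_counts_study(seed, de={"G000001"}, lfc=2.0)
        table = negbin_wald_dge(study)
        rec = {r.gene: r for r in table.records}["G000001"]
        errors.append(abs(rec.log_fc - 2.0))
    assert max(errors) < 0.3


def test_global_null_no_rejections_200_genes():
    total = 0
    for seed in range(10):
        study = make_counts_study(seed + 100, de=(), n_genes=200)
        table = negbin_wald_dge(study)
        total += sum(1 for r in table.records if r.adj_p < 0.05)
    assert total == 0


def test_all_zero_rows_reported_with_p_one():
    study = make_counts_study(3, de=(), n_genes=50)
    values = study.values.copy()
    values.iloc[0] = 0
    study2 = ExpressionStudy(
        study_id="z", values=values, case_samples=study.case_samples,
        control_samples=study.control_samples, kind=COUNTS,
    )
    table = negbin_wald_dge(study2)
    rec = {r.gene: r for r in table.records}[str(values.index[0])]
    assert rec.p_value == 1.0 and rec.log_fc == 0.0


def test_negbin_rejects_non_integer():
    study = make_counts_study(4, n_genes=20)
    values = study.values.astype(float) + 0.5
    bad = ExpressionStudy(
        study_id="bad", values=values, case_samples=study.case_samples,
        control_samples=study.control_samples, kind=COUNTS,
    )
    with pytest.raises(ValueError, match="nonnegative integers"):
        negbin_wald_dge(bad)


# --- duplicate collapse and summary ----------------------------------------


def rec(gene, lfc, adj=0.01, p=0.005, probe=None, direction="up"):
    return DEGRecord(
        gene=gene, log_fc=lfc, p_value=p, adj_p=adj,
        direction=direction, probe=probe,
    )


def test_collapse_keeps_max_abs_logfc():
    table = collapse_duplicates(
        [rec("A", 1.5, probe="p1"), rec("A", -0.2, probe="p2")]
    )
    assert len(table) == 1
    assert table.records[0].log_fc == 1.5


def test_collapse_tie_breaks_by_adj_p_then_probe():
    table = collapse_duplicates(
        [
            rec("A", 1.0, adj=0.04, probe="p2"),
            rec("A", -1.0, adj=0.01, probe="p3"),
            rec("A", 1.0, adj=0.01, probe="p1"),
        ]
    )
    assert table.records[0].probe == "p1"


def test_collapse_without_duplicates_is_identity():
    records = [rec("A", 1.0, probe="p1"), rec("B", 2.0, probe="p2")]
    table = collapse_duplicates(records)
    assert {r.gene for r in table.records} == {"A", "B"}


def test_two_probe_study_collapses_to_universe_size():
    design = StudyDesign("A", "Tissue", ARRAY, 6, 6, 11)
    genes = gene_universe(40)
    study = generate_expression_study(
        design, genes, {"G000002"}, effect_log2fc=2.0,
        dispersion_or_sd=0.2, duplicate_probes=True,
    )
    assert study.values.shape[0] == 80
    table = moderated_t_dge(study)
    assert len(table) == 40


def test_deg_table_rejects_duplicate_genes():
    with pytest.raises(ValueError):
        DEGTable(records=[rec("A", 1.0), rec("A", 2.0)], study_id="x")


def test_summary_empty():
    assert deg_summary(DEGTable(records=[], study_id="e")) == (0, 0, 0)


def test_summary_counts_planted_directions():
    design = StudyDesign("A", "PBMC", ARRAY, 10, 10, 21)
    genes = gene_universe(200)
    up = set(genes[:10])
    down = set(genes[10:15])
    study_up = generate_expression_study(
        design, genes, up, effect_log2fc=2.0, dispersion_or_sd=0.25,
    )
    # plant downs by flipping effect on a second study and merging frames
    design2 = StudyDesign("A", "PBMC", ARRAY, 10, 10, 22)
    study_down = generate_expression_study(
        design2, genes, down, effect_log2fc=-2.0, dispersion_or_sd=0.25,
    )
    values = study_up.values.copy()
    values.loc[sorted(down)] = study_down.values.loc[sorted(down)]
    merged = ExpressionStudy(
        study_id="m", values=values, case_samples=study_up.case_samples,
        control_samples=study_up.control_samples, kind=ARRAY,
    )
    summary = deg_summary(moderated_t_dge(merged))
    assert summary.n_up == 10
    assert summary.n_down == 5
    assert summary.n_total == summary.n_up + summary.n_down
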