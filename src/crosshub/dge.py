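"""Per-study differential expression.

Two desk-scale models are provided: an empirical-Bayes moderated t-test
for log-intensity (array-kind) studies and a plug-in negative-binomial
Wald test for counts-kind studies, both followed by Benjamini-Hochberg
adjustment. A gene is called up-regulated when ``adj_p < adj_p_cut`` and
``log_fc >= lfc_cut``, down-regulated when ``adj_p < adj_p_cut`` and
``log_fc <= -lfc_cut``, and not significant otherwise.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DegenerateInputError
from .study import ARRAY, COUNTS, ExpressionStudy

UP = "up"
DOWN = "down"
NOT_SIGNIFICANT = "not_significant"

DEFAULT_ADJ_P_CUT = 0.05
DEFAULT_LFC_CUT = 1.0

DEGSummary = namedtuple("DEGSummary", ["n_up", "n_down", "n_total"])


@dataclass(frozen=True)
class DEGRecord:
    """Differential-expression call for one probe/gene."""

    gene: str
    log_fc: float
    p_value: float
    adj_p: float
    direction: str
    probe: str | None = None


@dataclass
class DEGTable:
    """One collapsed record per gene, with the thresholds that produced it."""

    records: list[DEGRecord]
    study_id: str
    thresholds: tuple[float, float] = (DEFAULT_ADJ_P_CUT, DEFAULT_LFC_CUT)

    def __post_init__(self) -> None:
        genes = [r.gene for r in self.records]
        if len(genes) != len(set(genes)):
            raise ValueError("DEGTable requires one record per gene")

    def __len__(self) -> int:
        return len(self.records)

    def significant_genes(self) -> frozenset[str]:
        return frozenset(
            r.gene for r in self.records if r.direction != NOT_SIGNIFICANT
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [r.gene for r in self.records],
                "log_fc": [r.log_fc for r in self.records],
                "p_value": [r.p_value for r in self.records],
                "adj_p": [r.adj_p for r in self.records],
                "direction": [r.direction for r in self.records],
            }
        )


def classify_direction(
    log_fc: float,
    adj_p: float,
    adj_p_cut: float = DEFAULT_ADJ_P_CUT,
    lfc_cut: float = DEFAULT_LFC_CUT,
) -> str:
    """Direction call: boundary fold changes (|log_fc| == cut) are kept."""
    if adj_p < adj_p_cut and log_fc >= lfc_cut:
        return UP
    if adj_p < adj_p_cut and log_fc <= -lfc_cut:
        return DOWN
    return NOT_SIGNIFICANT


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Returns adjusted values in the input order, with the usual running
    minimum from the largest p downward and a cap at 1.

    Raises
    ------
    ValueError
        If any value lies outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = np.minimum(ranked, 1.0)
    return adjusted


# --- empirical-Bayes moderated t ------------------------------------------


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on psi'(y) = x; monotone decreasing, so the
    # damped update below converges from y0 = 0.5 + 1/x.
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments prior (d0, s0^2) for gene-wise variances.

    Matches the log-variances of a scaled F distribution: the mean of the
    adjusted log variances gives the prior scale and the excess spread
    beyond ``trigamma(df/2)`` gives the prior degrees of freedom. Returns
    ``d0 = inf`` when the observed spread is fully explained by sampling
    noise.
    """
    s2 = np.asarray(s2, dtype=float)
    usable = s2[s2 > 0]
    if usable.size < 2:
        raise DegenerateInputError("too few positive gene variances to fit prior")
    z = np.log(usable)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    resid = e_var - float(special.polygamma(1, df / 2.0))
    if resid <= 1e-12:
        return math.inf, math.exp(e_mean)
    d0 = 2.0 * _trigamma_inverse(resid)
    s0_sq = math.exp(
        e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)
    )
    return d0, s0_sq


def moderated_t_dge(
    study: ExpressionStudy,
    adj_p_cut: float = DEFAULT_ADJ_P_CUT,
    lfc_cut: float = DEFAULT_LFC_CUT,
    d0_override: float | None = None,
) -> DEGTable:
    """Moderated two-group t-test on a log2-intensity study.

    Gene-wise pooled variances are shrunk toward a moments-fit prior
    ``s0^2`` with prior degrees of freedom ``d0``; the test statistic is
    referred to a t distribution with ``df_residual + d0`` degrees of
    freedom. Setting ``d0_override=0`` recovers the ordinary pooled
    t-test exactly.
    """
    if study.kind != ARRAY:
        raise ValueError("moderated_t_dge requires an array-kind study")
    n1, n2 = study.n_case, study.n_control
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two samples")
    case = study.values[list(study.case_samples)].to_numpy(dtype=float)
    ctrl = study.values[list(study.control_samples)].to_numpy(dtype=float)
    log_fc = case.mean(axis=1) - ctrl.mean(axis=1)
    df = float(n1 + n2 - 2)
    s2 = (
        case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    ) / df
    if np.all(s2 <= 0):
        raise DegenerateInputError(
            "all genes have zero residual variance; input is degenerate"
        )
    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = 0.0 if d0 == 0 else fit_variance_prior(s2, df)[1]
    else:
        d0, s0_sq = fit_variance_prior(s2, df)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        total_df = math.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        total_df = df + d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, log_fc / np.where(se > 0, se, 1.0), np.inf)
    if math.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_stat), total_df)
    # zero spread and zero difference carries no evidence at all
    p = np.where(se == 0, np.where(log_fc == 0, 1.0, 0.0), p)
    p = np.clip(p, 0.0, 1.0)
    adj = bh_adjust(p)
    records = _build_records(study, log_fc, p, adj, adj_p_cut, lfc_cut)
    return collapse_duplicates(
        records, study_id=study.study_id, thresholds=(adj_p_cut, lfc_cut)
    )


# --- negative-binomial Wald -----------------------------------------------


def median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """Per-sample size factors from the median-of-ratios estimator.

    The pseudo-reference is the gene-wise geometric mean over samples;
    genes with any zero count are excluded from the reference.
    """
    counts = np.asarray(counts, dtype=float)
    positive = np.all(counts > 0, axis=1)
    if not np.any(positive):
        raise DegenerateInputError(
            "no gene has nonzero counts in every sample; "
            "cannot form the median-of-ratios reference"
        )
    ref = np.exp(np.mean(np.log(counts[positive]), axis=1))
    return np.median(counts[positive] / ref[:, None], axis=0)


def negbin_wald_dge(
    study: ExpressionStudy,
    adj_p_cut: float = DEFAULT_ADJ_P_CUT,
    lfc_cut: float = DEFAULT_LFC_CUT,
    dispersion_floor: float = 1e-8,
) -> DEGTable:
    """Two-group Wald test on counts under a negative-binomial model.

    Counts are normalized by median-of-ratios size factors; a gene-wise
    dispersion is estimated by the method of moments (floored at
    ``dispersion_floor``, no shrinkage across genes); the Wald statistic
    is the estimated log2 fold change over its delta-method standard
    error. All-zero genes are reported with ``p = 1`` rather than
    dropped.
    """
    if study.kind != COUNTS:
        raise ValueError("negbin_wald_dge requires a counts-kind study")
    n1, n2 = study.n_case, study.n_control
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two samples")
    values = study.values.to_numpy(dtype=float)
    if np.any(values < 0) or np.any(values != np.round(values)):
        raise ValueError("counts matrix must hold nonnegative integers")
    sf = median_of_ratios(values)
    columns = list(study.values.columns)
    case_idx = [columns.index(s) for s in study.case_samples]
    ctrl_idx = [columns.index(s) for s in study.control_samples]
    norm = values / sf[None, :]
    case = norm[:, case_idx]
    ctrl = norm[:, ctrl_idx]
    mu1 = case.mean(axis=1)
    mu0 = ctrl.mean(axis=1)
    inv_sf = 1.0 / sf
    c1 = float(np.mean(inv_sf))
    # pooled within-group variance of normalized counts; moments give
    # Var(K/s) ~ mu * mean(1/s) + alpha * mu^2
    pooled_var = (
        case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    ) / float(n1 + n2 - 2)
    grand_mu = (n1 * mu1 + n2 * mu0) / float(n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - grand_mu * c1) / np.square(grand_mu)
    alpha = np.where(np.isfinite(alpha), alpha, dispersion_floor)
    alpha = np.maximum(alpha, dispersion_floor)

    pseudo = 0.5 * c1  # half a normalized count for empty groups
    mu1_adj = np.where(mu1 > 0, mu1, pseudo)
    mu0_adj = np.where(mu0 > 0, mu0, pseudo)
    log_fc = np.log2(mu1_adj / mu0_adj)

    inv_case = np.sum(inv_sf[case_idx])
    inv_ctrl = np.sum(inv_sf[ctrl_idx])
    var_mu1 = (mu1_adj * inv_case + alpha * np.square(mu1_adj) * n1) / n1**2
    var_mu0 = (mu0_adj * inv_ctrl + alpha * np.square(mu0_adj) * n2) / n2**2
    ln2_sq = math.log(2.0) ** 2
    var_lfc = var_mu1 / (np.square(mu1_adj) * ln2_sq) + var_mu0 / (
        np.square(mu0_adj) * ln2_sq
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log_fc / np.sqrt(var_lfc)
    # t reference with the residual df: the plug-in dispersion makes the
    # normal reference anti-conservative at desk-scale group sizes
    p = 2.0 * stats.t.sf(np.abs(z), n1 + n2 - 2)
    all_zero = np.all(values == 0, axis=1)
    log_fc = np.where(all_zero, 0.0, log_fc)
    p = np.where(all_zero, 1.0, np.clip(p, 0.0, 1.0))
    adj = bh_adjust(p)
    records = _build_records(study, log_fc, p, adj, adj_p_cut, lfc_cut)
    return collapse_duplicates(
        records, study_id=study.study_id, thresholds=(adj_p_cut, lfc_cut)
    )


def run_dge(study: ExpressionStudy, **kwargs) -> DEGTable:
    """Dispatch to the model matching the study's platform kind."""
    if study.kind == ARRAY:
        return moderated_t_dge(study, **kwargs)
    return negbin_wald_dge(study, **kwargs)


# --- duplicate collapse and summaries -------------------------------------


def _build_records(
    study: ExpressionStudy,
    log_fc: np.ndarray,
    p: np.ndarray,
    adj: np.ndarray,
    adj_p_cut: float,
    lfc_cut: float,
) -> list[DEGRecord]:
    records = []
    for i, probe in enumerate(study.values.index):
        records.append(
            DEGRecord(
                gene=study.gene_of(probe),
                log_fc=float(log_fc[i]),
                p_value=float(p[i]),
                adj_p=float(adj[i]),
                direction=classify_direction(
                    float(log_fc[i]), float(adj[i]), adj_p_cut, lfc_cut
                ),
                probe=str(probe),
            )
        )
    return records


def collapse_duplicates(
    records: Iterable[DEGRecord],
    study_id: str = "",
    thresholds: tuple[float, float] = (DEFAULT_ADJ_P_CUT, DEFAULT_LFC_CUT),
) -> DEGTable:
    """Keep one record per gene: max |log_fc|, then smaller adj_p, then
    lexicographically smallest probe id."""
    best: dict[str, DEGRecord] = {}
    for rec in records:
        current = best.get(rec.gene)
        if current is None or _collapse_key(rec) < _collapse_key(current):
            best[rec.gene] = rec
    ordered = [best[g] for g in sorted(best)]
    return DEGTable(records=ordered, study_id=study_id, thresholds=thresholds)


def _collapse_key(rec: DEGRecord) -> tuple[float, float, str]:
    return (-abs(rec.log_fc), rec.adj_p, rec.probe or "")


def deg_summary(table: DEGTable) -> DEGSummary:
    """(n_up, n_down, n_total) with n_total = n_up + n_down."""
    n_up = sum(1 for r in table.records if r.direction == UP)
    n_down = sum(1 for r in table.records if r.direction == DOWN)
    return DEGSummary(n_up=n_up, n_down=n_down, n_total=n_up + n_down)
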