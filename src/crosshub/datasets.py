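"""Bundled worked-example data.

A published comorbidity-network analysis reported, for each of its two
PPI modules, the top-20 genes under four centrality ranking methods and
the consensus hub lists derived from them. Those printed tables are
bundled here as plain TSV so the consensus machinery can be exercised
and cross-checked without any network access.
"""

from __future__ import annotations

import csv
from importlib import resources

from .network import CentralityRanking

_RANKING_FILES = {
    1: "module1_top20_rankings.tsv",
    2: "module2_top20_rankings.tsv",
}
_HUB_FILES = {
    1: "module1_published_hubs.tsv",
    2: "module2_published_hubs.tsv",
}


def _data_text(name: str) -> str:
    return (
        resources.files("crosshub").joinpath("data", name).read_text()
    )


def load_worked_example_rankings(module: int) -> list[CentralityRanking]:
    """Four top-20 :class:`CentralityRanking` fixtures for a module (1 or 2).

    Scores are synthesized as descending ranks (20..1) purely so the
    published order is preserved; only the order is meaningful.
    """
    if module not in _RANKING_FILES:
        raise ValueError("module must be 1 or 2")
    rows = list(
        csv.DictReader(_data_text(_RANKING_FILES[module]).splitlines(), delimiter="\t")
    )
    rankings = []
    for method in ("betweenness", "closeness", "degree", "mcc"):
        ordered = [row[method] for row in rows]
        scores = {gene: float(len(ordered) - i) for i, gene in enumerate(ordered)}
        rankings.append(
            CentralityRanking(method=method, scores=scores, order=tuple(ordered))
        )
    return rankings


def load_worked_example_hubs(module: int) -> frozenset[str]:
    """The consensus hub list printed for a module (1 or 2)."""
    if module not in _HUB_FILES:
        raise ValueError("module must be 1 or 2")
    lines = _data_text(_HUB_FILES[module]).splitlines()
    return frozenset(line.strip() for line in lines[1:] if line.strip())
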