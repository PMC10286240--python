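from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles

from crosshub.study import ARRAY
from crosshub.synthetic import StudyDesign, gene_universe, generate_expression_study


def random_graph(rng: np.random.Generator, n_max: int = 10):
    """Random small labelled graph as (vertices, edges)."""
    n = int(rng.integers(2, n_max + 1))
    vertices = [f"v{i:02d}" for i in range(n)]
    p = float(rng.uniform(0.1, 0.8))
    edges = [
        (u, v)
        for i, u in enumerate(vertices)
        for v in vertices[i + 1 :]
        if rng.random() < p
    ]
    return vertices, edges


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_array_study():
    design = StudyDesign(
        disease_label="A",
        tissue_label="PBMC",
        platform_kind=ARRAY,
        n_case=10,
        n_control=10,
        seed=7,
    )
    genes = gene_universe(50)
    return generate_expression_study(
        design, genes, de_genes={"G000001"}, effect_log2fc=2.0,
        dispersion_or_sd=0.1, study_id="small_array",
    )
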