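"""Container for a single cohort's expression matrix and two-group design."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

ARRAY = "array"
COUNTS = "counts"
PLATFORM_KINDS = (ARRAY, COUNTS)


@dataclass
class ExpressionStudy:
    """One cohort: a feature x sample matrix plus case/control labels.

    Parameters
    ----------
    study_id : str
        Identifier used in outputs and provenance records.
    values : pandas.DataFrame
        Rows are probes (or genes), columns are sample ids. Array-kind
        studies hold log2 intensities; counts-kind studies hold
        nonnegative integer counts.
    case_samples, control_samples : tuple of str
        Disjoint column subsets defining the two groups.
    kind : {"array", "counts"}
        Determines which differential-expression model applies.
    probe_genes : pandas.Series, optional
        Maps row index (probe id) to gene symbol. When absent the row
        index is taken to already be the gene symbol.
    """

    study_id: str
    values: pd.DataFrame
    case_samples: tuple[str, ...]
    control_samples: tuple[str, ...]
    kind: str
    probe_genes: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in PLATFORM_KINDS:
            raise ValueError(f"unknown platform kind {self.kind!r}")
        self.case_samples = tuple(self.case_samples)
        self.control_samples = tuple(self.control_samples)
        overlap = set(self.case_samples) & set(self.control_samples)
        if overlap:
            raise ValueError(f"samples in both groups: {sorted(overlap)}")
        missing = (set(self.case_samples) | set(self.control_samples)) - set(
            self.values.columns
        )
        if missing:
            raise ValueError(f"samples not in matrix: {sorted(missing)}")
        if self.probe_genes is not None and not self.probe_genes.index.equals(
            self.values.index
        ):
            raise ValueError("probe_genes index must match the matrix index")

    @property
    def n_case(self) -> int:
        return len(self.case_samples)

    @property
    def n_control(self) -> int:
        return len(self.control_samples)

    def gene_of(self, probe: str) -> str:
        """Gene symbol for a probe id (identity when no probe map is set)."""
        if self.probe_genes is None:
            return str(probe)
        return str(self.probe_genes.loc[probe])
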