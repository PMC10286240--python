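"""Readers and writers for the plain-text interchange formats.

Formats: expression TSV (rows = probes/genes, header of sample ids, an
optional ``gene`` column mapping probes to symbols), sample-sheet TSV
(``sample_id``, ``group`` in {case, control}), GMT gene sets with a
namespace prefix in the term field ("BP|...", "KEGG|..."), 3-column edge
TSV (source, target, score), SIF ("node1 interaction node2" with an
optional score sidecar column), and regulator TSV (regulator, kind,
target, score). Parsers are strict: ragged rows, duplicate sample ids
and non-numeric cells raise :class:`InputParseError` naming the line.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enrichment import NAMESPACES, AnnotationTable, AnnotationTerm
from .errors import InputParseError
from .regulatory import REGULATOR_KINDS, RegulatorTargetTable
from .study import PLATFORM_KINDS, ExpressionStudy

_PATHWAY_PREFIXES = {"KEGG": "pathway", "PATHWAY": "pathway"}


def _read_rows(path: str | Path) -> list[list[str]]:
    path = Path(path)
    if not path.exists():
        raise InputParseError(f"{path}: file not found")
    with open(path, newline="") as fh:
        return [row for row in csv.reader(fh, delimiter="\t")]


def read_expression(
    path: str | Path,
    sample_sheet_path: str | Path,
    kind: str,
    study_id: str | None = None,
) -> ExpressionStudy:
    """Load an expression matrix and its case/control sample sheet."""
    if kind not in PLATFORM_KINDS:
        raise InputParseError(f"unknown platform kind {kind!r}")
    rows = _read_rows(path)
    if not rows or len(rows[0]) < 2:
        raise InputParseError(f"{path}: need a header with at least one sample")
    header = rows[0]
    has_gene_col = len(header) > 1 and header[1] == "gene"
    first_sample = 2 if has_gene_col else 1
    samples = header[first_sample:]
    if len(samples) != len(set(samples)):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise InputParseError(f"{path}: duplicate sample ids {dupes}")
    width = len(header)
    index: list[str] = []
    gene_map: list[str] = []
    data: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise InputParseError(
                f"{path}: line {lineno}: expected {width} fields, got {len(row)}"
            )
        index.append(row[0])
        if has_gene_col:
            gene_map.append(row[1])
        values = []
        for col, cell in zip(samples, row[first_sample:]):
            try:
                values.append(float(cell))
            except ValueError:
                raise InputParseError(
                    f"{path}: line {lineno}: non-numeric cell {cell!r} "
                    f"in sample column {col!r}"
                ) from None
        data.append(values)
    if len(index) != len(set(index)):
        raise InputParseError(f"{path}: duplicate row identifiers")
    values_df = pd.DataFrame(data, index=index, columns=samples)

    sheet = _read_rows(sample_sheet_path)
    if not sheet or sheet[0][:2] != ["sample_id", "group"]:
        raise InputParseError(
            f"{sample_sheet_path}: expected header 'sample_id<TAB>group'"
        )
    case: list[str] = []
    control: list[str] = []
    seen: set[str] = set()
    for lineno, row in enumerate(sheet[1:], start=2):
        if len(row) != 2:
            raise InputParseError(
                f"{sample_sheet_path}: line {lineno}: expected 2 fields"
            )
        sample, group = row
        if sample in seen:
            raise InputParseError(
                f"{sample_sheet_path}: line {lineno}: duplicate sample {sample!r}"
            )
        seen.add(sample)
        if group == "case":
            case.append(sample)
        elif group == "control":
            control.append(sample)
        else:
            raise InputParseError(
                f"{sample_sheet_path}: line {lineno}: group must be "
                f"'case' or 'control', got {group!r}"
            )
    missing = (set(case) | set(control)) - set(samples)
    if missing:
        raise InputParseError(
            f"{sample_sheet_path}: samples absent from matrix: {sorted(missing)}"
        )
    probe_genes = (
        pd.Series(gene_map, index=index) if has_gene_col else None
    )
    return ExpressionStudy(
        study_id=study_id or Path(path).stem,
        values=values_df,
        case_samples=tuple(case),
        control_samples=tuple(control),
        kind=kind,
        probe_genes=probe_genes,
    )


def write_expression(
    study: ExpressionStudy, path: str | Path, sample_sheet_path: str | Path
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        cols = list(study.values.columns)
        if study.probe_genes is not None:
            fh.write("\t".join(["probe", "gene"] + cols) + "\n")
            for probe in study.values.index:
                row = [str(probe), str(study.probe_genes.loc[probe])] + [
                    _fmt(x) for x in study.values.loc[probe]
                ]
                fh.write("\t".join(row) + "\n")
        else:
            fh.write("\t".join(["gene"] + cols) + "\n")
            for probe in study.values.index:
                row = [str(probe)] + [_fmt(x) for x in study.values.loc[probe]]
                fh.write("\t".join(row) + "\n")
    with open(sample_sheet_path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s in study.case_samples:
            fh.write(f"{s}\tcase\n")
        for s in study.control_samples:
            fh.write(f"{s}\tcontrol\n")


def _fmt(x) -> str:
    f = float(x)
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


def read_gmt(path: str | Path) -> AnnotationTable:
    """GMT: term <TAB> description <TAB> gene1 <TAB> gene2 ...

    The term field may carry a namespace prefix ("BP|...", "CC|...",
    "MF|...", "KEGG|..."); unprefixed terms default to BP.
    """
    rows = _read_rows(path)
    terms: list[AnnotationTerm] = []
    for lineno, row in enumerate(rows, start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 3:
            raise InputParseError(
                f"{path}: line {lineno}: GMT rows need term, description "
                f"and at least one gene"
            )
        raw_term, description = row[0], row[1]
        if "|" in raw_term:
            prefix, bare = raw_term.split("|", 1)
            namespace = _PATHWAY_PREFIXES.get(prefix, prefix)
        else:
            namespace, bare = "BP", raw_term
        if namespace not in NAMESPACES:
            raise InputParseError(
                f"{path}: line {lineno}: unknown namespace prefix {raw_term!r}"
            )
        genes = frozenset(g for g in row[2:] if g)
        if not genes:
            raise InputParseError(f"{path}: line {lineno}: term has no genes")
        terms.append(
            AnnotationTerm(
                term=bare, namespace=namespace, description=description, genes=genes
            )
        )
    return AnnotationTable(terms=tuple(terms))


def write_gmt(annotation: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in annotation.terms:
            prefix = "KEGG" if term.namespace == "pathway" else term.namespace
            fh.write(
                "\t".join(
                    [f"{prefix}|{term.term}", term.description]
                    + sorted(term.genes)
                )
                + "\n"
            )


def read_edges(path: str | Path) -> list[tuple[str, str, float]]:
    """Weighted edge list from 3-column TSV or SIF.

    TSV rows are ``source<TAB>target<TAB>score`` (an optional header line
    starting with 'source' is skipped). SIF rows (detected by the .sif
    suffix) are ``node1 interaction node2 [score]``; a missing score
    defaults to 1.0.
    """
    path = Path(path)
    rows = _read_rows(path)
    edges: list[tuple[str, str, float]] = []
    is_sif = path.suffix.lower() == ".sif"
    for lineno, row in enumerate(rows, start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if is_sif:
            fields = row if len(row) > 1 else row[0].split()
            if len(fields) not in (3, 4):
                raise InputParseError(
                    f"{path}: line {lineno}: SIF rows need 3 or 4 fields"
                )
            u, _, v = fields[:3]
            score_str = fields[3] if len(fields) == 4 else "1.0"
        else:
            if lineno == 1 and row[0].lower() == "source":
                continue
            if len(row) != 3:
                raise InputParseError(
                    f"{path}: line {lineno}: expected 3 fields, got {len(row)}"
                )
            u, v, score_str = row
        try:
            score = float(score_str)
        except ValueError:
            raise InputParseError(
                f"{path}: line {lineno}: non-numeric score {score_str!r}"
            ) from None
        edges.append((u, v, score))
    return edges


def write_edges(
    edges: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tscore\n")
        for u, v, s in edges:
            fh.write(f"{u}\t{v}\t{repr(float(s))}\n")


def read_regulators(path: str | Path) -> RegulatorTargetTable:
    """Regulator TSV: regulator, kind, target, score (score may be empty)."""
    rows = _read_rows(path)
    if not rows or rows[0] != ["regulator", "kind", "target", "score"]:
        raise InputParseError(
            f"{path}: expected header 'regulator<TAB>kind<TAB>target<TAB>score'"
        )
    parsed: list[dict] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 4:
            raise InputParseError(
                f"{path}: line {lineno}: expected 4 fields, got {len(row)}"
            )
        regulator, kind, target, score_str = row
        if kind not in REGULATOR_KINDS:
            raise InputParseError(
                f"{path}: line {lineno}: unknown kind {kind!r}"
            )
        if score_str.strip() in ("", "NA", "nan"):
            score = np.nan
        else:
            try:
                score = float(score_str)
            except ValueError:
                raise InputParseError(
                    f"{path}: line {lineno}: non-numeric score {score_str!r}"
                ) from None
        parsed.append(
            {"regulator": regulator, "kind": kind, "target": target, "score": score}
        )
    frame = pd.DataFrame(
        parsed, columns=["regulator", "kind", "target", "score"]
    )
    return RegulatorTargetTable(frame=frame)


def write_regulators(table: RegulatorTargetTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("regulator\tkind\ttarget\tscore\n")
        for row in table.frame.itertuples(index=False):
            score = "" if pd.isna(row.score) else repr(float(row.score))
            fh.write(f"{row.regulator}\t{row.kind}\t{row.target}\t{score}\n")


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_list(path: str | Path) -> frozenset[str]:
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())
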