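"""End-to-end orchestration: config, stage execution, report writing.

Stage order: differential expression -> group overlap -> enrichment ->
module-1 network/hubs -> module-2 network/hubs -> regulator layers ->
drug join -> report. The enrichment, regulatory and drug stages can be
skipped via config; stages depending on a skipped stage are skipped too
and the report records the gap. Two runs with identical config and seed
produce byte-identical artifacts and therefore identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .dge import DEGTable, deg_summary, run_dge
from .enrichment import (
    AnnotationTable,
    EnrichmentResult,
    common_terms,
    enrich_gene_set,
    genes_from_common_terms,
)
from .errors import ConfigError, InputParseError, StageError
from .io import (
    read_edges,
    read_expression,
    read_gmt,
    read_regulators,
    write_edges,
    write_expression,
    write_gene_list,
    write_gmt,
    write_regulators,
)
from .network import (
    HUB_METHODS,
    ConsensusHubSet,
    InteractionNetwork,
    build_network,
    compute_rankings,
    consensus_hubs,
)
from .overlap import GeneSetGroup, VennPartition, k_of_n_genes, merge_group, venn_partition
from .regulatory import (
    KIND_MIRNA,
    KIND_TF,
    BipartiteNetwork,
    RegulatorTargetTable,
    consensus_hub_regulators,
    drug_gene_join,
    filter_reliable_targets,
    hub_regulator_network,
    regulator_summary,
    regulators_by_min_targets,
)
from .study import ARRAY, COUNTS, ExpressionStudy

SKIPPABLE_STAGES = ("enrichment", "regulatory", "drugs")


@dataclass(frozen=True)
class Thresholds:
    """Every tunable cutoff of the pipeline, with the default protocol values."""

    adj_p: float = 0.05
    lfc: float = 1.0
    edge: float = 0.40
    enrich_p: float = 0.05
    regulator_score: float = 80.0
    top_k: int = 20
    top_n_regulators: int = 40
    min_methods: int = 3
    k_of_n: int = 3
    min_regulator_targets: int = 4

    def __post_init__(self) -> None:
        checks = [
            (0 < self.adj_p < 1, "adj_p must be in (0,1)"),
            (self.lfc >= 0, "lfc must be nonnegative"),
            (0 <= self.edge <= 1, "edge threshold must be in [0,1]"),
            (0 < self.enrich_p < 1, "enrich_p must be in (0,1)"),
            (0 <= self.regulator_score <= 100, "regulator_score in [0,100]"),
            (self.top_k >= 1, "top_k must be >= 1"),
            (self.top_n_regulators >= 1, "top_n_regulators must be >= 1"),
            (self.min_methods >= 1, "min_methods must be >= 1"),
            (self.k_of_n >= 1, "k_of_n must be >= 1"),
            (self.min_regulator_targets >= 1, "min_regulator_targets >= 1"),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigError(message)


@dataclass(frozen=True)
class StudySpec:
    study_id: str
    expression: Path
    samples: Path
    kind: str
    group: str


@dataclass
class PipelineConfig:
    seed: int
    output_dir: Path
    studies: tuple[StudySpec, ...]
    groups: Mapping[str, str]  # group label -> disease label
    annotation: Path | None
    edges: Path
    regulators: Path | None
    thresholds: Thresholds = field(default_factory=Thresholds)
    skip_stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.studies:
            raise ConfigError("config lists no studies")
        ids = [s.study_id for s in self.studies]
        if len(ids) != len(set(ids)):
            raise ConfigError("duplicate study ids in config")
        for spec in self.studies:
            if spec.kind not in (ARRAY, COUNTS):
                raise ConfigError(f"study {spec.study_id}: bad kind {spec.kind!r}")
            if spec.group not in self.groups:
                raise ConfigError(
                    f"study {spec.study_id}: unknown group {spec.group!r}"
                )
        unknown = set(self.skip_stages) - set(SKIPPABLE_STAGES)
        if unknown:
            raise ConfigError(f"stages not skippable: {sorted(unknown)}")
        if len(set(self.groups.values())) != 2 and "enrichment" not in self.skip_stages:
            raise ConfigError(
                "the enrichment stage compares exactly two diseases; "
                "skip it or configure two disease labels"
            )

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "studies": [
                {
                    "id": s.study_id,
                    "expression": str(s.expression),
                    "samples": str(s.samples),
                    "kind": s.kind,
                    "group": s.group,
                }
                for s in self.studies
            ],
            "groups": dict(sorted(self.groups.items())),
            "annotation": str(self.annotation),
            "edges": str(self.edges),
            "regulators": str(self.regulators),
            "thresholds": asdict(self.thresholds),
            "skip_stages": list(self.skip_stages),
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except FileNotFoundError:
            raise ConfigError(f"config file not found: {path}") from None
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from None
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        base = path.parent
        try:
            studies = tuple(
                StudySpec(
                    study_id=str(s["id"]),
                    expression=base / s["expression"],
                    samples=base / s["samples"],
                    kind=str(s["kind"]),
                    group=str(s["group"]),
                )
                for s in raw["studies"]
            )
            thresholds = Thresholds(**raw.get("thresholds", {}))
            return cls(
                seed=int(raw.get("seed", 0)),
                output_dir=base / raw.get("output_dir", "out"),
                studies=studies,
                groups=dict(raw["groups"]),
                annotation=(
                    base / raw["annotation"] if raw.get("annotation") else None
                ),
                edges=base / raw["edges"],
                regulators=(
                    base / raw["regulators"] if raw.get("regulators") else None
                ),
                skip_stages=tuple(raw.get("skip_stages", ())),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: bad config: {exc!r}") from exc


@dataclass
class ModuleResult:
    name: str
    genes: frozenset[str]
    network: InteractionNetwork
    rankings: list
    hubs: ConsensusHubSet


@dataclass
class ReportBundle:
    """Everything the report serializes; field order mirrors the stages."""

    deg_tables: dict[str, DEGTable]
    groups: list[GeneSetGroup]
    venn: VennPartition
    module1: ModuleResult
    module2: ModuleResult | None
    hub_union: frozenset[str]
    enrichment_results: dict[str, list[EnrichmentResult]]
    common: dict[str, frozenset[str]]
    mirna_net: BipartiteNetwork | None
    mirna_min_target_regs: frozenset[str]
    mirna_consensus: frozenset[str]
    tf_net: BipartiteNetwork | None
    drug_net: BipartiteNetwork | None
    seed: int
    config_hash: str
    thresholds: Thresholds
    skipped: tuple[str, ...] = ()


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc

    return wrap


def run_analysis(
    studies: Sequence[ExpressionStudy],
    study_groups: Mapping[str, str],
    group_diseases: Mapping[str, str],
    edges: Sequence[tuple[str, str, float]] | InteractionNetwork,
    annotation: AnnotationTable | None = None,
    regulators: RegulatorTargetTable | None = None,
    thresholds: Thresholds = Thresholds(),
    seed: int = 0,
    skip_stages: Sequence[str] = (),
    config_hash: str = "",
) -> ReportBundle:
    """Run the full in-memory analysis; see module docstring for order."""
    th = thresholds
    skip = set(skip_stages)
    if annotation is None:
        skip.add("enrichment")
    if regulators is None:
        skip.update({"regulatory", "drugs"})
    skipped: list[str] = sorted(skip & set(SKIPPABLE_STAGES))

    # -- differential expression
    def do_dge():
        return {
            s.study_id: run_dge(s, adj_p_cut=th.adj_p, lfc_cut=th.lfc)
            for s in studies
        }

    deg_tables = _stage("differential_expression")(do_dge)

    # -- group merge + venn + k-of-n
    def do_overlap():
        labels = sorted(set(study_groups.values()))
        groups = []
        for label in labels:
            tables = [
                deg_tables[s.study_id]
                for s in studies
                if study_groups[s.study_id] == label
            ]
            groups.append(merge_group(tables, group_id=label))
        venn = venn_partition(groups)
        module1_genes = k_of_n_genes(groups, th.k_of_n)
        return groups, venn, module1_genes

    groups, venn, module1_genes = _stage("set_overlap")(do_overlap)

    background = frozenset(
        rec.gene for table in deg_tables.values() for rec in table.records
    )

    # -- enrichment and the module-2 gene set
    enrichment_results: dict[str, list[EnrichmentResult]] = {}
    common: dict[str, frozenset[str]] = {}
    module2_genes: frozenset[str] | None = None
    if "enrichment" not in skip:

        def do_enrichment():
            diseases = sorted(set(group_diseases.values()))
            per_disease: dict[str, frozenset[str]] = {}
            for disease in diseases:
                deg_union: set[str] = set()
                for group in groups:
                    if group_diseases[group.group_id] == disease:
                        deg_union |= group.genes
                per_disease[disease] = frozenset(deg_union)
            results = {
                d: enrich_gene_set(per_disease[d], annotation, background)
                for d in diseases
            }
            shared = common_terms(
                results[diseases[0]], results[diseases[1]], alpha=th.enrich_p
            )
            all_degs = frozenset().union(*per_disease.values())
            genes2 = genes_from_common_terms(shared, annotation, all_degs)
            return results, shared, genes2

        enrichment_results, common, module2_genes = _stage("enrichment")(
            do_enrichment
        )

    # -- networks and consensus hubs
    def do_networks():
        if isinstance(edges, InteractionNetwork):
            full = build_network(edges.edge_list(), threshold=th.edge)
        else:
            full = build_network(edges, threshold=th.edge)

        def module(name: str, genes: frozenset[str]) -> ModuleResult:
            net = full.subgraph(genes)
            rankings = compute_rankings(net, HUB_METHODS)
            hubs = consensus_hubs(
                rankings, top_k_size=th.top_k, min_methods=th.min_methods
            )
            return ModuleResult(
                name=name, genes=genes, network=net, rankings=rankings, hubs=hubs
            )

        module1 = module("module1", module1_genes)
        module2 = (
            module("module2", module2_genes) if module2_genes is not None else None
        )
        return module1, module2

    module1, module2 = _stage("network_hubs")(do_networks)
    hub_union = module1.hubs.hubs | (
        module2.hubs.hubs if module2 is not None else frozenset()
    )

    # -- regulator layers
    mirna_net = tf_net = drug_net = None
    mirna_min = frozenset()
    mirna_consensus = frozenset()
    if "regulatory" not in skip:

        def do_regulatory():
            reliable = filter_reliable_targets(
                regulators, min_score=th.regulator_score, strict=True
            )
            mirna = hub_regulator_network(reliable, hub_union, KIND_MIRNA)
            min_regs = regulators_by_min_targets(
                mirna, min_targets=th.min_regulator_targets
            )
            consensus = consensus_hub_regulators(
                mirna, top_n=th.top_n_regulators, min_methods=th.min_methods
            )
            tf = hub_regulator_network(reliable, hub_union, KIND_TF)
            return mirna, min_regs, consensus, tf

        mirna_net, mirna_min, mirna_consensus, tf_net = _stage("regulatory")(
            do_regulatory
        )

    if "drugs" not in skip and regulators is not None:
        drug_net = _stage("drugs")(drug_gene_join, regulators, hub_union)

    return ReportBundle(
        deg_tables=deg_tables,
        groups=groups,
        venn=venn,
        module1=module1,
        module2=module2,
        hub_union=hub_union,
        enrichment_results=enrichment_results,
        common=common,
        mirna_net=mirna_net,
        mirna_min_target_regs=mirna_min,
        mirna_consensus=mirna_consensus,
        tf_net=tf_net,
        drug_net=drug_net,
        seed=seed,
        config_hash=config_hash,
        thresholds=th,
        skipped=tuple(skipped),
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Load every configured input, run the analysis, write the report."""

    def load_inputs():
        studies = [
            read_expression(s.expression, s.samples, s.kind, study_id=s.study_id)
            for s in config.studies
        ]
        study_groups = {s.study_id: s.group for s in config.studies}
        annotation = read_gmt(config.annotation) if config.annotation else None
        edges = read_edges(config.edges)
        regulators = (
            read_regulators(config.regulators) if config.regulators else None
        )
        return studies, study_groups, annotation, edges, regulators

    studies, study_groups, annotation, edges, regulators = _stage("load_inputs")(
        load_inputs
    )
    bundle = run_analysis(
        studies,
        study_groups,
        dict(config.groups),
        edges,
        annotation=annotation,
        regulators=regulators,
        thresholds=config.thresholds,
        seed=config.seed,
        skip_stages=config.skip_stages,
        config_hash=config.config_hash(),
    )
    write_report(bundle, config.output_dir)
    return bundle


# --- report serialization --------------------------------------------------


def _region_key(key: frozenset[str]) -> str:
    return "+".join(sorted(key))


def build_report_json(bundle: ReportBundle) -> dict[str, Any]:
    """The structured summary serialized as report.json."""
    report: dict[str, Any] = {
        "metadata": {
            "package_version": __version__,
            "seed": bundle.seed,
            "config_hash": bundle.config_hash,
            "thresholds": asdict(bundle.thresholds),
            "skipped_stages": list(bundle.skipped),
        },
        "deg_summary": {
            study_id: dict(deg_summary(table)._asdict())
            for study_id, table in sorted(bundle.deg_tables.items())
        },
        "group_sizes": {g.group_id: len(g.genes) for g in bundle.groups},
        "venn_region_counts": {
            _region_key(k): n for k, n in sorted(
                bundle.venn.counts().items(), key=lambda kv: _region_key(kv[0])
            )
        },
        "module1": _module_json(bundle.module1),
        "module2": _module_json(bundle.module2) if bundle.module2 else None,
        "hub_union": sorted(bundle.hub_union),
        "enrichment": {
            disease: {
                "n_tested": len(results),
                "n_significant": sum(1 for r in results if r.significant),
            }
            for disease, results in sorted(bundle.enrichment_results.items())
        },
        "common_terms": {
            ns: sorted(terms) for ns, terms in sorted(bundle.common.items())
        },
        "regulators": {
            "mirna": _bipartite_json(bundle.mirna_net)
            | {
                "min_target_regulators": sorted(bundle.mirna_min_target_regs),
                "consensus": sorted(bundle.mirna_consensus),
            }
            if bundle.mirna_net is not None
            else None,
            "tf": _bipartite_json(bundle.tf_net) if bundle.tf_net else None,
            "drugs": _bipartite_json(bundle.drug_net) if bundle.drug_net else None,
        },
    }
    return report


def _module_json(module: ModuleResult | None) -> dict[str, Any] | None:
    if module is None:
        return None
    return {
        "n_genes": len(module.genes),
        "n_network_vertices": len(module.network.vertices),
        "n_network_edges": module.network.n_edges,
        "hubs": sorted(module.hubs.hubs),
        "support": {g: module.hubs.support[g] for g in sorted(module.hubs.support)},
    }


def _bipartite_json(net: BipartiteNetwork | None) -> dict[str, Any]:
    if net is None:
        return {}
    return {
        "n_regulators": len(net.regulators),
        "n_genes": len(net.genes),
        "n_edges": len(net.edges),
    }


def write_report(bundle: ReportBundle, out_dir: str | Path) -> dict[str, str]:
    """Serialize every table; returns {relative path: sha256} (manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "deg").mkdir(exist_ok=True)
    (out / "rankings").mkdir(exist_ok=True)
    (out / "enrichment").mkdir(exist_ok=True)
    (out / "regulators").mkdir(exist_ok=True)

    for study_id, table in sorted(bundle.deg_tables.items()):
        frame = table.to_frame()
        frame.to_csv(out / "deg" / f"{study_id}_deg.tsv", sep="\t", index=False)
    with open(out / "deg_summary.tsv", "w") as fh:
        fh.write("study\tn_up\tn_down\tn_total\n")
        for study_id, table in sorted(bundle.deg_tables.items()):
            s = deg_summary(table)
            fh.write(f"{study_id}\t{s.n_up}\t{s.n_down}\t{s.n_total}\n")

    with open(out / "venn_regions.tsv", "w") as fh:
        fh.write("region\tn_genes\tgenes\n")
        for key in sorted(bundle.venn.regions, key=_region_key):
            genes = sorted(bundle.venn.regions[key])
            fh.write(f"{_region_key(key)}\t{len(genes)}\t{','.join(genes)}\n")
    with open(out / "venn_regions.gmt", "w") as fh:
        for key in sorted(bundle.venn.regions, key=_region_key):
            genes = sorted(bundle.venn.regions[key])
            if genes:
                fh.write(
                    "\t".join([_region_key(key), "venn region"] + genes) + "\n"
                )

    for module in (bundle.module1, bundle.module2):
        if module is None:
            continue
        write_gene_list(module.genes, out / f"{module.name}_genes.txt")
        for ranking in module.rankings:
            with open(
                out / "rankings" / f"{module.name}_{ranking.method}.tsv", "w"
            ) as fh:
                fh.write("rank\tgene\tscore\n")
                for i, gene in enumerate(ranking.order, start=1):
                    fh.write(f"{i}\t{gene}\t{repr(ranking.scores[gene])}\n")
        with open(out / f"hubs_{module.name}.tsv", "w") as fh:
            fh.write("gene\tsupport\n")
            for gene in sorted(module.hubs.hubs):
                fh.write(f"{gene}\t{module.hubs.support[gene]}\n")
    write_gene_list(bundle.hub_union, out / "hubs_union.txt")

    for disease, results in sorted(bundle.enrichment_results.items()):
        namespaces = sorted({r.namespace for r in results})
        for ns in namespaces:
            with open(out / "enrichment" / f"{disease}_{ns}.tsv", "w") as fh:
                fh.write("term\tp\tadj_p\tq_value\tfold_enrichment\tk\tM\tn\tN\n")
                for r in results:
                    if r.namespace != ns:
                        continue
                    fh.write(
                        f"{r.term}\t{repr(r.p)}\t{repr(r.adj_p)}\t"
                        f"{repr(r.q_value)}\t{repr(r.fold_enrichment)}\t"
                        f"{r.k}\t{r.M}\t{r.n}\t{r.N}\n"
                    )
    if bundle.common:
        with open(out / "common_terms.json", "w") as fh:
            json.dump(
                {ns: sorted(t) for ns, t in sorted(bundle.common.items())},
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")

    layer_nets = [
        ("mirna", bundle.mirna_net, bundle.mirna_consensus, KIND_MIRNA),
        ("tf", bundle.tf_net, frozenset(), KIND_TF),
        ("drug", bundle.drug_net, frozenset(), "drug"),
    ]
    summaries = []
    for name, net, consensus, kind in layer_nets:
        if net is None:
            continue
        with open(out / "regulators" / f"{name}_edges.tsv", "w") as fh:
            fh.write("regulator\ttarget\n")
            for reg, gene in net.edge_list():
                fh.write(f"{reg}\t{gene}\n")
        summaries.append(regulator_summary(net, consensus, kind))
    if summaries:
        import pandas as pd

        pd.concat(summaries, ignore_index=True).to_csv(
            out / "regulators" / "summary.tsv", sep="\t", index=False
        )

    report = build_report_json(bundle)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest: dict[str, str] = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            rel = str(path.relative_to(out))
            manifest[rel] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# --- minimal structural schema check ---------------------------------------


def report_schema() -> dict[str, Any]:
    from importlib import resources

    text = resources.files("crosshub").joinpath(
        "data", "report_schema.json"
    ).read_text()
    return json.loads(text)


def validate_report(report: Mapping[str, Any], schema: Mapping[str, Any] | None = None):
    """Check the report against the bundled structural schema.

    Supports the subset of JSON-schema keywords the bundled schema uses:
    ``type``, ``properties``, ``required``, and nullable via a type list.
    Raises ``ValueError`` on the first violation.
    """
    if schema is None:
        schema = report_schema()
    _validate_node(report, schema, "$")


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
    "null": type(None),
}


def _validate_node(value: Any, schema: Mapping[str, Any], where: str) -> None:
    expected = schema.get("type")
    if expected is not None:
        types = expected if isinstance(expected, list) else [expected]
        python_types = tuple(
            t for name in types for t in (
                _TYPES[name] if isinstance(_TYPES[name], tuple) else (_TYPES[name],)
            )
        )
        if not isinstance(value, python_types):
            raise ValueError(
                f"{where}: expected {expected}, got {type(value).__name__}"
            )
    if isinstance(value, dict):
        for key in schema.get("required", []):
            if key not in value:
                raise ValueError(f"{where}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _validate_node(value[key], sub, f"{where}.{key}")


# --- writing a generated scenario to disk ----------------------------------


def write_scenario_inputs(scenario, directory: str | Path) -> Path:
    """Materialize a synthetic scenario as pipeline input files.

    Returns the path of the generated config.yaml, ready for
    :func:`PipelineConfig.from_yaml` / ``crosshub run``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study_entries = []
    for study in scenario.studies:
        expr = directory / f"{study.study_id}_expr.tsv"
        sheet = directory / f"{study.study_id}_samples.tsv"
        write_expression(study, expr, sheet)
        study_entries.append(
            {
                "id": study.study_id,
                "expression": expr.name,
                "samples": sheet.name,
                "kind": study.kind,
                "group": scenario.study_groups[study.study_id],
            }
        )
    write_gmt(scenario.annotation, directory / "annotation.gmt")
    write_edges(scenario.network.edge_list(), directory / "edges.tsv")
    write_regulators(scenario.regulators, directory / "regulators.tsv")
    truth = {
        "shared_genes": sorted(scenario.truth.shared_genes),
        "hub_genes": sorted(scenario.truth.hub_genes),
        "planted_terms": sorted(scenario.planted_terms),
        "regulators": {
            r: sorted(t) for r, t in sorted(scenario.truth.regulator_truth.items())
        },
    }
    with open(directory / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    config = {
        "seed": scenario.seed,
        "output_dir": "out",
        "groups": dict(sorted(scenario.group_diseases.items())),
        "studies": study_entries,
        "annotation": "annotation.gmt",
        "edges": "edges.tsv",
        "regulators": "regulators.tsv",
    }
    config_path = directory / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True))
    return config_path
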