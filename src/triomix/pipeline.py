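"""End-to-end orchestration: differential calling on all three layers,
promoter assignment, anti-correlation integration, networks and a report.

A single config seed fans out to per-stage child seeds through
``numpy.random.default_rng(seed).integers(...)`` inside the scenario
builder, so reruns with the same config are byte-identical and individual
stages remain reproducible from written intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import differential as dd
from . import integration as ii
from . import networks_enrichment as ne
from .errors import ValidationError
from .io_formats import (
    CountMatrix,
    ExpressionMatrix,
    TargetPair,
    read_annotation,
    read_bismark_coverage,
    read_count_matrix,
    read_target_table,
    write_edge_list,
    write_records,
)
from .methylation_annotation import (
    DEFAULT_PROMOTER_HALFWIDTH,
    GeneAnnotation,
    MethylRegionTable,
    PromoterAssignment,
    aggregate_to_tiles,
    annotate_regions,
    coverage_filter,
    feature_class_distribution,
    fpkm,
)
from .synthetic_data import ScenarioBundle, build_scenario, cpm


@dataclass
class PipelineConfig:
    """All knobs of the pipeline in one structured object.

    Threshold defaults are the study criteria: genes/miRNAs |log2FC| >= 0.5
    at FDR <= 0.05, methylated regions |log2FC| >= 1 at raw p <= 0.05,
    two-level anti-correlation PCC < -0.5 with p < 0.05, network filter
    PCC < -0.1 with p < 0.1, co-expression minimum 0.1.
    """

    seed: int = 0
    outdir: str | None = None
    simulate: dict[str, int] | None = None
    scenario_params: dict = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    deg_thresholds: dd.ThresholdSet = dd.DEG_THRESHOLDS
    demir_thresholds: dd.ThresholdSet = dd.DEMIR_THRESHOLDS
    dmr_thresholds: dd.ThresholdSet = dd.DMR_THRESHOLDS
    pcc_2level: float = -0.5
    p_2level: float = 0.05
    pcc_network: float = ne.NETWORK_PCC_CUT
    p_network: float = ne.NETWORK_P_CUT
    coexpr_min: float = ne.COEXPRESSION_MIN
    promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH
    tile_size: int = 100
    coverage_min_reads: int = 5
    lowcount_min_reads: int = 4
    keep_nonsignificant: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("deg_thresholds", "demir_thresholds", "dmr_thresholds"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = dd.ThresholdSet(**raw[key])
        return cls(**raw)

    def to_echo(self) -> dict:
        """Config as a plain dict for provenance echoing; the output location
        itself is runtime context and excluded so reruns hash identically."""
        out = dataclasses.asdict(self)
        out.pop("outdir", None)
        return out


@dataclass
class PipelineResult:
    deg_records: list[dd.DifferentialRecord]
    demir_records: list[dd.DifferentialRecord]
    dmr_records: list[dd.DifferentialRecord]
    assignments: list[PromoterAssignment]
    promoter_dmrs: list[ii.PromoterDmr]
    dmr_deg_links: list[ii.DmrExpressionLink]
    anticorr: list[ii.AnticorrInteraction]
    triples: list[ii.IntegrationTriple]
    network: object
    report: dict


def promoter_dmrs_from(
    dmr_records: Sequence[dd.DifferentialRecord],
    assignments: Sequence[PromoterAssignment],
) -> list[ii.PromoterDmr]:
    """Significant methylation records whose region sits in a promoter window."""
    assign = {a.region_id: a for a in assignments}
    out = []
    for rec in dmr_records:
        if rec.direction == "ns":
            continue
        a = assign.get(rec.feature_id)
        if a is None or a.feature_class != "promoter":
            continue
        out.append(
            ii.PromoterDmr(a.gene_id, rec.feature_id, rec.log2fc, rec.p_value,
                           "hyper" if rec.direction == "up" else "hypo")
        )
    return out


def run_on_inputs(
    gene_counts: CountMatrix,
    mirna_counts: CountMatrix,
    meth_table: MethylRegionTable,
    annotation: GeneAnnotation,
    target_pairs: Sequence[TargetPair],
    gene_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    config: PipelineConfig,
) -> PipelineResult:
    cfg = config
    deg = dd.classify(dd.test_counts(gene_counts, layer="gene"), cfg.deg_thresholds)
    demir = dd.classify(dd.test_counts(mirna_counts, layer="mirna"), cfg.demir_thresholds)

    filtered = coverage_filter(meth_table, cfg.coverage_min_reads)
    filtered = dd.filter_low_coverage_regions(filtered, cfg.lowcount_min_reads)
    dmr = dd.classify(dd.test_methylation(filtered), cfg.dmr_thresholds)

    assignments = annotate_regions(filtered, annotation)
    prom_dmrs = promoter_dmrs_from(dmr, assignments)

    links = ii.link_dmr_deg(prom_dmrs, deg)
    anticorr = ii.link_demir_targets(
        demir, target_pairs, deg, gene_expr, mirna_expr, cfg.pcc_2level, cfg.p_2level
    )
    anticorr = ii.attach_demir_stats(anticorr, demir)
    triples = ii.integrate_three_level(prom_dmrs, deg, anticorr)

    # network stage keeps every opposite-direction interaction, then applies
    # its own permissive cutoffs, optionally flagging rather than dropping
    candidates = ii.link_demir_targets(
        demir, target_pairs, deg, gene_expr, mirna_expr, pcc_cut=2.0, p_cut=2.0
    )
    node_lfc = {r.feature_id: r.log2fc for r in [*deg, *demir]}
    network = ne.build_mirna_network(
        candidates, cfg.pcc_network, cfg.p_network, cfg.keep_nonsignificant, node_lfc
    )

    report = _build_report(deg, demir, dmr, assignments, links, anticorr, triples, network)
    return PipelineResult(deg, demir, dmr, assignments, prom_dmrs, links,
                          anticorr, triples, network, report)


def run_on_bundle(bundle: ScenarioBundle, config: PipelineConfig) -> PipelineResult:
    annotation = bundle.annotation.to_gene_annotation(config.promoter_halfwidth)
    return run_on_inputs(
        bundle.gene_counts, bundle.mirna_counts, bundle.meth_table, annotation,
        bundle.target_pairs, bundle.gene_fpkm, bundle.mirna_cpm, config,
    )


def recovered_categories(result: PipelineResult) -> dict[str, str]:
    """Category color per unique gene in the final triples."""
    return {t.gene_id: t.category.value for t in result.triples}


def _build_report(deg, demir, dmr, assignments, links, anticorr, triples, network) -> dict:
    by_dir = lambda recs, d: sum(1 for r in recs if r.direction == d)
    cat = ii.category_summary(triples)
    report = {
        "degs": {"tested": len(deg), "up": by_dir(deg, "up"), "down": by_dir(deg, "down")},
        "demirs": {"tested": len(demir), "up": by_dir(demir, "up"), "down": by_dir(demir, "down")},
        "dmrs": {"tested": len(dmr), "hyper": by_dir(dmr, "up"), "hypo": by_dir(dmr, "down")},
        "feature_classes": (
            feature_class_distribution(assignments).round(4).to_dict() if assignments else {}
        ),
        "dmr_deg_links": len(links),
        "anticorr_interactions": len(anticorr),
        "triples": len(triples),
        "category_genes": cat,
        "network": {
            "nodes": network.number_of_nodes(),
            "edges": network.number_of_edges(),
            "hubs": (
                [list(h) for h in ne.hub_ranking(network)[:5]]
                if network.number_of_nodes() else []
            ),
        },
    }
    return report


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline from a config, either simulating a scenario or
    loading inputs from the configured paths, and write stage outputs."""
    if config.simulate is not None:
        bundle = build_scenario(config.simulate, seed=config.seed, **config.scenario_params)
        result = run_on_bundle(bundle, config)
    else:
        result = run_on_inputs(*_load_inputs(config), config)
    if config.outdir:
        _write_outputs(result, config)
    return result


def _infer_groups(samples: Sequence[str]) -> dict[str, str]:
    groups = {}
    for s in samples:
        if s.startswith("control"):
            groups[s] = "control"
        elif s.startswith("treated"):
            groups[s] = "treated"
        else:
            raise ValidationError(
                f"cannot infer group for sample {s!r}; name must start with control/treated"
            )
    return groups


def _load_inputs(config: PipelineConfig):
    paths = config.inputs
    for key in ("gene_counts", "mirna_counts", "annotation", "targets"):
        if key not in paths:
            raise ValidationError(f"config.inputs missing {key!r}")
    def _read_counts(path):
        with open(path) as fh:
            samples = fh.readline().rstrip("\n").split("\t")[1:]
        return read_count_matrix(path, _infer_groups(samples))

    gene_counts = _read_counts(paths["gene_counts"])
    mirna_counts = _read_counts(paths["mirna_counts"])
    genes = read_annotation(paths["annotation"])
    annotation = GeneAnnotation(genes, config.promoter_halfwidth)
    targets = read_target_table(paths["targets"])
    cov_paths = {k[4:]: v for k, v in paths.items() if k.startswith("cov:")}
    if not cov_paths:
        raise ValidationError("config.inputs needs per-sample coverage files under 'cov:<sample>' keys")
    per_sample = {s: read_bismark_coverage(p) for s, p in sorted(cov_paths.items())}
    meth_table = aggregate_to_tiles(per_sample, _infer_groups(list(per_sample)), config.tile_size)
    lengths = {g.gene_id: g.exonic_length for g in genes}
    gene_expr = fpkm(gene_counts, lengths)
    mirna_expr = cpm(mirna_counts)
    return gene_counts, mirna_counts, meth_table, annotation, targets, gene_expr, mirna_expr


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config_echo.yaml").write_text(yaml.safe_dump(config.to_echo(), sort_keys=True))
    write_records(result.deg_records, outdir / "deg_records.tsv")
    write_records(result.demir_records, outdir / "demir_records.tsv")
    write_records(result.dmr_records, outdir / "dmr_records.tsv")
    write_records(result.assignments, outdir / "region_assignments.tsv")
    triples_frame = pd.DataFrame(
        [
            (t.gene_id, t.region_id, t.dmr_log2fc, t.dmr_p, t.deg_log2fc, t.deg_fdr,
             t.mirna_id, t.demir_log2fc, t.demir_fdr, t.category.value)
            for t in result.triples
        ],
        columns=["gene_id", "region_id", "dmr_log2fc", "dmr_p", "deg_log2fc",
                 "deg_fdr", "mirna_id", "demir_log2fc", "demir_fdr", "category"],
    )
    triples_frame.to_csv(outdir / "triples.tsv", sep="\t", index=False, float_format="%.6g")
    write_edge_list(result.network, outdir / "network_edges.tsv")
    (outdir / "report.json").write_text(json.dumps(result.report, indent=2, sort_keys=True))
    (outdir / "report.md").write_text(_report_markdown(result.report))


def _report_markdown(report: dict) -> str:
    lines = ["# Pipeline report", ""]
    lines.append(f"- DEGs: {report['degs']['up']} up / {report['degs']['down']} down "
                 f"of {report['degs']['tested']} tested")
    lines.append(f"- DEmiRs: {report['demirs']['up']} up / {report['demirs']['down']} down "
                 f"of {report['demirs']['tested']} tested")
    lines.append(f"- DMRs: {report['dmrs']['hyper']} hyper / {report['dmrs']['hypo']} hypo "
                 f"of {report['dmrs']['tested']} tested")
    lines.append(f"- promoter DMR x gene inverse links: {report['dmr_deg_links']}")
    lines.append(f"- anticorrelated miRNA-target interactions: {report['anticorr_interactions']}")
    cat = report["category_genes"]
    lines.append(f"- integration triples: {report['triples']} over {cat['unique_genes']} unique genes")
    lines.append(f"- categories: red={cat['red']} blue={cat['blue']} "
                 f"green={cat['green']} orange={cat['orange']} "
                 f"(consistent={cat['consistent']}, inconsistent={cat['inconsistent']})")
    lines.append(f"- network: {report['network']['nodes']} nodes, "
                 f"{report['network']['edges']} edges")
    return "\n".join(lines) + "\n"


def output_hashes(outdir: str | Path) -> dict[str, str]:
    """SHA-256 of every file in an output directory (reproducibility check)."""
    outdir = Path(outdir)
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(outdir.iterdir()) if p.is_file()
    }
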