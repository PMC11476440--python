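"""Synthetic multi-omics inputs with planted ground truth.

Every generator is fully determined by its integer seed.  The statistical
models mirror what the downstream tests assume: read counts are
negative-binomial (gamma-Poisson) with log-normal library-size variation
(sigma = 0.1), per-region methylation counts are binomial with group shifts
on the logistic (log-odds) scale, and cytosine contexts follow the roughly
74/12/14 CpG/CHG/CHH split typical of a mammalian methylome.  Scenario
bundles plant genes in each of the four regulatory categories at generous
effect sizes so the full pipeline can be checked against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, ValidationError
from .io_formats import CountMatrix, ExpressionMatrix, GeneModel, TargetPair
from .methylation_annotation import (
    DEFAULT_PROMOTER_HALFWIDTH,
    GeneAnnotation,
    MethylRegionTable,
    fpkm,
)

CATEGORIES = ("red", "blue", "green", "orange")

#: per-category direction signs: (promoter methylation, gene, miRNA)
CATEGORY_SIGNS: Mapping[str, tuple[int, int, int]] = {
    "red": (+1, -1, +1),
    "blue": (-1, +1, -1),
    "green": (+1, +1, -1),
    "orange": (-1, -1, +1),
}

DEFAULT_CONTEXT_PROPS = (0.74, 0.12, 0.14)  # CpG, CHG, CHH
DEFAULT_BASELINE_METH = {"CpG": 0.70, "CHG": 0.05, "CHH": 0.05}


@dataclass
class SimulationTruth:
    """Ground-truth labels for one simulated input bundle."""

    de_genes: dict[str, float] = field(default_factory=dict)
    de_mirnas: dict[str, float] = field(default_factory=dict)
    dmr_regions: dict[str, float] = field(default_factory=dict)
    anticorr_pairs: set[tuple[str, str]] = field(default_factory=set)
    category_genes: dict[str, str] = field(default_factory=dict)
    seed: int = 0


@dataclass
class SyntheticAnnotation:
    """Gene models plus the chromosome sizes they were placed on."""

    genes: list[GeneModel]
    chrom_lengths: dict[str, int]

    def to_gene_annotation(self, promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH) -> GeneAnnotation:
        return GeneAnnotation(self.genes, promoter_halfwidth)

    def exonic_lengths(self) -> dict[str, int]:
        return {g.gene_id: g.exonic_length for g in self.genes}


def _group_samples(n_per_group: int) -> tuple[list[str], dict[str, str]]:
    names = [f"control_{i + 1}" for i in range(n_per_group)] + [
        f"treated_{i + 1}" for i in range(n_per_group)
    ]
    labels = {s: ("control" if s.startswith("control") else "treated") for s in names}
    return names, labels


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    n_genes: int,
    n_chroms: int = 2,
    chrom_len: int = 1_000_000,
    intergenic_gap: int = 1_000,
    seed: int = 0,
    prefix: str = "gene",
    gene_length_range: tuple[int, int] = (2_000, 8_000),
    max_exons: int = 4,
) -> SyntheticAnnotation:
    """Place non-overlapping gene models with strand, TSS and exon structure.

    Genes are laid out left to right per chromosome, separated by at least
    ``intergenic_gap`` bp (with random extra spacing); a
    :class:`~triomix.errors.CapacityError` is raised when they do not fit.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    width = len(str(n_genes))
    genes: list[GeneModel] = []
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0) for i in range(n_chroms)]
    gid = 0
    for chrom, n_here in zip(chroms, per_chrom):
        cursor = intergenic_gap
        for _ in range(n_here):
            length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
            extra = int(rng.integers(0, intergenic_gap + 1))
            start = cursor + extra
            end = start + length
            if end + intergenic_gap > chrom_len:
                raise CapacityError(
                    f"cannot place {n_genes} genes on {n_chroms} chromosome(s) of {chrom_len} bp "
                    f"with {intergenic_gap} bp gaps"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, max_exons + 1))
            exons = _cut_exons(rng, start, end, n_exons)
            gid += 1
            genes.append(GeneModel(f"{prefix}_{gid:0{width}d}", chrom, strand, start, end, exons))
            cursor = end + intergenic_gap
    return SyntheticAnnotation(genes, {c: chrom_len for c in chroms})


def _cut_exons(rng: np.random.Generator, start: int, end: int, n_exons: int) -> tuple[tuple[int, int], ...]:
    if n_exons == 1:
        return ((start, end),)
    # 2*n_exons - 2 interior boundaries; first and last segments are exons
    n_cuts = 2 * n_exons - 2
    cuts = np.sort(rng.choice(np.arange(start + 1, end), size=n_cuts, replace=False))
    bounds = [start, *cuts.tolist(), end]
    return tuple((bounds[i], bounds[i + 1]) for i in range(0, len(bounds) - 1, 2))


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(
    feature_ids: Sequence[str] | SyntheticAnnotation,
    n_per_group: int,
    planted: Mapping[str, float] | None = None,
    baseline_mean: float = 100.0,
    dispersion: float = 0.05,
    seed: int = 0,
    libsize_sigma: float = 0.1,
    layer: str = "gene",
) -> tuple[CountMatrix, SimulationTruth]:
    """Negative-binomial count matrix with planted log2 fold changes.

    Non-planted features share ``baseline_mean`` across groups; a planted
    feature's treated-group mean is ``baseline_mean * 2**log2fc``.  Counts are
    gamma-Poisson with shape 1/dispersion; library sizes are log-normal
    multipliers (sigma = ``libsize_sigma``) around 1.
    """
    if dispersion <= 0:
        raise ValidationError("dispersion must be > 0")
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    if isinstance(feature_ids, SyntheticAnnotation):
        feature_ids = [g.gene_id for g in feature_ids.genes]
    planted = dict(planted or {})
    unknown = set(planted) - set(feature_ids)
    if unknown:
        raise ValidationError(f"planted features not in feature list: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    samples, labels = _group_samples(n_per_group)
    lib = np.exp(rng.normal(0.0, libsize_sigma, size=len(samples)))
    lfc = np.array([planted.get(f, 0.0) for f in feature_ids])
    mu_control = np.full(len(feature_ids), baseline_mean)
    mu_treated = baseline_mean * np.power(2.0, lfc)
    mu = np.column_stack(
        [mu_control if labels[s] == "control" else mu_treated for s in samples]
    )
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion) * lib[None, :]
    counts = rng.poisson(lam)
    frame = pd.DataFrame(counts, index=pd.Index(list(feature_ids), name="feature_id"),
                         columns=samples)
    truth = SimulationTruth(seed=seed)
    if layer == "mirna":
        truth.de_mirnas = {f: v for f, v in planted.items() if v != 0}
    else:
        truth.de_genes = {f: v for f, v in planted.items() if v != 0}
    return CountMatrix(frame, labels), truth


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_methylation(
    annotation: SyntheticAnnotation,
    region_size: int = 100,
    coverage_mean: float = 30.0,
    baseline_meth: Mapping[str, float] | None = None,
    planted_dmrs: Mapping[str, float] | None = None,
    n_per_group: int = 6,
    n_background: int = 200,
    context_props: tuple[float, float, float] = DEFAULT_CONTEXT_PROPS,
    promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH,
    seed: int = 0,
) -> tuple[MethylRegionTable, SimulationTruth, dict[str, str]]:
    """Per-region binomial methylation counts with promoter-planted shifts.

    ``planted_dmrs`` maps gene id -> log-odds shift applied to the treated
    group of a region placed wholly inside that gene's promoter window,
    centred on the TSS.  Background regions are placed uniformly at random
    and keep their baseline methylation (by context) in both groups.

    Returns the region table, the truth (region id -> planted shift) and a
    map from planted region id to its gene.
    """
    baseline_meth = dict(baseline_meth or DEFAULT_BASELINE_METH)
    for ctx, frac in baseline_meth.items():
        if not 0.0 < frac < 1.0:
            raise ValidationError(f"baseline methylation for {ctx} must be in (0, 1)")
    if coverage_mean <= 0:
        raise ValidationError("coverage_mean must be > 0")
    planted_dmrs = dict(planted_dmrs or {})
    genes = {g.gene_id: g for g in annotation.genes}
    rng = np.random.default_rng(seed)
    samples, labels = _group_samples(n_per_group)

    meta: list[tuple[str, str, int, int, str]] = []  # id, chrom, start, end, context
    shifts: list[float] = []
    region_gene: dict[str, str] = {}
    for gene_id in sorted(planted_dmrs):
        if gene_id not in genes:
            raise ValidationError(
                f"planted region for unknown gene {gene_id!r}: not inside any promoter window"
            )
        g = genes[gene_id]
        chrom_len = annotation.chrom_lengths[g.chrom]
        start = int(np.clip(g.tss - region_size // 2,
                            max(0, g.tss - promoter_halfwidth),
                            min(chrom_len, g.tss + promoter_halfwidth) - region_size))
        rid = f"dmr_{gene_id}"
        meta.append((rid, g.chrom, start, start + region_size, "CpG"))
        shifts.append(float(planted_dmrs[gene_id]))
        region_gene[rid] = gene_id

    chroms = sorted(annotation.chrom_lengths)
    contexts = np.array(["CpG", "CHG", "CHH"])
    bg_ctx = rng.choice(contexts, size=n_background, p=np.asarray(context_props))
    width = len(str(max(n_background, 1)))
    for i in range(n_background):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, annotation.chrom_lengths[chrom] - region_size))
        meta.append((f"bg_{i + 1:0{width}d}", chrom, start, start + region_size, str(bg_ctx[i])))
        shifts.append(0.0)

    base_logit = np.array([_logit(baseline_meth[m[4]]) for m in meta])
    shift_arr = np.array(shifts)
    n_regions = len(meta)
    m_mat = np.zeros((n_regions, len(samples)), dtype=int)
    u_mat = np.zeros_like(m_mat)
    for j, s in enumerate(samples):
        p = _logistic(base_logit + (shift_arr if labels[s] == "treated" else 0.0))
        cov = rng.poisson(coverage_mean, size=n_regions)
        m = rng.binomial(cov, p)
        m_mat[:, j] = m
        u_mat[:, j] = cov - m
    idx = pd.Index([m[0] for m in meta], name="region_id")
    regions = pd.DataFrame(
        [(m[1], m[2], m[3], m[4]) for m in meta], index=idx,
        columns=["chrom", "start", "end", "context"],
    )
    table = MethylRegionTable(
        regions,
        pd.DataFrame(m_mat, index=idx, columns=samples),
        pd.DataFrame(u_mat, index=idx, columns=samples),
        labels,
    )
    truth = SimulationTruth(
        dmr_regions={rid: s for rid, s in zip(idx, shifts) if s != 0.0}, seed=seed
    )
    return table, truth, region_gene


# ---------------------------------------------------------------------------
# target table
# ---------------------------------------------------------------------------

def simulate_target_table(
    de_mirnas: Mapping[str, float],
    de_genes: Mapping[str, float],
    n_decoys: int = 0,
    seed: int = 0,
    pairs: set[tuple[str, str]] | None = None,
    decoy_mirnas: Sequence[str] | None = None,
    decoy_genes: Sequence[str] | None = None,
) -> tuple[list[TargetPair], set[tuple[str, str]]]:
    """miRNA -> gene interaction table containing the planted
    anti-correlation-consistent pairs plus decoys with no relationship.

    When ``pairs`` is not given, each differential gene is paired round-robin
    with a differential miRNA of opposite sign.  Decoys draw from
    ``decoy_mirnas`` x ``decoy_genes`` (synthetic ids are invented if absent).
    """
    rng = np.random.default_rng(seed)
    if pairs is None:
        pairs = set()
        up_mirs = sorted(m for m, v in de_mirnas.items() if v > 0)
        down_mirs = sorted(m for m, v in de_mirnas.items() if v < 0)
        for i, (gene, lfc) in enumerate(sorted(de_genes.items())):
            pool = down_mirs if lfc > 0 else up_mirs
            if not pool:
                raise ValidationError(f"no opposite-direction miRNA available for {gene!r}")
            pairs.add((pool[i % len(pool)], gene))
    table = [TargetPair(m, g, "synthetic") for m, g in sorted(pairs)]
    if n_decoys > 0:
        mir_pool = list(decoy_mirnas or [f"decoy_mir_{i + 1}" for i in range(max(4, n_decoys))])
        gene_pool = list(decoy_genes or [f"decoy_gene_{i + 1}" for i in range(max(4, n_decoys))])
        made = 0
        existing = set(pairs)
        while made < n_decoys:
            m = mir_pool[int(rng.integers(0, len(mir_pool)))]
            g = gene_pool[int(rng.integers(0, len(gene_pool)))]
            if (m, g) in existing:
                continue
            existing.add((m, g))
            table.append(TargetPair(m, g, "synthetic"))
            made += 1
    return table, set(pairs)


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

@dataclass
class ScenarioBundle:
    """One complete synthetic input set for the full pipeline."""

    annotation: SyntheticAnnotation
    gene_counts: CountMatrix
    mirna_counts: CountMatrix
    meth_table: MethylRegionTable
    target_pairs: list[TargetPair]
    gene_fpkm: ExpressionMatrix
    mirna_cpm: ExpressionMatrix
    truth: SimulationTruth


def cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Counts per million mapped reads (depth-normalized expression)."""
    totals = counts.values.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        raise ValidationError("zero library total")
    vals = counts.values.to_numpy(dtype=float) / totals[None, :] * 1e6
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.values.index, columns=counts.values.columns),
        dict(counts.group_labels),
    )


def build_scenario(
    category_spec: Mapping[str, int],
    seed: int = 0,
    n_background_genes: int = 80,
    n_background_mirnas: int = 25,
    n_per_group_expr: int = 5,
    n_per_group_meth: int = 6,
    n_background_regions: int = 200,
    n_decoy_pairs: int = 30,
    baseline_mean: float = 200.0,
    dispersion: float = 0.02,
    coverage_mean: float = 30.0,
    effect_lfc: float = 5.0,
    meth_shift: float = 7.0,
    chrom_len: int = 2_000_000,
    intergenic_gap: int = 6_000,
) -> ScenarioBundle:
    """Plant genes in the four regulatory categories and emit all inputs.

    Defaults reflect the emulated study design: 5 expression replicates and
    6 methylation replicates per group, with effect sizes an order of
    magnitude above the calling thresholds (|log2FC| 5 for counts, 7 log-odds
    for promoter methylation) so that, at low dispersion, the pipeline
    recovers the planted category assignment exactly.
    """
    for cat in category_spec:
        if cat not in CATEGORIES:
            raise ValidationError(f"unknown category {cat!r}; expected one of {CATEGORIES}")
        if category_spec[cat] < 0:
            raise ValidationError("category counts must be >= 0")
    master = np.random.default_rng(seed)
    child = [int(s) for s in master.integers(0, 2**31 - 1, size=6)]

    n_planted = sum(category_spec.values())
    n_genes = n_background_genes + n_planted
    annotation = generate_annotation(
        n_genes, n_chroms=2, chrom_len=chrom_len, intergenic_gap=intergenic_gap,
        seed=child[0], prefix="gene",
    )
    gene_ids = [g.gene_id for g in annotation.genes]
    mirna_ids = [f"mir_{i + 1:03d}" for i in range(n_background_mirnas + n_planted)]

    chosen_genes = master.choice(gene_ids, size=n_planted, replace=False)
    chosen_mirs = master.choice(mirna_ids, size=n_planted, replace=False)

    category_genes: dict[str, str] = {}
    de_genes: dict[str, float] = {}
    de_mirnas: dict[str, float] = {}
    planted_dmrs: dict[str, float] = {}
    pairs: set[tuple[str, str]] = set()
    k = 0
    for cat in CATEGORIES:
        for _ in range(category_spec.get(cat, 0)):
            gene = str(chosen_genes[k])
            mir = str(chosen_mirs[k])
            dmr_sign, gene_sign, mir_sign = CATEGORY_SIGNS[cat]
            category_genes[gene] = cat
            de_genes[gene] = gene_sign * effect_lfc
            de_mirnas[mir] = mir_sign * effect_lfc
            planted_dmrs[gene] = dmr_sign * meth_shift
            pairs.add((mir, gene))
            k += 1

    gene_counts, _ = simulate_counts(
        gene_ids, n_per_group_expr, de_genes, baseline_mean, dispersion, seed=child[1]
    )
    mirna_counts, _ = simulate_counts(
        mirna_ids, n_per_group_expr, de_mirnas, baseline_mean, dispersion,
        seed=child[2], layer="mirna",
    )
    meth_table, meth_truth, _region_gene = simulate_methylation(
        annotation, coverage_mean=coverage_mean, planted_dmrs=planted_dmrs,
        n_per_group=n_per_group_meth, n_background=n_background_regions, seed=child[3],
    )
    bg_mirs = [m for m in mirna_ids if m not in de_mirnas]
    bg_genes = [g for g in gene_ids if g not in de_genes]
    target_pairs, _ = simulate_target_table(
        de_mirnas, de_genes, n_decoys=n_decoy_pairs, seed=child[4], pairs=pairs,
        decoy_mirnas=bg_mirs, decoy_genes=bg_genes,
    )
    gene_fpkm = fpkm(gene_counts, annotation.exonic_lengths())
    mirna_cpm = cpm(mirna_counts)

    truth = SimulationTruth(
        de_genes=de_genes,
        de_mirnas=de_mirnas,
        dmr_regions=meth_truth.dmr_regions,
        anticorr_pairs=pairs,
        category_genes=category_genes,
        seed=seed,
    )
    return ScenarioBundle(
        annotation, gene_counts, mirna_counts, meth_table, target_pairs,
        gene_fpkm, mirna_cpm, truth,
    )
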