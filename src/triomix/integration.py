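"""Cross-omics integration: promoter-methylation/expression inverse linking,
miRNA-target anti-correlation filtering, and the four-way regulatory-category
classification of genes carrying evidence in all three layers.

A gene enters the three-level integration when (i) a significant
differentially methylated region sits in its promoter window, (ii) the gene
itself is differentially expressed, and (iii) a differentially expressed
miRNA of opposite direction targets it with a sufficiently negative Pearson
correlation of expression across samples.  The joint sign pattern of the
three layers places each gene-miRNA pair in one of four regulatory
categories: two "consistent" patterns in which promoter methylation and
miRNA pressure point the same way as the expression change, and two
"inconsistent" ones in which the methylation state opposes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .differential import DifferentialRecord
from .errors import ValidationError
from .io_formats import ExpressionMatrix, TargetPair

DEFAULT_PCC_CUT = -0.5
DEFAULT_P_CUT = 0.05


class RegulatoryCategory(Enum):
    """Four-way joint sign pattern of (promoter methylation, gene, miRNA)."""

    CONSISTENT_HYPER_DOWN = "red"      # hypermethylated, gene down, miRNA up
    CONSISTENT_HYPO_UP = "blue"        # hypomethylated, gene up, miRNA down
    INCONSISTENT_HYPER_UP = "green"    # hypermethylated, gene up, miRNA down
    INCONSISTENT_HYPO_DOWN = "orange"  # hypomethylated, gene down, miRNA up

    @property
    def color(self) -> str:
        return self.value

    @property
    def consistent(self) -> bool:
        return self in (RegulatoryCategory.CONSISTENT_HYPER_DOWN,
                        RegulatoryCategory.CONSISTENT_HYPO_UP)


@dataclass(frozen=True)
class PromoterDmr:
    """A significant differentially methylated region assigned to a gene's promoter."""

    gene_id: str
    region_id: str
    log2fc: float
    p_value: float
    direction: str  # 'hyper' or 'hypo'

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValidationError("PromoterDmr direction must be 'hyper' or 'hypo'")


@dataclass(frozen=True)
class AnticorrInteraction:
    """A miRNA-target interaction with opposite differential directions and
    a Pearson anti-correlation of expression (NaN when supplied externally
    without expression data)."""

    mirna_id: str
    gene_id: str
    pcc: float
    pcc_p: float
    mirna_direction: str
    gene_direction: str
    demir_log2fc: float = math.nan
    demir_fdr: float = math.nan

    def __post_init__(self) -> None:
        if {self.mirna_direction, self.gene_direction} != {"up", "down"}:
            raise ValidationError("interaction directions must be opposite (up/down)")


@dataclass(frozen=True)
class DmrExpressionLink:
    """Two-level inverse link between a promoter methylation change and the
    expression change of the regulated feature (gene or miRNA host locus)."""

    feature_id: str
    region_id: str
    dmr_log2fc: float
    feature_log2fc: float


@dataclass(frozen=True)
class IntegrationTriple:
    """One gene x miRNA combination supported by all three omics layers."""

    gene_id: str
    region_id: str
    dmr_log2fc: float
    dmr_p: float
    deg_log2fc: float
    deg_fdr: float
    mirna_id: str
    demir_log2fc: float
    demir_fdr: float
    category: RegulatoryCategory


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p from the t-transform
    (n-2 degrees of freedom).  Constant vectors yield (nan, nan)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    r, p = stats.pearsonr(x, y)
    return (float(r), float(p))


# ---------------------------------------------------------------------------
# two-level links
# ---------------------------------------------------------------------------

def _inverse(dmr_direction: str, feature_direction: str) -> bool:
    return (dmr_direction == "up" and feature_direction == "down") or (
        dmr_direction == "down" and feature_direction == "up"
    )


def link_dmr_deg(
    promoter_dmrs: Sequence[PromoterDmr],
    degs: Sequence[DifferentialRecord],
) -> list[DmrExpressionLink]:
    """Pair promoter methylation changes with inversely regulated genes:
    hypermethylated promoter with a downregulated gene, or hypomethylated
    with an upregulated one."""
    deg_by_id = {r.feature_id: r for r in degs if r.direction != "ns"}
    links = []
    for dmr in promoter_dmrs:
        deg = deg_by_id.get(dmr.gene_id)
        if deg is None:
            continue
        dmr_dir = "up" if dmr.direction == "hyper" else "down"
        if _inverse(dmr_dir, deg.direction):
            links.append(DmrExpressionLink(dmr.gene_id, dmr.region_id, dmr.log2fc, deg.log2fc))
    return links


def link_dmr_demir(
    mirna_promoter_dmrs: Sequence[PromoterDmr],
    demirs: Sequence[DifferentialRecord],
) -> list[DmrExpressionLink]:
    """Inverse links between promoter methylation at miRNA host loci and the
    miRNAs' own expression; both inverse orientations (hyper/down and
    hypo/up) are emitted, treating the relationship as reciprocal."""
    return link_dmr_deg(mirna_promoter_dmrs, demirs)


def link_demir_targets(
    demirs: Sequence[DifferentialRecord],
    target_table: Sequence[TargetPair],
    degs: Sequence[DifferentialRecord],
    gene_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    pcc_cut: float = DEFAULT_PCC_CUT,
    p_cut: float = DEFAULT_P_CUT,
) -> list[AnticorrInteraction]:
    """Anti-correlation filter over miRNA-target candidates.

    Only pairs with opposite differential directions are tested; for those,
    the Pearson correlation is computed across all samples of both groups
    pooled, and an interaction is retained iff pcc < ``pcc_cut`` and
    p < ``p_cut`` (strict inequalities).
    """
    if gene_expr.sample_ids != mirna_expr.sample_ids:
        raise ValidationError("gene and miRNA expression matrices must share sample ordering")
    demir_by_id = {r.feature_id: r for r in demirs if r.direction != "ns"}
    deg_by_id = {r.feature_id: r for r in degs if r.direction != "ns"}
    out = []
    for pair in target_table:
        mir = demir_by_id.get(pair.mirna_id)
        deg = deg_by_id.get(pair.gene_id)
        if mir is None or deg is None or mir.direction == deg.direction:
            continue
        if pair.gene_id not in gene_expr.values.index:
            raise ValidationError(f"gene {pair.gene_id!r} absent from expression matrix")
        if pair.mirna_id not in mirna_expr.values.index:
            raise ValidationError(f"miRNA {pair.mirna_id!r} absent from expression matrix")
        r, p = pearson_with_p(
            mirna_expr.values.loc[pair.mirna_id], gene_expr.values.loc[pair.gene_id]
        )
        if not math.isnan(r) and r < pcc_cut and p < p_cut:
            out.append(
                AnticorrInteraction(pair.mirna_id, pair.gene_id, r, p,
                                    mir.direction, deg.direction)
            )
    return out


# ---------------------------------------------------------------------------
# three-level integration
# ---------------------------------------------------------------------------

_CATEGORY_BY_SIGNS: Mapping[tuple[str, str, str], RegulatoryCategory] = {
    ("hyper", "down", "up"): RegulatoryCategory.CONSISTENT_HYPER_DOWN,
    ("hypo", "up", "down"): RegulatoryCategory.CONSISTENT_HYPO_UP,
    ("hyper", "up", "down"): RegulatoryCategory.INCONSISTENT_HYPER_UP,
    ("hypo", "down", "up"): RegulatoryCategory.INCONSISTENT_HYPO_DOWN,
}


def classify_category(dmr_dir: str, deg_dir: str, demir_dir: str) -> RegulatoryCategory:
    """Map the three direction signs to a regulatory category.

    Only the four combinations with opposite gene and miRNA directions are
    admissible; the other four never reach integration because miRNA-gene
    opposition is a precondition of inclusion.
    """
    if dmr_dir not in ("hyper", "hypo") or deg_dir not in ("up", "down") or demir_dir not in ("up", "down"):
        raise ValidationError("directions must be hyper/hypo, up/down, up/down")
    key = (dmr_dir, deg_dir, demir_dir)
    if key not in _CATEGORY_BY_SIGNS:
        raise ValidationError(
            f"inadmissible sign combination {key}: gene and miRNA directions must be opposite"
        )
    return _CATEGORY_BY_SIGNS[key]


def integrate_three_level(
    promoter_dmrs: Sequence[PromoterDmr],
    degs: Sequence[DifferentialRecord],
    anticorr: Sequence[AnticorrInteraction],
) -> list[IntegrationTriple]:
    """Join the three evidence layers into per-(gene, miRNA) triples.

    Inputs are threshold-passing records.  A gene contributes one triple per
    anticorrelated miRNA; when several promoter regions hit the same gene the
    one with the smallest p-value is used.  The output is a subset of the
    Cartesian join: no triple lacks any layer.
    """
    best_dmr: dict[str, PromoterDmr] = {}
    for dmr in promoter_dmrs:
        cur = best_dmr.get(dmr.gene_id)
        if cur is None or (dmr.p_value, dmr.region_id) < (cur.p_value, cur.region_id):
            best_dmr[dmr.gene_id] = dmr
    deg_by_id = {r.feature_id: r for r in degs if r.direction != "ns"}
    triples = []
    for inter in anticorr:
        deg = deg_by_id.get(inter.gene_id)
        dmr = best_dmr.get(inter.gene_id)
        if deg is None or dmr is None:
            continue
        category = classify_category(dmr.direction, deg.direction, inter.mirna_direction)
        triples.append(
            IntegrationTriple(
                gene_id=inter.gene_id,
                region_id=dmr.region_id,
                dmr_log2fc=dmr.log2fc,
                dmr_p=dmr.p_value,
                deg_log2fc=deg.log2fc,
                deg_fdr=deg.fdr,
                mirna_id=inter.mirna_id,
                demir_log2fc=inter.demir_log2fc,
                demir_fdr=inter.demir_fdr,
                category=category,
            )
        )
    return triples


def attach_demir_stats(
    anticorr: Sequence[AnticorrInteraction], demirs: Sequence[DifferentialRecord]
) -> list[AnticorrInteraction]:
    """Copy interactions with the targeting miRNA's log2FC and FDR filled in,
    so the final triples carry every printed column."""
    import dataclasses

    by_id = {r.feature_id: r for r in demirs}
    out = []
    for inter in anticorr:
        rec = by_id.get(inter.mirna_id)
        if rec is not None:
            inter = dataclasses.replace(inter, demir_log2fc=rec.log2fc, demir_fdr=rec.fdr)
        out.append(inter)
    return out


def unique_genes(triples: Sequence[IntegrationTriple]) -> list[str]:
    return sorted({t.gene_id for t in triples})


def category_summary(triples: Sequence[IntegrationTriple]) -> dict[str, int]:
    """Unique-gene counts per category color plus consistent/inconsistent totals."""
    gene_cat: dict[str, RegulatoryCategory] = {}
    for t in triples:
        gene_cat[t.gene_id] = t.category
    counts = {c.value: 0 for c in RegulatoryCategory}
    for cat in gene_cat.values():
        counts[cat.value] += 1
    counts["consistent"] = sum(1 for c in gene_cat.values() if c.consistent)
    counts["inconsistent"] = sum(1 for c in gene_cat.values() if not c.consistent)
    counts["unique_genes"] = len(gene_cat)
    return counts
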