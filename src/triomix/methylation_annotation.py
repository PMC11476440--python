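"""Per-base methylation arithmetic, cytosine context classification, genomic
feature annotation of methylated regions, promoter-window assignment and FPKM.

The promoter of a gene is defined as the window of ``promoter_halfwidth`` bp
(default 2000) on each side of its strand-aware TSS, half-open in genome
coordinates.  A region overlapping a promoter window by at least 1 bp is
assigned to that gene's promoter; feature-class precedence is
promoter > exon > intron > intergenic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError
from .io_formats import CountMatrix, ExpressionMatrix, GeneModel

FEATURE_CLASSES = ("promoter", "exon", "intron", "intergenic")
DEFAULT_PROMOTER_HALFWIDTH = 2000

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ---------------------------------------------------------------------------
# methylation level
# ---------------------------------------------------------------------------

def methylation_fraction(methylated: int, unmethylated: int) -> float:
    """Fraction of methylated reads: methylated Cs / (methylated Cs + unmethylated Ts).

    Returns NaN (missing, never 0) when both counts are zero.
    """
    if methylated < 0 or unmethylated < 0:
        raise ValidationError("read counts must be non-negative")
    total = methylated + unmethylated
    if total == 0:
        return math.nan
    return methylated / total


def classify_context(sequence: str, position: int, strand: str = "+") -> str:
    """Classify a cytosine's sequence context as CpG, CHG or CHH (H = A/C/T).

    The context is read on the strand's own 5'->3' sequence: on ``-`` the
    reference base at ``position`` must be G and the downstream bases run
    leftward, complemented.  Fewer than two downstream bases at a contig edge
    fall back to CHH by convention.
    """
    seq = sequence.upper()
    if strand == "+":
        if position < 0 or position >= len(seq) or seq[position] != "C":
            raise ValidationError(f"position {position} is not a C on the + strand")
        nxt = seq[position + 1] if position + 1 < len(seq) else None
        nxt2 = seq[position + 2] if position + 2 < len(seq) else None
    elif strand == "-":
        if position < 0 or position >= len(seq) or seq[position] != "G":
            raise ValidationError(f"position {position} is not a C on the - strand")
        nxt = _COMPLEMENT.get(seq[position - 1]) if position - 1 >= 0 else None
        nxt2 = _COMPLEMENT.get(seq[position - 2]) if position - 2 >= 0 else None
    else:
        raise ValidationError("strand must be '+' or '-'")
    if nxt == "G":
        return "CpG"
    if nxt is None or nxt2 is None:
        return "CHH"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


# ---------------------------------------------------------------------------
# region tables
# ---------------------------------------------------------------------------

@dataclass
class MethylRegionTable:
    """Genomic regions with per-sample (methylated, unmethylated) read counts.

    ``regions`` is indexed by region id with columns chrom, start, end,
    context; ``meth`` and ``unmeth`` are regions x samples count frames
    sharing that index.
    """

    regions: pd.DataFrame
    meth: pd.DataFrame
    unmeth: pd.DataFrame
    group_labels: dict[str, str]

    def __post_init__(self) -> None:
        if not (self.regions.index.equals(self.meth.index) and self.meth.index.equals(self.unmeth.index)):
            raise ValidationError("region/meth/unmeth indexes must agree")
        if not list(self.meth.columns) == list(self.unmeth.columns):
            raise ValidationError("meth/unmeth sample columns must agree")
        if (self.meth.to_numpy() < 0).any() or (self.unmeth.to_numpy() < 0).any():
            raise ValidationError("negative methylation counts")
        if (self.regions["end"] <= self.regions["start"]).any():
            raise ValidationError("empty region interval")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meth.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.meth.columns if self.group_labels[s] == group]

    def totals(self) -> pd.DataFrame:
        return self.meth + self.unmeth

    def subset(self, region_ids) -> "MethylRegionTable":
        return MethylRegionTable(
            self.regions.loc[region_ids],
            self.meth.loc[region_ids],
            self.unmeth.loc[region_ids],
            dict(self.group_labels),
        )


def aggregate_to_tiles(
    per_sample: Mapping[str, pd.DataFrame],
    group_labels: Mapping[str, str],
    tile_size: int = 100,
) -> MethylRegionTable:
    """Aggregate per-position coverage records into fixed-width genomic tiles.

    ``per_sample`` maps sample id to a frame as returned by
    :func:`~triomix.io_formats.read_bismark_coverage`.  Tiles are aligned to
    multiples of ``tile_size``; positions missing from a sample contribute
    zero counts.  Context is not tracked at tile level and reported 'mixed'.
    """
    samples = list(per_sample)
    tiles: dict[tuple[str, int], dict[str, tuple[int, int]]] = {}
    for sample, frame in per_sample.items():
        starts = frame["start"].to_numpy()
        bins = (starts // tile_size).astype(int)
        grouped = (
            frame.assign(_bin=bins)
            .groupby(["chrom", "_bin"])[["count_m", "count_u"]]
            .sum()
        )
        for (chrom, b), row in grouped.iterrows():
            tiles.setdefault((chrom, int(b)), {})[sample] = (int(row["count_m"]), int(row["count_u"]))
    keys = sorted(tiles)
    region_ids, meta, m_rows, u_rows = [], [], [], []
    for chrom, b in keys:
        start, end = b * tile_size, (b + 1) * tile_size
        region_ids.append(f"{chrom}:{start}-{end}")
        meta.append((chrom, start, end, "mixed"))
        per = tiles[(chrom, b)]
        m_rows.append([per.get(s, (0, 0))[0] for s in samples])
        u_rows.append([per.get(s, (0, 0))[1] for s in samples])
    idx = pd.Index(region_ids, name="region_id")
    return MethylRegionTable(
        pd.DataFrame(meta, index=idx, columns=["chrom", "start", "end", "context"]),
        pd.DataFrame(m_rows, index=idx, columns=samples),
        pd.DataFrame(u_rows, index=idx, columns=samples),
        dict(group_labels),
    )


def coverage_filter(table: MethylRegionTable, min_reads: int = 5) -> MethylRegionTable:
    """Keep regions with coverage strictly exceeding ``min_reads`` in at least
    one replicate of *each* group."""
    totals = table.totals()
    g1 = table.samples_in_group("control")
    g2 = table.samples_in_group("treated")
    keep = (totals[g1].max(axis=1) > min_reads) & (totals[g2].max(axis=1) > min_reads)
    return table.subset(table.regions.index[keep])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterAssignment:
    """A region -> gene link with feature class and signed TSS distance.

    ``tss_distance`` is measured from the region midpoint to the gene's TSS in
    gene orientation: negative values lie upstream of the TSS.
    """

    region_id: str
    gene_id: str
    feature_class: str
    tss_distance: float


class GeneAnnotation:
    """Indexed collection of gene models for interval queries.

    Builds per-chromosome interval trees over promoter windows, exons and
    gene spans; promoter windows are clipped at zero.
    """

    def __init__(self, genes: Sequence[GeneModel],
                 promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH) -> None:
        self.genes = {g.gene_id: g for g in genes}
        if len(self.genes) != len(genes):
            raise ValidationError("duplicate gene ids in annotation")
        self.promoter_halfwidth = promoter_halfwidth
        self._promoters: dict[str, IntervalTree] = {}
        self._exons: dict[str, IntervalTree] = {}
        self._spans: dict[str, IntervalTree] = {}
        for g in genes:
            lo = max(0, g.tss - promoter_halfwidth)
            hi = g.tss + promoter_halfwidth
            self._promoters.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g.gene_id)
            self._spans.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
            for (s, e) in g.exons:
                self._exons.setdefault(g.chrom, IntervalTree()).addi(s, e, g.gene_id)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._spans)

    def gene_ids(self) -> list[str]:
        return sorted(self.genes)

    def tss_distance(self, gene_id: str, midpoint: float) -> float:
        g = self.genes[gene_id]
        d = midpoint - g.tss
        return d if g.strand == "+" else -d

    def _nearest(self, chrom: str, midpoint: float, candidates) -> str:
        return min(candidates, key=lambda gid: (abs(self.tss_distance(gid, midpoint)), gid))

    def annotate_region(self, region_id: str, chrom: str, start: int, end: int) -> PromoterAssignment:
        """Assign one region to exactly one feature class and one gene.

        Precedence: promoter > exon > intron > intergenic; within a class the
        gene with minimal absolute TSS distance wins, ties broken by
        lexicographic gene id.  Intergenic regions still report the nearest
        gene on the chromosome.
        """
        if chrom not in self._spans:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        mid = (start + end) / 2
        hits = self._promoters.get(chrom, IntervalTree()).overlap(start, end)
        if hits:
            gid = self._nearest(chrom, mid, {h.data for h in hits})
            return PromoterAssignment(region_id, gid, "promoter", self.tss_distance(gid, mid))
        hits = self._exons.get(chrom, IntervalTree()).overlap(start, end)
        if hits:
            gid = self._nearest(chrom, mid, {h.data for h in hits})
            return PromoterAssignment(region_id, gid, "exon", self.tss_distance(gid, mid))
        hits = self._spans.get(chrom, IntervalTree()).overlap(start, end)
        if hits:
            gid = self._nearest(chrom, mid, {h.data for h in hits})
            return PromoterAssignment(region_id, gid, "intron", self.tss_distance(gid, mid))
        chrom_genes = [g.gene_id for g in self.genes.values() if g.chrom == chrom]
        gid = self._nearest(chrom, mid, chrom_genes)
        return PromoterAssignment(region_id, gid, "intergenic", self.tss_distance(gid, mid))


def annotate_regions(table: MethylRegionTable, annotation: GeneAnnotation) -> list[PromoterAssignment]:
    return [
        annotation.annotate_region(rid, row.chrom, int(row.start), int(row.end))
        for rid, row in zip(table.regions.index, table.regions.itertuples(index=False))
    ]


def feature_class_distribution(assignments: Sequence[PromoterAssignment]) -> pd.Series:
    """Proportions of regions per feature class (sums to 1)."""
    if not assignments:
        raise ValidationError("no assignments provided")
    counts = pd.Series(0.0, index=pd.Index(FEATURE_CLASSES, name="feature_class"))
    for a in assignments:
        counts[a.feature_class] += 1
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

def fpkm(counts: CountMatrix, feature_lengths: Mapping[str, int]) -> ExpressionMatrix:
    """Fragments per kilobase of feature per million mapped fragments.

    value = count / (length/1e3 * library_total/1e6), with the library total
    taken as the per-sample column sum of the count matrix.
    """
    lengths = np.array([feature_lengths[f] for f in counts.feature_ids], dtype=float)
    if (lengths <= 0).any():
        raise ValidationError("feature lengths must be positive")
    totals = counts.values.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        raise ValidationError("zero library total")
    vals = counts.values.to_numpy(dtype=float) / (lengths[:, None] / 1e3) / (totals[None, :] / 1e6)
    frame = pd.DataFrame(vals, index=counts.values.index, columns=counts.values.columns)
    return ExpressionMatrix(frame, dict(counts.group_labels))
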