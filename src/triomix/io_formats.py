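"""Readers and writers for every external format the pipeline touches.

Internal coordinates are 0-based half-open throughout the package; conversion
to and from 1-based inclusive dialects (Bismark coverage files) happens only
at the I/O boundary in this module.  All readers validate strictly and raise
:class:`~triomix.errors.FormatError` / :class:`~triomix.errors.ValidationError`
rather than silently coercing malformed input.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: allowed experimental group labels, in (reference, contrast) order
GROUPS = ("control", "treated")


# ---------------------------------------------------------------------------
# in-memory containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Integer read counts, features x samples, with a group label per sample.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one integer column per sample.
    group_labels
        Mapping sample id -> ``"control"`` or ``"treated"``.
    """

    values: pd.DataFrame
    group_labels: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if not np.issubdtype(np.asarray(self.values.values).dtype, np.number):
            raise ValidationError("counts must be numeric")
        arr = self.values.to_numpy()
        if (arr < 0).any():
            raise ValidationError("negative counts are not allowed")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integers")
        for s in self.values.columns:
            g = self.group_labels.get(s)
            if g not in GROUPS:
                raise ValidationError(f"sample {s!r} has no valid group label (got {g!r})")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_labels[s] == group]


@dataclass
class ExpressionMatrix:
    """Real-valued normalized expression (FPKM or CPM), features x samples."""

    values: pd.DataFrame
    group_labels: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate feature ids in expression matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS and exon structure.

    The TSS equals the span start on the ``+`` strand and ``span end - 1`` on
    the ``-`` strand.  Exons are 0-based half-open, sorted and non-overlapping.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.start < self.end:
            raise ValidationError(f"{self.gene_id}: empty span")
        prev_end = self.start
        for (s, e) in self.exons:
            if s < prev_end or e > self.end or s >= e:
                raise ValidationError(f"{self.gene_id}: exons must be sorted, disjoint and inside the span")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class TargetPair:
    """A miRNA -> target-gene interaction from a TarBase-like table."""

    mirna_id: str
    gene_id: str
    evidence_tag: str = ""

    def __post_init__(self) -> None:
        if not self.mirna_id or not self.gene_id:
            raise ValidationError("TargetPair ids must be non-empty")


# ---------------------------------------------------------------------------
# count / expression matrices
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path, group_map: Mapping[str, str]) -> CountMatrix:
    """Read a TSV count matrix (feature id column + one column per sample).

    The header row names the samples; every sample must appear in
    ``group_map``.  Rows with the wrong number of columns, negative or
    non-integer counts, and duplicate feature ids are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: header must name at least one sample")
        samples = header[1:]
        for s in samples:
            if s not in group_map:
                raise ValidationError(f"{path}: sample {s!r} missing from group map")
        feats: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(header)} columns, got {len(parts)}"
                )
            feats.append(parts[0])
            try:
                vals = [int(v) for v in parts[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer count") from exc
            rows.append(vals)
    frame = pd.DataFrame(rows, index=pd.Index(feats, name="feature_id"), columns=samples)
    return CountMatrix(frame, {s: group_map[s] for s in samples})


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    frame = matrix.values.copy()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t")


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.values.copy()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", float_format="%.6g")


def read_expression_matrix(path: str | Path, group_map: Mapping[str, str]) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(frame, {s: group_map[s] for s in frame.columns})


# ---------------------------------------------------------------------------
# Bismark coverage
# ---------------------------------------------------------------------------

def read_bismark_coverage(path: str | Path) -> pd.DataFrame:
    """Read a 6-column Bismark ``.cov`` file into per-position records.

    Input positions are 1-based inclusive; the returned frame carries 0-based
    half-open ``start``/``end``.  A methylation percentage inconsistent with
    the counts beyond 0.1 raises a warning (the counts win); negative counts
    are fatal.  Positions with zero total coverage are retained with a NaN
    ``fraction``.

    Returns a DataFrame with columns
    ``chrom, start, end, fraction, count_m, count_u``.
    """
    path = Path(path)
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise FormatError(f"{path}: line {lineno}: expected 6 columns, got {len(parts)}")
            chrom, start1, end1, pct, m, u = parts
            try:
                start1, end1 = int(start1), int(end1)
                pct = float(pct)
                m, u = int(m), int(u)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: malformed fields") from exc
            if m < 0 or u < 0:
                raise ValidationError(f"{path}: line {lineno}: negative counts")
            total = m + u
            frac = m / total if total > 0 else np.nan
            if total > 0 and abs(pct - 100.0 * frac) > 0.1:
                warnings.warn(
                    f"{path}: line {lineno}: stated methylation {pct}% inconsistent with "
                    f"counts {m}/{total} (expected {100.0 * frac:.1f}%)",
                    stacklevel=2,
                )
            recs.append((chrom, start1 - 1, end1, frac, m, u))
    return pd.DataFrame(
        recs, columns=["chrom", "start", "end", "fraction", "count_m", "count_u"]
    )


def write_bismark_coverage(frame: pd.DataFrame, path: str | Path) -> None:
    """Write per-position/region records as Bismark-style coverage (1-based inclusive)."""
    with open(path, "w") as fh:
        for row in frame.itertuples(index=False):
            total = row.count_m + row.count_u
            pct = 100.0 * row.count_m / total if total > 0 else 0.0
            fh.write(
                f"{row.chrom}\t{row.start + 1}\t{row.end}\t{pct:.6g}\t{row.count_m}\t{row.count_u}\n"
            )


# ---------------------------------------------------------------------------
# target table, GMT, edge lists, differential records
# ---------------------------------------------------------------------------

def read_target_table(path: str | Path) -> list[TargetPair]:
    """Read a miRNA->gene interaction TSV, keeping unique (miRNA, gene) pairs.

    The first two columns are miRNA and gene ids; a third column, when
    present, is a free-text evidence tag.  Duplicate pairs (e.g. the same
    interaction under two evidence tags) collapse to one, keeping the first.
    """
    path = Path(path)
    pairs: list[TargetPair] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            return []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: expected >=2 columns")
            mirna, gene = parts[0].strip(), parts[1].strip()
            if not mirna or not gene:
                raise ValidationError(f"{path}: line {lineno}: empty id field")
            key = (mirna, gene)
            if key in seen:
                continue
            seen.add(key)
            pairs.append(TargetPair(mirna, gene, parts[2] if len(parts) > 2 else ""))
    return pairs


def write_target_table(pairs: Iterable[TargetPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene_id\tevidence\n")
        for p in pairs:
            fh.write(f"{p.mirna_id}\t{p.gene_id}\t{p.evidence_tag}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name, description, members. Duplicate names error."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT needs name, description, >=1 member")
            name = parts[0]
            if name in sets:
                raise ValidationError(f"{path}: duplicate gene-set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, ""] + sorted(members)) + "\n")


def write_edge_list(network, path: str | Path) -> None:
    """Write a directed network as a TSV edge list (source, target, weight, p, significant)."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\tp\tsignificant\n")
        for u, v, data in sorted(network.edges(data=True)):
            fh.write(
                f"{u}\t{v}\t{data.get('weight', float('nan')):.6g}\t"
                f"{data.get('p', float('nan')):.6g}\t{int(data.get('significant', True))}\n"
            )


def read_edge_list(path: str | Path):
    """Inverse of :func:`write_edge_list`; returns a ``networkx.DiGraph``."""
    import networkx as nx

    g = nx.DiGraph()
    frame = pd.read_csv(path, sep="\t")
    for row in frame.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=float(row.weight), p=float(row.p),
                   significant=bool(row.significant))
    return g


def write_records(records: Sequence, path: str | Path) -> None:
    """Write a sequence of dataclass records (differential results etc.) as TSV."""
    if not records:
        Path(path).write_text("")
        return
    frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_records_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene annotation (BED12 native, minimal GTF accepted)
# ---------------------------------------------------------------------------

def write_annotation_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12 (exons as blocks); coordinates stay 0-based half-open."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes},\t{starts},\n"
            )


def read_annotation_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise FormatError(f"{path}: line {lineno}: BED12 needs 12 columns")
            chrom, start, end, name, _score, strand = parts[:6]
            start, end = int(start), int(end)
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            exons = tuple((start + off, start + off + sz) for off, sz in zip(offsets, sizes))
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    return genes


def read_annotation_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GTF restricted to ``exon`` features with a
    ``gene_id`` attribute (1-based inclusive coordinates, converted here)."""
    by_gene: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}: line {lineno}: GTF needs 9 columns")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = parts[:9]
            if feature != "exon":
                continue
            gene_id = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gene_id = chunk.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                raise FormatError(f"{path}: line {lineno}: exon without gene_id attribute")
            rec = by_gene.setdefault(gene_id, {"chrom": chrom, "strand": strand, "exons": []})
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise ValidationError(f"{path}: gene {gene_id!r} spans chromosomes or strands")
            rec["exons"].append((int(start1) - 1, int(end1)))
    genes = []
    for gene_id, rec in by_gene.items():
        exons = tuple(sorted(rec["exons"]))
        genes.append(
            GeneModel(gene_id, rec["chrom"], rec["strand"], exons[0][0], exons[-1][1], exons)
        )
    return genes


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Dispatch on file extension: ``.bed`` -> BED12, ``.gtf`` -> GTF."""
    path = Path(path)
    if path.suffix == ".gtf":
        return read_annotation_gtf(path)
    return read_annotation_bed12(path)
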