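"""Per-layer differential calling: genes and miRNAs from negative-binomial
count models, methylated regions from a binomial-logistic likelihood-ratio
test, with Benjamini-Hochberg FDR control and inclusive threshold rules.

Defaults mirror the study design this package re-implements: genes and
miRNAs are called at |log2FC| >= 0.5 with FDR <= 0.05, methylated regions at
|log2FC| >= 1 (log2 odds ratio) with raw p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_formats import CountMatrix
from .methylation_annotation import MethylRegionTable

LAYERS = ("gene", "mirna", "methyl-region")
DIRECTIONS = ("up", "down", "ns")


@dataclass(frozen=True)
class DifferentialRecord:
    """One feature's differential result for any omics layer.

    For methylated regions ``log2fc`` is the log2 odds ratio of methylation
    (treated vs control); for count layers it is the log2 ratio of normalized
    group means.
    """

    feature_id: str
    layer: str
    log2fc: float
    p_value: float
    fdr: float
    direction: str = "ns"


@dataclass(frozen=True)
class ThresholdSet:
    """Significance rule for one layer: |log2fc| >= lfc_cut and sig <= sig_cut,
    where ``sig_kind`` selects raw p or BH FDR. Comparisons are inclusive."""

    lfc_cut: float
    sig_cut: float
    sig_kind: str = "fdr"

    def __post_init__(self) -> None:
        if self.lfc_cut < 0:
            raise ValidationError("lfc_cut must be >= 0")
        if not 0 < self.sig_cut <= 1:
            raise ValidationError("sig_cut must be in (0, 1]")
        if self.sig_kind not in ("p", "fdr"):
            raise ValidationError("sig_kind must be 'p' or 'fdr'")


DEG_THRESHOLDS = ThresholdSet(0.5, 0.05, "fdr")
DEMIR_THRESHOLDS = ThresholdSet(0.5, 0.05, "fdr")
DMR_THRESHOLDS = ThresholdSet(1.0, 0.05, "p")


# ---------------------------------------------------------------------------
# normalization and multiplicity
# ---------------------------------------------------------------------------

def normalize_libraries(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios library size factors, rescaled to geometric mean 1.

    The geometric-mean reference uses only features with nonzero counts in
    every sample (a zero anywhere makes the ratio degenerate); an all-zero
    matrix is an error.
    """
    arr = counts.values.to_numpy(dtype=float)
    usable = (arr > 0).all(axis=1)
    if not usable.any():
        raise ValidationError("no feature with nonzero counts in every sample")
    logs = np.log(arr[usable])
    log_ref = logs.mean(axis=1)
    factors = np.exp(np.median(logs - log_ref[:, None], axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.values.columns, name="size_factor")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# count layers (genes, miRNAs)
# ---------------------------------------------------------------------------

def test_counts(
    counts: CountMatrix,
    layer: str = "gene",
    pseudocount: float = 0.5,
    dispersion_floor: float = 0.01,
    min_norm_mean: float = 1.0,
) -> list[DifferentialRecord]:
    """Negative-binomial Wald test of treated vs control per feature.

    Counts are scaled by median-of-ratios size factors.  Features whose
    normalized mean falls below ``min_norm_mean`` are removed before testing
    (independent low-count filter).  log2FC is computed on normalized group
    means with a pseudocount; the Wald statistic uses a method-of-moments
    NB dispersion (floored at ``dispersion_floor``) and is referred to a t
    distribution with n1+n2-2 degrees of freedom as a small-sample
    correction.  FDR is Benjamini-Hochberg over the tested features.
    """
    g1 = counts.samples_in_group("control")
    g2 = counts.samples_in_group("treated")
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("need >=2 samples per group")
    sf = normalize_libraries(counts)
    norm = counts.values.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    norm = pd.DataFrame(norm, index=counts.values.index, columns=counts.values.columns)

    keep = norm.mean(axis=1) >= min_norm_mean
    norm = norm.loc[keep]
    if norm.empty:
        return []

    a1, a2 = norm[g1].to_numpy(), norm[g2].to_numpy()
    n1, n2 = a1.shape[1], a2.shape[1]
    m1, m2 = a1.mean(axis=1), a2.mean(axis=1)
    v1 = a1.var(axis=1, ddof=1)
    v2 = a2.var(axis=1, ddof=1)

    lfc = np.log2((m2 + pseudocount) / (m1 + pseudocount))

    # pooled method-of-moments NB dispersion: var = mu + alpha mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha1 = np.where(m1 > 0, (v1 - m1) / np.maximum(m1, 1e-12) ** 2, 0.0)
        alpha2 = np.where(m2 > 0, (v2 - m2) / np.maximum(m2, 1e-12) ** 2, 0.0)
    alpha = np.maximum(((n1 - 1) * alpha1 + (n2 - 1) * alpha2) / (n1 + n2 - 2), dispersion_floor)

    var_mean1 = (m1 + alpha * m1**2) / n1
    var_mean2 = (m2 + alpha * m2**2) / n2
    se = np.sqrt(
        var_mean1 / (m1 + pseudocount) ** 2 + var_mean2 / (m2 + pseudocount) ** 2
    ) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(wald), df=n1 + n2 - 2)
    fdr = bh_adjust(p)

    return [
        DifferentialRecord(fid, layer, float(l), float(pv), float(q))
        for fid, l, pv, q in zip(norm.index, lfc, p, fdr)
    ]


def classify(records: Sequence[DifferentialRecord], thresholds: ThresholdSet) -> list[DifferentialRecord]:
    """Set each record's direction: up / down when both the fold-change and
    significance thresholds are met (inclusively), else ns."""
    out = []
    for r in records:
        sig = r.p_value if thresholds.sig_kind == "p" else r.fdr
        if sig <= thresholds.sig_cut and r.log2fc >= thresholds.lfc_cut:
            d = "up"
        elif sig <= thresholds.sig_cut and r.log2fc <= -thresholds.lfc_cut:
            d = "down"
        else:
            d = "ns"
        out.append(replace(r, direction=d))
    return out


def significant(records: Sequence[DifferentialRecord]) -> list[DifferentialRecord]:
    return [r for r in records if r.direction != "ns"]


# ---------------------------------------------------------------------------
# methylation layer
# ---------------------------------------------------------------------------

def filter_low_coverage_regions(
    table: MethylRegionTable, min_reads: int = 4, sample_fraction: float = 0.5
) -> MethylRegionTable:
    """Drop regions with fewer than ``min_reads`` total reads in at least
    ``sample_fraction`` of the samples."""
    totals = table.totals()
    n = totals.shape[1]
    low = (totals < min_reads).sum(axis=1)
    keep = low < sample_fraction * n
    return table.subset(table.regions.index[keep])


def test_methylation(table: MethylRegionTable, pseudocount: float = 0.5) -> list[DifferentialRecord]:
    """Likelihood-ratio test of a two-group binomial-logistic model per region.

    Counts are pooled within each group (the pooled totals are sufficient for
    a shared within-group methylation probability).  log2FC is the log2 odds
    ratio of pooled methylation, treated vs control, with ``pseudocount``
    added to all four cells; p comes from the chi-square(1) LRT of separate
    group probabilities against a single pooled probability.  BH FDR is
    reported alongside although the conventional calling rule for this layer
    uses raw p.
    """
    g1 = table.samples_in_group("control")
    g2 = table.samples_in_group("treated")
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("need >=2 samples per group")
    m1 = table.meth[g1].sum(axis=1).to_numpy(dtype=float)
    u1 = table.unmeth[g1].sum(axis=1).to_numpy(dtype=float)
    m2 = table.meth[g2].sum(axis=1).to_numpy(dtype=float)
    u2 = table.unmeth[g2].sum(axis=1).to_numpy(dtype=float)
    if ((m1 + u1) == 0).any() or ((m2 + u2) == 0).any():
        raise ValidationError("zero total reads in a group; apply coverage filters first")

    pc = pseudocount
    lfc = np.log2(((m2 + pc) / (u2 + pc)) / ((m1 + pc) / (u1 + pc)))

    def _ll(m: np.ndarray, u: np.ndarray) -> np.ndarray:
        # binomial log-likelihood at the MLE, zero-safe via x*log(x) -> 0
        t = m + u
        with np.errstate(divide="ignore", invalid="ignore"):
            term_m = np.where(m > 0, m * np.log(m / t), 0.0)
            term_u = np.where(u > 0, u * np.log(u / t), 0.0)
        return term_m + term_u

    lr = 2.0 * (_ll(m1, u1) + _ll(m2, u2) - _ll(m1 + m2, u1 + u2))
    lr = np.maximum(lr, 0.0)
    p = stats.chi2.sf(lr, df=1)
    fdr = bh_adjust(p)
    return [
        DifferentialRecord(rid, "methyl-region", float(l), float(pv), float(q))
        for rid, l, pv, q in zip(table.regions.index, lfc, p, fdr)
    ]


def records_to_frame(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    cols = ["feature_id", "layer", "log2fc", "p_value", "fdr", "direction"]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(
        [(r.feature_id, r.layer, r.log2fc, r.p_value, r.fdr, r.direction) for r in records],
        columns=cols,
    )
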