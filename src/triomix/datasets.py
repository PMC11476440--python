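"""Published worked example: the 21 promoter-methylation / gene / miRNA
records reported for newborn mouse kidneys after perinatal IL-6 exposure.

Each record carries the printed log2 fold change of a promoter DMR (log2
odds ratio of methylation, IL-6 vs control) with its p-value, the gene's
expression log2FC with its FDR, and the targeting miRNA's log2FC with its
FDR.  The records are already threshold-passing in the source analysis, so
directions are taken from the signs.  They cover 19 unique genes; Man2a1
appears with three different miRNAs.
"""

from __future__ import annotations

import math

import pandas as pd

from .differential import DifferentialRecord
from .integration import AnticorrInteraction, PromoterDmr

# gene, dmr_log2fc, dmr_p, deg_log2fc, deg_fdr, mirna, demir_log2fc, demir_fdr
IL6_KIDNEY_RECORDS: tuple[tuple, ...] = (
    ("Man2a1", 1.224, 0.002, -0.452, 1.68933e-08, "miR-92b-3p", 0.421, 0.002),
    ("Man2a1", 1.224, 0.002, -0.452, 1.68933e-08, "miR-191-5p", 0.33, 0.002),
    ("Man2a1", 1.224, 0.002, -0.452, 1.68933e-08, "miR-92a-3p", 0.265, 0.014),
    ("Atp6v0d1", 1.548, 0.038, -0.214, 0.031, "miR-125b-5p", 0.266, 0.015),
    ("Camkk1", -2.714, 2.23904e-06, 0.42, 0.047, "miR-223-3p", -0.333, 0.026),
    ("Tnfaip8l1", -1.543, 0.004, 0.623, 0.001, "miR-223-3p", -0.333, 0.026),
    ("Suox", -1.929, 0.004, 0.353, 0.048, "miR-125b-1-3p", -0.36, 0.031),
    ("Rint1", -1.046, 0.008, 0.29, 0.01, "miR-223-3p", -0.333, 0.026),
    ("Pomk", -1.217, 0.016, 0.355, 0.036, "miR-223-3p", -0.333, 0.026),
    ("Thap2", -1.111, 0.03, 1.105, 7.02311e-27, "miR-223-3p", -0.333, 0.026),
    ("Zfp455", -1.154, 0.034, 0.575, 0.023, "miR-223-3p", -0.333, 0.026),
    ("Khdrbs3", -1.32, 0.034, 0.221, 0.037, "miR-223-3p", -0.333, 0.026),
    ("Arl3", -1.018, 0.036, 0.409, 0.0, "miR-223-3p", -0.333, 0.026),
    ("Eml6", 1.171, 0.014, 0.469, 0.001, "miR-223-3p", -0.333, 0.026),
    ("Atp7b", 1.294, 0.017, 0.806, 0.005, "miR-223-3p", -0.333, 0.026),
    ("Cul3", -1.59, 0.003, -0.304, 0.001, "miR-92a-3p", 0.265, 0.014),
    ("Stag2", -1.052, 0.008, -0.347, 0.001, "miR-92a-3p", 0.265, 0.014),
    ("Klf6", -1.083, 0.018, -0.733, 8.18305e-05, "miR-92a-3p", 0.265, 0.014),
    ("Klhl15", -1.493, 0.02, -0.263, 0.04, "miR-92a-3p", 0.265, 0.014),
    ("Chm", -1.067, 0.021, -0.287, 0.002, "miR-92a-3p", 0.265, 0.014),
    ("Atp11c", -1.082, 0.045, -0.215, 0.024, "miR-125b-5p", 0.266, 0.015),
)

COLUMNS = (
    "gene_id", "dmr_log2fc", "dmr_p", "deg_log2fc", "deg_fdr",
    "mirna_id", "demir_log2fc", "demir_fdr",
)


def il6_kidney_frame() -> pd.DataFrame:
    """The worked-example records as a DataFrame (one row per gene-miRNA pair)."""
    return pd.DataFrame(list(IL6_KIDNEY_RECORDS), columns=list(COLUMNS))


def il6_kidney_inputs() -> tuple[list[PromoterDmr], list[DifferentialRecord], list[DifferentialRecord], list[AnticorrInteraction]]:
    """Re-encode the worked example as three-level integration inputs.

    Returns (promoter DMRs, DEG records, DEmiR records, anticorrelated
    interactions), with directions set from the printed log2FC signs since
    the records passed their thresholds in the source analysis.  Published
    tables do not print the underlying correlation coefficients, so the
    interactions carry NaN PCC fields.
    """
    dmrs: dict[str, PromoterDmr] = {}
    degs: dict[str, DifferentialRecord] = {}
    demirs: dict[str, DifferentialRecord] = {}
    inters: list[AnticorrInteraction] = []
    for row in IL6_KIDNEY_RECORDS:
        gene, dmr_lfc, dmr_p, deg_lfc, deg_fdr, mir, mir_lfc, mir_fdr = row
        dmrs.setdefault(
            gene,
            PromoterDmr(gene, f"dmr_{gene}", dmr_lfc, dmr_p,
                        "hyper" if dmr_lfc > 0 else "hypo"),
        )
        degs.setdefault(
            gene,
            DifferentialRecord(gene, "gene", deg_lfc, deg_fdr, deg_fdr,
                               "up" if deg_lfc > 0 else "down"),
        )
        demirs.setdefault(
            mir,
            DifferentialRecord(mir, "mirna", mir_lfc, mir_fdr, mir_fdr,
                               "up" if mir_lfc > 0 else "down"),
        )
        inters.append(
            AnticorrInteraction(
                mir, gene, math.nan, math.nan,
                "up" if mir_lfc > 0 else "down",
                "up" if deg_lfc > 0 else "down",
                demir_log2fc=mir_lfc, demir_fdr=mir_fdr,
            )
        )
    return list(dmrs.values()), list(degs.values()), list(demirs.values()), inters
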