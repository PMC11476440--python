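"""miRNA-centric regulatory networks, degree-based hub ranking, shared-target
analysis, FPKM co-expression edges and hypergeometric over-representation.

The regulatory network is a directed miRNA -> gene graph built from
anti-correlated interactions at permissive cutoffs (PCC < -0.1, p < 0.1 by
default); edges failing the p cutoff may be kept but flagged non-significant
so that every distinct interaction remains inspectable.  Hubs are miRNAs
ranked by out-degree, i.e. by the number of anti-correlated targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .errors import ValidationError
from .integration import AnticorrInteraction
from .io_formats import ExpressionMatrix

NETWORK_PCC_CUT = -0.1
NETWORK_P_CUT = 0.1
COEXPRESSION_MIN = 0.1


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation of one gene set in a query list."""

    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    adjusted_p: float


# ---------------------------------------------------------------------------
# network construction and topology
# ---------------------------------------------------------------------------

def build_mirna_network(
    interactions: Sequence[AnticorrInteraction],
    pcc_cut: float = NETWORK_PCC_CUT,
    p_cut: float = NETWORK_P_CUT,
    keep_nonsignificant: bool = False,
    node_log2fc: Mapping[str, float] | None = None,
) -> nx.DiGraph:
    """Directed miRNA -> gene network from anti-correlated interactions.

    Edges must satisfy pcc < ``pcc_cut``.  Those additionally passing
    p < ``p_cut`` carry ``significant=True``; the rest are dropped unless
    ``keep_nonsignificant`` is set, in which case they stay, flagged.
    """
    node_log2fc = node_log2fc or {}
    g = nx.DiGraph()
    for inter in interactions:
        if inter.mirna_id == inter.gene_id:
            raise ValidationError("self-edges are not allowed")
        if not (inter.pcc < pcc_cut):
            continue
        sig = inter.pcc_p < p_cut
        if not sig and not keep_nonsignificant:
            continue
        g.add_node(inter.mirna_id, kind="mirna",
                   log2fc=node_log2fc.get(inter.mirna_id, math.nan))
        g.add_node(inter.gene_id, kind="gene",
                   log2fc=node_log2fc.get(inter.gene_id, math.nan))
        g.add_edge(inter.mirna_id, inter.gene_id,
                   weight=inter.pcc, p=inter.pcc_p, significant=sig)
    return g


def hub_ranking(network: nx.DiGraph) -> list[tuple[str, int]]:
    """miRNAs ordered by out-degree (number of targets), descending; ties
    broken lexicographically."""
    if network.number_of_nodes() == 0:
        raise ValidationError("empty network")
    mirnas = [n for n, d in network.nodes(data=True) if d.get("kind") == "mirna"]
    return sorted(((m, network.out_degree(m)) for m in mirnas),
                  key=lambda t: (-t[1], t[0]))


def shared_targets(network: nx.DiGraph, mirna_a: str, mirna_b: str) -> set[str]:
    """Intersection of the two miRNAs' target sets."""
    for m in (mirna_a, mirna_b):
        if m not in network:
            raise ValidationError(f"unknown miRNA {m!r}")
    return set(network.successors(mirna_a)) & set(network.successors(mirna_b))


# ---------------------------------------------------------------------------
# co-expression
# ---------------------------------------------------------------------------

def coexpression_edges(
    seed_genes: Iterable[str],
    candidate_edges: Sequence[tuple[str, str]],
    fpkm: ExpressionMatrix,
    pcc_min: float = COEXPRESSION_MIN,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Score candidate edges by Pearson co-expression over FPKM samples.

    Edges are retained iff pcc >= ``pcc_min``; edges with a constant
    expression vector are dropped with a warning column rather than scored.
    Returns the retained edge frame (source, target, pcc, p, source_is_seed,
    target_is_seed) and a summary with the fractions of retained edges with
    pcc > 0.5 and <= 0.5.
    """
    import warnings

    seeds = set(seed_genes)
    rows = []
    vals = fpkm.values
    for a, b in candidate_edges:
        if a not in vals.index or b not in vals.index:
            raise ValidationError(f"edge endpoint missing from FPKM matrix: {(a, b)}")
        x = vals.loc[a].to_numpy(dtype=float)
        y = vals.loc[b].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"constant expression vector on edge {(a, b)}; dropped",
                          stacklevel=2)
            continue
        r, p = stats.pearsonr(x, y)
        if r >= pcc_min:
            rows.append((a, b, float(r), float(p), a in seeds, b in seeds))
    frame = pd.DataFrame(
        rows, columns=["source", "target", "pcc", "p", "source_is_seed", "target_is_seed"]
    )
    n = len(frame)
    strong = int((frame["pcc"] > 0.5).sum()) if n else 0
    summary = {
        "n_edges": float(n),
        "fraction_above_0.5": strong / n if n else math.nan,
        "fraction_at_or_below_0.5": (n - strong) / n if n else math.nan,
    }
    return frame, summary


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def hypergeometric_ora(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    correction: str = "bh",
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of gene sets in a query list.

    p = P(X >= overlap) with population = universe, successes = set
    intersected with the universe, draws = query.  Sets with no overlapping
    gene are omitted from the output.  ``correction`` is 'bh' or
    'bonferroni' over the reported sets.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValidationError("empty universe")
    if not query <= universe:
        raise ValidationError("query must be a subset of the universe")
    if correction not in ("bh", "bonferroni"):
        raise ValidationError("correction must be 'bh' or 'bonferroni'")
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        overlap = len(members & query)
        if overlap < 1:
            continue
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(query)))
        rows.append((name, overlap, len(members), p))
    if not rows:
        return []
    ps = np.array([r[3] for r in rows])
    if correction == "bh":
        adj = bh_adjust(ps)
    else:
        adj = np.minimum(ps * len(ps), 1.0)
    results = [
        EnrichmentResult(name, overlap, set_size, len(query), len(universe), p, float(a))
        for (name, overlap, set_size, p), a in zip(rows, adj)
    ]
    return sorted(results, key=lambda r: (r.p, r.set_name))
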