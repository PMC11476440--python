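import math

import numpy as np
import pandas as pd
import pytest

from triomix import (
    AnticorrInteraction,
    DifferentialRecord,
    ExpressionMatrix,
    PromoterDmr,
    RegulatoryCategory,
    TargetPair,
    ValidationError,
    category_summary,
    classify_category,
    integrate_three_level,
    link_demir_targets,
    link_dmr_deg,
    link_dmr_demir,
    pearson_with_p,
    unique_genes,
)


class TestPearsonWithP:
    def test_perfect_anticorrelation(self):
        r, p = pearson_with_p([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == pytest.approx(-1.0)

    def test_perfect_correlation(self):
        r, _ = pearson_with_p([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_hand_computed_t_transform(self):
        r, p = pearson_with_p([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)
        assert p == pytest.approx(2 / 3, abs=1e-6)

    def test_constant_vector_sentinel(self):
        r, p = pearson_with_p([1, 1, 1], [1, 2, 3])
        assert math.isnan(r) and math.isnan(p)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            pearson_with_p([1, 2, 3], [1, 2])


def _deg(gene, lfc, direction, fdr=0.01):
    return DifferentialRecord(gene, "gene", lfc, fdr, fdr, direction)


def _demir(mir, lfc, direction, fdr=0.01):
    return DifferentialRecord(mir, "mirna", lfc, fdr, fdr, direction)


class TestTwoLevelLinks:
    def test_hyper_with_down_gene_emits(self):
        links = link_dmr_deg(
            [PromoterDmr("G", "r1", 1.5, 0.01, "hyper")], [_deg("G", -1.0, "down")]
        )
        assert len(links) == 1 and links[0].feature_id == "G"

    def test_hyper_with_up_gene_does_not_emit(self):
        links = link_dmr_deg(
            [PromoterDmr("G", "r1", 1.5, 0.01, "hyper")], [_deg("G", 1.0, "up")]
        )
        assert links == []

    def test_planted_link_count_is_exact(self):
        dmrs = [PromoterDmr(f"g{i}", f"r{i}", 1.5, 0.01, "hyper") for i in range(82)]
        degs = [_deg(f"g{i}", -1.0, "down") for i in range(82)]
        assert len(link_dmr_deg(dmrs, degs)) == 82

    def test_mirna_loci_reciprocal_orientations(self):
        dmrs = [
            PromoterDmr("miR-a", "r1", -2.0, 0.01, "hypo"),
            PromoterDmr("miR-b", "r2", 2.0, 0.01, "hyper"),
        ]
        demirs = [_demir("miR-a", 1.0, "up"), _demir("miR-b", -1.0, "down")]
        links = link_dmr_demir(dmrs, demirs)
        assert {l.feature_id for l in links} == {"miR-a", "miR-b"}

    def test_no_mirna_loci_empty(self):
        assert link_dmr_demir([], [_demir("miR-a", 1.0, "up")]) == []


class TestAnticorrFilter:
    SAMPLES = ["c1", "c2", "c3", "t1", "t2", "t3"]

    def _matrices(self, gene_vec, mir_vec):
        gene = ExpressionMatrix(
            pd.DataFrame([gene_vec], index=pd.Index(["G"]), columns=self.SAMPLES),
            {s: "control" for s in self.SAMPLES},
        )
        mir = ExpressionMatrix(
            pd.DataFrame([mir_vec], index=pd.Index(["M"]), columns=self.SAMPLES),
            {s: "control" for s in self.SAMPLES},
        )
        return gene, mir

    def test_strong_anticorrelation_retained(self):
        gene, mir = self._matrices([10, 9, 11, 2, 1, 3], [1, 2, 1, 8, 9, 8])
        out = link_demir_targets(
            [_demir("M", 1.0, "up")], [TargetPair("M", "G")], [_deg("G", -1.0, "down")],
            gene, mir,
        )
        assert len(out) == 1
        assert out[0].pcc < -0.5 and out[0].pcc_p < 0.05

    def test_cutoff_is_strict(self):
        gene, mir = self._matrices([10, 9, 11, 2, 1, 3], [1, 2, 1, 8, 9, 8])
        out = link_demir_targets(
            [_demir("M", 1.0, "up")], [TargetPair("M", "G")], [_deg("G", -1.0, "down")],
            gene, mir, pcc_cut=-1.0,  # observed pcc > -1 -> strict '<' rejects
        )
        assert out == []

    def test_same_direction_pair_never_tested(self):
        gene, mir = self._matrices([10, 9, 11, 2, 1, 3], [1, 2, 1, 8, 9, 8])
        out = link_demir_targets(
            [_demir("M", 1.0, "up")], [TargetPair("M", "G")], [_deg("G", 1.0, "up")],
            gene, mir,
        )
        assert out == []

    def test_relaxing_cutoff_grows_set_monotonically(self):
        rng = np.random.default_rng(5)
        samples = self.SAMPLES
        genes = pd.DataFrame(rng.uniform(1, 10, size=(20, 6)),
                             index=[f"g{i}" for i in range(20)], columns=samples)
        mirs = pd.DataFrame(rng.uniform(1, 10, size=(4, 6)),
                            index=[f"m{i}" for i in range(4)], columns=samples)
        gene_expr = ExpressionMatrix(genes, {s: "control" for s in samples})
        mir_expr = ExpressionMatrix(mirs, {s: "control" for s in samples})
        degs = [_deg(f"g{i}", -1.0, "down") for i in range(20)]
        demirs = [_demir(f"m{i}", 1.0, "up") for i in range(4)]
        table = [TargetPair(f"m{i % 4}", f"g{i}") for i in range(20)]
        sizes = [
            len(link_demir_targets(demirs, table, degs, gene_expr, mir_expr, pcc, 1.01))
            for pcc in (-0.9, -0.5, -0.1, 0.5)
        ]
        assert sizes == sorted(sizes)


class TestClassifyCategory:
    ADMISSIBLE = [
        (("hyper", "down", "up"), RegulatoryCategory.CONSISTENT_HYPER_DOWN),
        (("hypo", "up", "down"), RegulatoryCategory.CONSISTENT_HYPO_UP),
        (("hyper", "up", "down"), RegulatoryCategory.INCONSISTENT_HYPER_UP),
        (("hypo", "down", "up"), RegulatoryCategory.INCONSISTENT_HYPO_DOWN),
    ]

    @pytest.mark.parametrize("signs,expected", ADMISSIBLE)
    def test_admissible_combinations(self, signs, expected):
        assert classify_category(*signs) is expected

    @pytest.mark.parametrize(
        "signs",
        [("hyper", "down", "down"), ("hyper", "up", "up"),
         ("hypo", "down", "down"), ("hypo", "up", "up")],
    )
    def test_non_opposite_combinations_rejected(self, signs):
        with pytest.raises(ValidationError):
            classify_category(*signs)

    def test_ns_direction_rejected(self):
        with pytest.raises(ValidationError):
            classify_category("hyper", "ns", "up")

    def test_published_example_rows(self):
        # Man2a1: hypermethylated promoter, downregulated gene, upregulated miRNA
        assert classify_category("hyper", "down", "up").color == "red"
        # Camkk1, Atp7b, Atp11c sign patterns
        assert classify_category("hypo", "up", "down").color == "blue"
        assert classify_category("hyper", "up", "down").color == "green"
        assert classify_category("hypo", "down", "up").color == "orange"


class TestIntegrateThreeLevel:
    def test_worked_example_counts(self, worked_example):
        dmrs, degs, demirs, inters = worked_example
        triples = integrate_three_level(dmrs, degs, inters)
        assert len(triples) == 21
        assert len(unique_genes(triples)) == 19
        summary = category_summary(triples)
        assert summary["red"] == 2 and summary["blue"] == 9
        assert summary["green"] == 2 and summary["orange"] == 6
        assert summary["consistent"] == 11 and summary["inconsistent"] == 8

    def test_empty_anticorr_empty_output(self, worked_example):
        dmrs, degs, _, _ = worked_example
        assert integrate_three_level(dmrs, degs, []) == []

    def test_closure_no_triple_without_all_layers(self, worked_example):
        dmrs, degs, _, inters = worked_example
        triples = integrate_three_level(dmrs[:5], degs, inters)
        covered = {d.gene_id for d in dmrs[:5]}
        assert {t.gene_id for t in triples} <= covered

    def test_gene_with_multiple_mirnas_repeats(self, worked_example):
        dmrs, degs, _, inters = worked_example
        triples = integrate_three_level(dmrs, degs, inters)
        man2a1 = [t for t in triples if t.gene_id == "Man2a1"]
        assert len(man2a1) == 3
        assert {t.mirna_id for t in man2a1} == {"miR-92b-3p", "miR-191-5p", "miR-92a-3p"}

    def test_smallest_p_promoter_dmr_wins(self):
        dmrs = [
            PromoterDmr("G", "r_weak", 1.2, 0.04, "hyper"),
            PromoterDmr("G", "r_strong", 1.8, 0.001, "hyper"),
        ]
        degs = [_deg("G", -1.0, "down")]
        inters = [AnticorrInteraction("M", "G", -0.9, 0.001, "up", "down")]
        (t,) = integrate_three_level(dmrs, degs, inters)
        assert t.region_id == "r_strong"
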