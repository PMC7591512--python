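"""RPKM, expression flags, allele-specific DE and the candidate screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pmakit.expression_analysis import (
    DEResult,
    ExpressionRecord,
    allele_de,
    candidate_pma_screen,
    de_table,
    expressed_flag,
    gdmr_comparison,
    rpkm,
)
from pmakit.genome_annotation import GenomeInterval, PromoterRecord
from pmakit.methylome import SampleMethylome


def record(counts, libs=None, gene="g", allele="paternal", stage="4C",
           genotype="WT", exon_len=1000):
    libs = libs or [1_000_000] * len(counts)
    return ExpressionRecord(gene, stage, genotype, allele, list(counts),
                            list(libs), exon_len)


class TestRpkm:
    def test_hand_value(self):
        assert rpkm(10, 1000, 1_000_000) == pytest.approx(10.0)

    def test_zero_count(self):
        assert rpkm(0, 1000, 1_000_000) == 0.0

    def test_scale_invariance(self):
        assert rpkm(10, 1000, 1_000_000) == pytest.approx(
            rpkm(30, 1000, 3_000_000))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)

    def test_matches_brute_force_random_tables(self):
        rng = np.random.default_rng(40)
        for _ in range(100):
            c = int(rng.integers(0, 10_000))
            l = int(rng.integers(100, 100_000))
            lib = int(rng.integers(10_000, 10_000_000))
            assert rpkm(c, l, lib) == pytest.approx(c / (lib / 1e6) / (l / 1e3))


class TestExpressedFlag:
    @pytest.mark.parametrize("value,cutoff,flag", [
        (1.0, 1.0, True),   # inclusive threshold
        (0.99, 1.0, False),
        (1.9, 2.0, False),
        (2.0, 2.0, True),
        (0.0, 1.0, False),
    ])
    def test_threshold(self, value, cutoff, flag):
        assert expressed_flag(value, cutoff) == flag


class TestAlleleDe:
    def test_strong_upregulation(self):
        wt = record([0, 0])
        ko = record([100, 100], genotype="matKO")
        r = de_table([wt], [ko])[0]
        assert 2**r.log2_fold_change == pytest.approx(201.0)
        assert r.is_de
        # oracle: exact binomial tail for 200 of 200 pooled reads in KO
        assert r.p_value == pytest.approx(
            sps.binomtest(200, 200, 0.5).pvalue, abs=1e-12)

    def test_identical_records_not_de(self):
        wt = record([50, 60])
        ko = record([50, 60], genotype="matKO")
        r = de_table([wt], [ko])[0]
        assert r.log2_fold_change == pytest.approx(0.0)
        assert not r.is_de

    def test_fold_filter_blocks_small_changes(self):
        # large counts, 1.5-fold change: tiny p but below the fold cutoff
        wt = record([10_000, 10_000])
        ko = record([15_000, 15_000], genotype="matKO")
        r = de_table([wt], [ko])[0]
        assert r.p_value < 1e-10
        assert abs(r.log2_fold_change) < 1
        assert not r.is_de

    def test_library_normalisation(self):
        # same expression rate at doubled KO depth: no fold change
        wt = record([100, 100], libs=[1_000_000] * 2)
        ko = record([200, 200], libs=[2_000_000] * 2, genotype="matKO")
        r = de_table([wt], [ko])[0]
        assert r.log2_fold_change == pytest.approx(0.0, abs=0.01)
        assert r.p_value > 0.5

    def test_q_at_least_p(self):
        rng = np.random.default_rng(41)
        wts, kos = [], []
        for i in range(50):
            base = int(rng.integers(10, 500))
            wts.append(record([base, base + 5], gene=f"g{i}"))
            kos.append(record(
                [int(base * rng.uniform(0.5, 2)), base], gene=f"g{i}",
                genotype="matKO"))
        for r in de_table(wts, kos):
            assert r.q_value >= r.p_value - 1e-12

    def test_mismatched_contrast_rejected(self):
        with pytest.raises(ValueError):
            allele_de(record([1, 2], gene="a"),
                      record([1, 2], gene="b", genotype="matKO"))

    def test_planted_fold_recovered(self, default_truth):
        """Fold-4 planted paternal upregulation at 4C is recovered near 4
        with tight dispersion and large baselines."""
        import dataclasses

        from pmakit.synthetic_data import simulate_expression_counts

        cfg = dataclasses.replace(default_truth.config, expr_dispersion=1e-4,
                                  expr_baseline_mean=5000.0)
        wt = {(r.gene_id, r.allele): r for r in
              simulate_expression_counts(default_truth, "4C", "WT", cfg)}
        ko = {(r.gene_id, r.allele): r for r in
              simulate_expression_counts(default_truth, "4C", "matKO", cfg)}
        for gid, stage, allele, fold in default_truth.planted_de:
            r = allele_de(wt[(gid, allele)], ko[(gid, allele)])
            assert 2**r.log2_fold_change == pytest.approx(fold, rel=0.1)
            rm = allele_de(wt[(gid, "maternal")], ko[(gid, "maternal")])
            assert 2**rm.log2_fold_change == pytest.approx(1.0, rel=0.1)


def _meth(levels_by_slot, coverage=200):
    rows = []
    for slot, pct in levels_by_slot.items():
        start = slot * 2000
        meth = int(round(coverage * pct / 100))
        for j in range(4):
            rows.append(("chr1", start + 50 + j * 150, meth, coverage - meth))
    return SampleMethylome(
        "s", "total",
        pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"]), 100, 1)


def _prom(slot, gene, ratio=0.5, n_exonic=1):
    start = slot * 2000
    return PromoterRecord(
        gene_id=gene, tss=GenomeInterval("chr1", start + 300, start + 301),
        window=GenomeInterval("chr1", start, start + 600),
        cpg_ratio=ratio, gc_content=0.5,
        density_class="intermediate" if ratio >= 0.12 else "low",
        is_cgi_promoter=ratio >= 0.12, h3k4me3_rpkm=2.0,
        n_exonic_variants=n_exonic,
    )


def _de(gene, lfc, q, stage="4C", allele="paternal"):
    return DEResult(gene, allele, stage, lfc, p_value=min(q, 1.0), q_value=q)


class TestCandidateScreen:
    def base_inputs(self):
        promoters = [_prom(0, "gA"), _prom(1, "gB")]
        de4p = [_de("gA", 2.5, 0.01), _de("gB", 2.5, 0.01)]
        de4m = [_de("gA", 0.1, 0.9, allele="maternal"),
                _de("gB", 0.1, 0.9, allele="maternal")]
        deip = [_de("gA", 0.0, 1.0, stage="ICM"),
                _de("gB", 0.0, 1.0, stage="ICM")]
        wt2c = _meth({0: 25, 1: 25})
        ko2c = _meth({0: 2, 1: 2})
        sperm = _meth({0: 2, 1: 2})
        oocyte = _meth({0: 2, 1: 2})
        return promoters, de4p, de4m, deip, wt2c, ko2c, sperm, oocyte

    def test_passing_gene_is_candidate(self):
        args = self.base_inputs()
        assert candidate_pma_screen(args[1], args[2], args[3], args[0],
                                    *args[4:]) == ["gA", "gB"]

    def test_maternal_fold_excludes(self):
        promoters, de4p, de4m, deip, *meths = self.base_inputs()
        de4m[0] = _de("gA", np.log2(2.5), 0.5, allele="maternal")
        assert candidate_pma_screen(de4p, de4m, deip, promoters,
                                    *meths) == ["gB"]

    def test_matko_methylation_excludes(self):
        promoters, de4p, de4m, deip, wt2c, ko2c, sperm, oocyte = (
            self.base_inputs())
        ko2c = _meth({0: 10, 1: 2})  # gA not hypomethylated in matKO
        assert candidate_pma_screen(de4p, de4m, deip, promoters, wt2c, ko2c,
                                    sperm, oocyte) == ["gB"]

    def test_icm_upregulation_excludes(self):
        promoters, de4p, de4m, deip, *meths = self.base_inputs()
        deip[1] = _de("gB", 2.0, 0.01, stage="ICM")
        assert candidate_pma_screen(de4p, de4m, deip, promoters,
                                    *meths) == ["gA"]

    def test_oocyte_methylation_blocks_gain(self):
        promoters, de4p, de4m, deip, wt2c, ko2c, sperm, oocyte = (
            self.base_inputs())
        oocyte = _meth({0: 85, 1: 2})  # gain vs max(sperm, oocyte) < 18
        assert candidate_pma_screen(de4p, de4m, deip, promoters, wt2c, ko2c,
                                    sperm, oocyte) == ["gB"]

    def test_exonic_variant_required(self):
        promoters, *rest = self.base_inputs()
        promoters[0].n_exonic_variants = 0
        assert candidate_pma_screen(rest[0], rest[1], rest[2], promoters,
                                    *rest[3:]) == ["gB"]

    def test_gene_order_invariance(self):
        args = self.base_inputs()
        flipped = ([args[0][1], args[0][0]], list(reversed(args[1])),
                   list(reversed(args[2])), list(reversed(args[3])))
        assert candidate_pma_screen(args[1], args[2], args[3], args[0],
                                    *args[4:]) == candidate_pma_screen(
            flipped[1], flipped[2], flipped[3], flipped[0], *args[4:])

    def test_missing_table_raises(self):
        args = self.base_inputs()
        with pytest.raises(ValueError, match="missing required table"):
            candidate_pma_screen([], args[2], args[3], args[0], *args[4:])


class TestGdmrComparison:
    def test_parent_of_origin_and_levels(self):
        gdmrs = [("m1", GenomeInterval("chr1", 0, 600)),
                 ("p1", GenomeInterval("chr1", 2000, 2600))]
        wt = _meth({0: 45, 1: 45})
        ko = _meth({0: 5, 1: 45})
        oocyte = _meth({0: 90, 1: 5})
        sperm = _meth({0: 5, 1: 90})
        recs = gdmr_comparison(gdmrs, wt, ko, oocyte, sperm)
        assert recs[0].parent_of_origin == "maternal"
        assert recs[1].parent_of_origin == "paternal"
        assert recs[0].wt_pct == pytest.approx(45, abs=0.5)
        assert recs[0].ko_pct == pytest.approx(5, abs=0.5)
        assert recs[1].ko_pct == pytest.approx(45, abs=0.5)

    def test_uninformative_gdmr_unassessed(self):
        gdmrs = [("m1", GenomeInterval("chr1", 0, 600))]
        wt = _meth({0: 45})
        ko = _meth({5: 45})  # no coverage over the gDMR
        oocyte = _meth({0: 90})
        sperm = _meth({0: 5})
        recs = gdmr_comparison(gdmrs, wt, ko, oocyte, sperm)
        assert recs[0].parent_of_origin == "unassessed"
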