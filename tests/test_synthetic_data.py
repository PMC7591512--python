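"""Ground-truth generator: determinism, planted invariants, sampling
properties and no-leakage of truth into standard-format files."""

import dataclasses
import json

import numpy as np
import pytest

from pmakit.chromatin_association import score_mark
from pmakit.genome_annotation import enumerate_cpg_sites
from pmakit.synthetic_data import (
    SimulationConfig,
    generate_truth,
    simulate_chip_track,
    simulate_expression_counts,
    simulate_methylome,
    write_dataset,
)


class TestGenerateTruth:
    def test_deterministic_for_fixed_seed(self, small_config):
        a = generate_truth(small_config).to_manifest()
        b = generate_truth(dataclasses.replace(small_config)).to_manifest()
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_different_seed_differs(self, small_config, small_truth):
        other = generate_truth(dataclasses.replace(small_config, seed=8))
        assert (json.dumps(other.to_manifest(), sort_keys=True)
                != json.dumps(small_truth.to_manifest(), sort_keys=True))

    def test_no_planted_genes(self, small_config):
        cfg = dataclasses.replace(small_config, n_planted_pma=0,
                                  n_planted_de=0)
        truth = generate_truth(cfg)
        assert truth.planted_pma == []
        sperm = truth.true_meth[("sperm_DBA", "total")]
        embryo = truth.true_meth[("2C", "paternal")]
        for g in truth.genes:
            gain = (embryo.value(g.chrom, g.tss)
                    - sperm.value(g.chrom, g.tss))
            assert gain < 0.30

    def test_planted_count_and_invariants(self, small_truth):
        truth = small_truth
        assert len(truth.planted_pma) == truth.config.n_planted_pma
        sperm = truth.true_meth[("sperm_DBA", "total")]
        embryo = truth.true_meth[("2C", "paternal")]
        for gid in truth.planted_pma:
            g = truth.gene(gid)
            s = sperm.value(g.chrom, g.tss)
            assert s < 0.20
            assert embryo.value(g.chrom, g.tss) - s >= 0.30
            # >= 4 CpGs and >= 1 variant in the promoter window
            win = truth.promoter_window(gid)
            seq = truth.genome["maternal_ref"][g.chrom][win.start:win.end]
            assert len(enumerate_cpg_sites(seq)) >= 4
            assert any(c == g.chrom and win.start <= p < win.end
                       for c, p, _, _ in truth.snvs)

    def test_haplotypes_differ_only_at_snvs(self, small_truth):
        truth = small_truth
        snv_pos = {(c, p) for c, p, _, _ in truth.snvs}
        for chrom, mat in truth.genome["maternal_ref"].items():
            pat = truth.genome["paternal_ref"][chrom]
            diff = np.flatnonzero(
                np.frombuffer(mat.encode(), dtype="S1")
                != np.frombuffer(pat.encode(), dtype="S1")
            )
            assert {(chrom, int(p)) for p in diff} == {
                (c, p) for c, p in snv_pos if c == chrom}

    def test_haplotypes_share_cpg_sites(self, small_truth):
        for chrom, mat in small_truth.genome["maternal_ref"].items():
            pat = small_truth.genome["paternal_ref"][chrom]
            assert enumerate_cpg_sites(mat).tolist() == \
                enumerate_cpg_sites(pat).tolist()

    def test_exons_within_chromosomes(self, small_truth):
        sizes = small_truth.chrom_sizes
        for g in small_truth.genes:
            for s, e in g.exons:
                assert 0 <= s < e <= sizes[g.chrom]

    def test_undersized_chromosome_rejected(self, small_config):
        with pytest.raises(ValueError, match="too small"):
            generate_truth(dataclasses.replace(small_config,
                                               chrom_length=10_000))

    def test_too_many_planted_rejected(self, small_config):
        with pytest.raises(ValueError):
            generate_truth(dataclasses.replace(small_config,
                                               n_planted_pma=100))


class TestSimulateMethylome:
    def test_zero_coverage_mean_empty(self, small_truth):
        cfg = dataclasses.replace(small_truth.config, coverage_mean=0.0)
        m = simulate_methylome(small_truth, "2C", "paternal", cfg)
        assert len(m.calls) == 0

    def test_unknown_sample_rejected(self, small_truth):
        with pytest.raises(KeyError):
            simulate_methylome(small_truth, "nope", "total")

    def test_binomial_sampling_property(self, small_truth):
        """Mean observed methylation at high coverage sits within 3
        standard errors of the truth (closed-form binomial SE)."""
        cfg = dataclasses.replace(small_truth.config, coverage_mean=200.0)
        m = simulate_methylome(small_truth, "sperm_DBA", "total", cfg)
        profile = small_truth.true_meth[("sperm_DBA", "total")]
        fracs, trues = [], []
        for chrom in small_truth.chrom_sizes:
            sub = m.calls[m.calls["chrom"] == chrom]
            pos = sub["pos"].to_numpy()
            fracs.append((sub["meth"]
                          / (sub["meth"] + sub["unmeth"])).to_numpy())
            trues.append(profile.values(chrom, pos))
        frac = np.concatenate(fracs)
        true = np.concatenate(trues)
        # background sites only (single shared truth value)
        bg = np.isclose(true, profile.background)
        assert bg.sum() >= 100
        p = profile.background
        se = np.sqrt(p * (1 - p) / 200 / bg.sum())
        assert abs(frac[bg].mean() - p) < 3 * se + 0.01

    def test_all_unmethylated_truth(self, small_truth):
        """A profile with truth 0 yields no methylated reads."""
        truth = small_truth
        profile = truth.true_meth[("sperm_DBA", "total")]
        zero = dataclasses.replace(truth.config)
        from pmakit.synthetic_data import MethProfile
        truth.true_meth[("zero_test", "total")] = MethProfile(0.0, [])
        try:
            m = simulate_methylome(truth, "zero_test", "total", zero)
            assert (m.calls["meth"] == 0).all()
        finally:
            del truth.true_meth[("zero_test", "total")]


class TestSimulateChip:
    def test_enriched_promoters_score_high(self, small_truth):
        track = simulate_chip_track(small_truth, "H3K4me3", "sperm", "total")
        scores = [score_mark(track, small_truth.promoter_window(gid))
                  for gid in small_truth.h3k4me3_enriched]
        assert np.mean([s >= 1.0 for s in scores]) > 0.95

    def test_low_class_promoters_score_low(self, small_truth):
        track = simulate_chip_track(small_truth, "H3K4me3", "sperm", "total")
        low = [g.gene_id for g in small_truth.genes
               if small_truth.promoter_class_truth[g.gene_id] == "low"]
        for gid in low:
            assert score_mark(track, small_truth.promoter_window(gid)) < 1.0

    def test_h3k9me3_marks_planted_windows(self, small_truth):
        track = simulate_chip_track(small_truth, "H3K9me3", "zygote",
                                    "paternal")
        for gid in small_truth.planted_pma:
            assert score_mark(track, small_truth.promoter_window(gid)) >= 1.0

    def test_unknown_mark_rejected(self, small_truth):
        with pytest.raises(ValueError):
            simulate_chip_track(small_truth, "H3K36me3", "sperm")


class TestSimulateExpression:
    def test_replicate_structure(self, small_truth):
        recs = simulate_expression_counts(small_truth, "4C", "WT")
        assert all(len(r.replicate_counts) == 2 for r in recs)
        alleles = {r.allele for r in recs}
        assert alleles == {"maternal", "paternal", "total"}

    def test_total_is_allele_sum(self, small_truth):
        recs = simulate_expression_counts(small_truth, "4C", "WT")
        by = {(r.gene_id, r.allele): r for r in recs}
        for g in small_truth.genes:
            tot = by[(g.gene_id, "total")].replicate_counts
            mat = by[(g.gene_id, "maternal")].replicate_counts
            pat = by[(g.gene_id, "paternal")].replicate_counts
            assert tot == [m + p for m, p in zip(mat, pat)]

    def test_nb_mean_with_planted_fold(self, small_truth):
        """matKO/WT paternal mean ratio approaches the planted fold when
        dispersion vanishes and baselines are large (NB mean oracle)."""
        cfg = dataclasses.replace(small_truth.config, expr_dispersion=0.0,
                                  expr_baseline_mean=20_000.0)
        wt = {(r.gene_id, r.allele): r for r in
              simulate_expression_counts(small_truth, "4C", "WT", cfg)}
        ko = {(r.gene_id, r.allele): r for r in
              simulate_expression_counts(small_truth, "4C", "matKO", cfg)}
        for gid, stage, allele, fold in small_truth.planted_de:
            ratio = (np.mean(ko[(gid, allele)].replicate_counts)
                     / np.mean(wt[(gid, allele)].replicate_counts))
            assert ratio == pytest.approx(fold, rel=0.05)
            m_ratio = (np.mean(ko[(gid, "maternal")].replicate_counts)
                       / np.mean(wt[(gid, "maternal")].replicate_counts))
            assert m_ratio == pytest.approx(1.0, rel=0.05)

    def test_bad_genotype_rejected(self, small_truth):
        with pytest.raises(ValueError):
            simulate_expression_counts(small_truth, "4C", "het")


class TestWriteDataset:
    def test_files_and_no_leakage(self, small_truth, tmp_path):
        out = write_dataset(small_truth, tmp_path / "data")
        expected = ["genome.maternal.fa", "genome.paternal.fa", "genes.tsv",
                    "snvs.tsv", "gdmrs.bed", "truth.json", "libsize.tsv"]
        for name in expected:
            assert (out / name).exists()
        # the planted/persistence truth never appears outside truth.json
        for f in out.iterdir():
            if f.name == "truth.json":
                continue
            text = f.read_text().lower()
            for marker in ("planted", "persistence", "truth", "retained"):
                assert marker not in text, f"truth leaked into {f.name}"

    def test_checksum_determinism(self, small_truth, small_config, tmp_path):
        import hashlib

        out1 = write_dataset(small_truth, tmp_path / "a")
        from pmakit.synthetic_data import generate_truth
        out2 = write_dataset(generate_truth(small_config), tmp_path / "b")

        def digest(d):
            h = hashlib.sha256()
            for f in sorted(p.name for p in d.iterdir()):
                h.update(f.encode())
                h.update((d / f).read_bytes())
            return h.hexdigest()

        assert digest(out1) == digest(out2)
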