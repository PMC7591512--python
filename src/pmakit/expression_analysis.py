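"""RPKM, expression flags, allele-specific differential expression and the
candidate PMA screen.

Differential expression between maternal-knockout (matKO) and wild-type
embryos is computed per gene, per allele (total / maternal / paternal):

* fold change = (mean library-normalised KO count + 0.5) /
  (mean library-normalised WT count + 0.5) — the 0.5 pseudocount keeps
  folds stable with duplicate-level replication;
* p-value from a conditional binomial exact test: given the pooled count
  across both genotypes, the KO share is binomial with success probability
  equal to the pooled KO library share under the null of equal expression;
* Benjamini-Hochberg adjustment across all tested genes of a stage x
  allele contrast; a gene is differentially expressed when |log2 fold| >=
  log2(fold_min) and q <= fdr.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .genome_annotation import GenomeInterval, PromoterRecord
from .methylome import SampleMethylome, region_methylation
from .stats_util import bh_adjust

__all__ = [
    "ExpressionRecord",
    "DEResult",
    "rpkm",
    "expressed_flag",
    "allele_de",
    "de_table",
    "candidate_pma_screen",
    "gdmr_comparison",
]


def rpkm(count: float, exon_length_bp: int, library_size: int) -> float:
    """Reads per kilobase of feature per million mapped library reads."""
    if exon_length_bp <= 0:
        raise ValueError("exon_length_bp must be > 0")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return count * 1e9 / (library_size * exon_length_bp)


def expressed_flag(rpkm_mean: float, cutoff: float = 1.0) -> bool:
    """Expressed iff mean RPKM >= cutoff (inclusive)."""
    if rpkm_mean < 0:
        raise ValueError("rpkm_mean must be >= 0")
    return rpkm_mean >= cutoff


@dataclass
class ExpressionRecord:
    """Allele-resolved replicate counts for one gene in one condition."""

    gene_id: str
    stage: str
    genotype: str  # WT | matKO
    allele: str  # total | maternal | paternal
    replicate_counts: list
    library_sizes: list
    exon_length_bp: int

    def __post_init__(self) -> None:
        if len(self.replicate_counts) != len(self.library_sizes):
            raise ValueError("counts and library sizes differ in length")
        if len(self.replicate_counts) < 1:
            raise ValueError("need at least one replicate")

    @property
    def rpkm_per_replicate(self) -> list:
        return [
            rpkm(c, self.exon_length_bp, l)
            for c, l in zip(self.replicate_counts, self.library_sizes)
        ]

    @property
    def rpkm_mean(self) -> float:
        return float(np.mean(self.rpkm_per_replicate))


@dataclass
class DEResult:
    gene_id: str
    allele: str
    stage: str
    log2_fold_change: float
    p_value: float
    q_value: float | None = None
    fold_min: float = 2.0
    fdr: float = 0.1

    @property
    def is_de(self) -> bool:
        if self.q_value is None:
            raise ValueError("q_value not filled; run de_table first")
        return (
            abs(self.log2_fold_change) >= np.log2(self.fold_min)
            and self.q_value <= self.fdr
        )


def allele_de(wt: ExpressionRecord, ko: ExpressionRecord) -> DEResult:
    """Per-gene KO-vs-WT contrast; q is filled later across the gene set."""
    if (wt.gene_id, wt.stage, wt.allele) != (ko.gene_id, ko.stage, ko.allele):
        raise ValueError("WT and KO records must describe the same contrast")
    libs = np.asarray(wt.library_sizes + ko.library_sizes, dtype=float)
    if (libs <= 0).all():
        raise ValueError("all library sizes are zero")
    ref = libs.mean()
    norm_wt = np.asarray(wt.replicate_counts, dtype=float) * ref / np.asarray(
        wt.library_sizes, dtype=float
    )
    norm_ko = np.asarray(ko.replicate_counts, dtype=float) * ref / np.asarray(
        ko.library_sizes, dtype=float
    )
    fold = (norm_ko.mean() + 0.5) / (norm_wt.mean() + 0.5)
    pooled_ko = int(np.sum(ko.replicate_counts))
    pooled_wt = int(np.sum(wt.replicate_counts))
    n = pooled_ko + pooled_wt
    ko_share = float(np.sum(ko.library_sizes) / libs.sum())
    if n == 0:
        p = 1.0
    else:
        p = float(sps.binomtest(pooled_ko, n, ko_share).pvalue)
    return DEResult(
        gene_id=wt.gene_id, allele=wt.allele, stage=wt.stage,
        log2_fold_change=float(np.log2(fold)), p_value=p,
    )


def de_table(
    wt_records: list[ExpressionRecord],
    ko_records: list[ExpressionRecord],
    fold_min: float = 2.0,
    fdr: float = 0.1,
) -> list[DEResult]:
    """Run :func:`allele_de` over a gene set and fill BH q-values."""
    if len(wt_records) != len(ko_records):
        raise ValueError("WT and KO record lists differ in length")
    results = [allele_de(w, k) for w, k in zip(wt_records, ko_records)]
    qs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
        r.fold_min = fold_min
        r.fdr = fdr
    return results


def _window_pct(methylome: SampleMethylome, window: GenomeInterval,
                min_cpgs: int = 2) -> float | None:
    return region_methylation(methylome, window, min_cpgs).mean_pct


def candidate_pma_screen(
    de_4c_paternal: list[DEResult],
    de_4c_maternal: list[DEResult],
    de_icm_paternal: list[DEResult],
    promoters: list[PromoterRecord],
    wt2c_total: SampleMethylome,
    ko2c_total: SampleMethylome,
    sperm: SampleMethylome,
    oocyte: SampleMethylome,
    meth_gain_min: float = 18.0,
    meth_hypo_max: float = 4.0,
    min_cpgs: int = 2,
) -> list[str]:
    """Screen for candidate maternal-DNMT3A-target promoters.

    A gene is a candidate when ALL of: CGI promoter; >= 1 exonic variant;
    paternal upregulation (is_de, fold > 1) in matKO at 4C; no maternal
    fold >= 2 at 4C; no paternal upregulation at ICM; WT 2-cell total
    promoter methylation exceeds max(sperm, oocyte) by >= meth_gain_min
    points; matKO 2-cell total promoter methylation < meth_hypo_max.
    """
    prom = {p.gene_id: p for p in promoters}
    pat4 = {r.gene_id: r for r in de_4c_paternal}
    mat4 = {r.gene_id: r for r in de_4c_maternal}
    paticm = {r.gene_id: r for r in de_icm_paternal}
    for name, table in (
        ("4C paternal DE", pat4), ("4C maternal DE", mat4),
        ("ICM paternal DE", paticm),
    ):
        if not table:
            raise ValueError(f"missing required table: {name}")
    candidates: list[str] = []
    for gid in sorted(pat4):
        p = prom.get(gid)
        if p is None or not p.is_cgi_promoter or p.n_exonic_variants < 1:
            continue
        r4 = pat4[gid]
        if not (r4.is_de and r4.log2_fold_change > 0):
            continue
        rm = mat4.get(gid)
        if rm is not None and rm.log2_fold_change >= 1.0:  # maternal fold >= 2
            continue
        ri = paticm.get(gid)
        if ri is not None and ri.is_de and ri.log2_fold_change > 0:
            continue
        wt_pct = _window_pct(wt2c_total, p.window, min_cpgs)
        ko_pct = _window_pct(ko2c_total, p.window, min_cpgs)
        sp_pct = _window_pct(sperm, p.window, min_cpgs)
        oo_pct = _window_pct(oocyte, p.window, min_cpgs)
        if None in (wt_pct, ko_pct, sp_pct, oo_pct):
            continue
        if wt_pct - max(sp_pct, oo_pct) < meth_gain_min:
            continue
        if ko_pct >= meth_hypo_max:
            continue
        candidates.append(gid)
    return candidates


@dataclass
class GdmrRecord:
    region: GenomeInterval
    name: str
    wt_pct: float | None
    ko_pct: float | None
    oocyte_pct: float | None
    sperm_pct: float | None
    parent_of_origin: str  # maternal | paternal | ambiguous | unassessed


def gdmr_comparison(
    gdmrs: list[tuple],
    wt2c_total: SampleMethylome,
    ko2c_total: SampleMethylome,
    oocyte: SampleMethylome,
    sperm: SampleMethylome,
    min_cpgs: int = 2,
    origin_margin: float = 40.0,
) -> list[GdmrRecord]:
    """Total methylation over imprinted gametic DMRs in WT vs matKO.

    ``gdmrs`` is a list of (name, GenomeInterval).  A gDMR is maternal
    when oocyte exceeds sperm by >= origin_margin points (paternal for the
    converse); gDMRs not informative in both embryo samples are listed as
    unassessed.
    """
    out: list[GdmrRecord] = []
    for name, region in gdmrs:
        wt = _window_pct(wt2c_total, region, min_cpgs)
        ko = _window_pct(ko2c_total, region, min_cpgs)
        oo = _window_pct(oocyte, region, min_cpgs)
        sp = _window_pct(sperm, region, min_cpgs)
        if oo is not None and sp is not None and oo - sp >= origin_margin:
            origin = "maternal"
        elif oo is not None and sp is not None and sp - oo >= origin_margin:
            origin = "paternal"
        else:
            origin = "ambiguous"
        if wt is None or ko is None:
            out.append(GdmrRecord(region, name, wt, ko, oo, sp, "unassessed"))
        else:
            out.append(GdmrRecord(region, name, wt, ko, oo, sp, origin))
    return out
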