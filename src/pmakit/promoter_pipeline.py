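"""The curated CGI-promoter funnel and promoter-level PMA calling.

Filter funnel, applied to all annotated autosomal promoters:

1. strain consistency — sperm methylation must agree (both low or both
   high) between the two parental strains; promoters hypomethylated in one
   strain but methylated in the other are excluded as strain effects;
2. CGI / H3K4me3 — keep intermediate-to-high CpG-density promoters with
   sperm H3K4me3 RPKM >= 1;
3. allele assessability — the window must contain a genetic variant (so
   reads can be assigned to a parent) and be informative in both sperm and
   embryo-paternal methylomes;
4. PMA call — paternal 2-cell window methylation minus sperm methylation
   >= gain_min percentage points.

Called PMA promoters are further classified by ICM paternal persistence
(< 5 %% hypo, 5-20 %% intermediate, >= 20 %% retained) and cross-checked in
uniparental (androgenetic / parthenogenetic) embryos, which carry a single
parental genome type and therefore need no variant-based read splitting.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_annotation import GenomeInterval, PromoterRecord
from .methylome import SampleMethylome, region_methylation
from .pma_detection import PMACall

__all__ = [
    "PersistenceRecord",
    "FunnelReport",
    "strain_consistency_filter",
    "cgi_h3k4_filter",
    "allele_coverage_filter",
    "call_promoter_pma",
    "classify_persistence",
    "uniparental_gain",
    "funnel_report",
]


@dataclass
class PersistenceRecord:
    gene_id: str
    icm_paternal_pct: float | None
    persistence_class: str  # hypo | intermediate | retained | no-coverage


@dataclass
class FunnelReport:
    counts: dict
    labels: dict  # gene_id -> list of filter labels


def _window_pct(methylome: SampleMethylome, window: GenomeInterval,
                min_cpgs: int = 2) -> float | None:
    return region_methylation(methylome, window, min_cpgs).mean_pct


def strain_consistency_filter(
    sperm_strain_a: SampleMethylome,
    sperm_strain_b: SampleMethylome,
    promoters: list[PromoterRecord],
    low_max: float = 20.0,
    high_min: float = 80.0,
    specific_other_min: float = 50.0,
    min_cpgs: int = 2,
) -> dict:
    """Label promoters by cross-strain sperm methylation agreement.

    Labels: consistent-low, consistent-high, strain-specific-hypo-a,
    strain-specific-hypo-b, inconsistent, unassessed.  Downstream stages
    keep consistent-low promoters (the hypomethylated-CGI analysis).
    """
    labels: dict[str, str] = {}
    for p in promoters:
        a = _window_pct(sperm_strain_a, p.window, min_cpgs)
        b = _window_pct(sperm_strain_b, p.window, min_cpgs)
        if a is None or b is None:
            labels[p.gene_id] = "unassessed"
        elif a < low_max and b < low_max:
            labels[p.gene_id] = "consistent-low"
        elif a > high_min and b > high_min:
            labels[p.gene_id] = "consistent-high"
        elif a < low_max and b > specific_other_min:
            labels[p.gene_id] = "strain-specific-hypo-a"
        elif b < low_max and a > specific_other_min:
            labels[p.gene_id] = "strain-specific-hypo-b"
        else:
            labels[p.gene_id] = "inconsistent"
        p.filter_labels.add(labels[p.gene_id])
    return labels


def cgi_h3k4_filter(
    promoters: list[PromoterRecord],
    h3k4_rpkm_min: float = 1.0,
) -> list[PromoterRecord]:
    """Keep CGI promoters (intermediate/high CpG density) with sperm
    H3K4me3 RPKM >= h3k4_rpkm_min (inclusive)."""
    missing = [p.gene_id for p in promoters if p.h3k4me3_rpkm is None]
    if missing:
        raise ValueError(f"promoters missing H3K4me3 scores: {missing[:10]}")
    kept = [
        p for p in promoters
        if p.is_cgi_promoter and p.h3k4me3_rpkm >= h3k4_rpkm_min
    ]
    for p in kept:
        p.filter_labels.add("cgi_h3k4_pass")
    return kept


def allele_coverage_filter(
    promoters: list[PromoterRecord],
    variants: list[tuple],
    sperm: SampleMethylome,
    embryo_paternal: SampleMethylome,
    min_cpgs: int = 2,
) -> list[PromoterRecord]:
    """Keep promoters whose window holds >= 1 variant and is informative
    in both sperm and embryo-paternal methylomes.

    ``variants`` is a list of (chrom, pos) with 0-based positions; any
    variant record type (SNV or INDEL) counts by position.
    """
    kept: list[PromoterRecord] = []
    for p in promoters:
        n_var = sum(1 for chrom, pos in variants if p.window.contains(chrom, pos))
        p.n_window_variants = n_var
        if n_var == 0:
            continue
        if not region_methylation(sperm, p.window, min_cpgs).informative:
            continue
        if not region_methylation(embryo_paternal, p.window, min_cpgs).informative:
            continue
        p.filter_labels.add("allele_assessable")
        kept.append(p)
    return kept


def call_promoter_pma(
    assessable: list[PromoterRecord],
    sperm: SampleMethylome,
    embryo_paternal: SampleMethylome,
    gain_min: float = 30.0,
    min_cpgs: int = 2,
) -> list[PMACall]:
    """PMA iff embryo-paternal window mean minus sperm mean >= gain_min."""
    calls: list[PMACall] = []
    for p in assessable:
        g = _window_pct(sperm, p.window, min_cpgs)
        e = _window_pct(embryo_paternal, p.window, min_cpgs)
        if g is None or e is None:
            continue
        if e - g >= gain_min:
            p.filter_labels.add("pma")
            calls.append(
                PMACall(p.window, g, e, category="TSS", source="promoter")
            )
    return calls


def classify_persistence(
    pma_promoters: list[PromoterRecord],
    icm_paternal: SampleMethylome,
    min_cpgs: int = 2,
    hypo_max: float = 5.0,
    retained_min: float = 20.0,
) -> list[PersistenceRecord]:
    """Class ICM paternal persistence of PMA promoters.

    < hypo_max: hypo; [hypo_max, retained_min): intermediate;
    >= retained_min: retained.  Promoters without informative ICM
    allele-specific coverage are reported as "no-coverage".
    """
    out: list[PersistenceRecord] = []
    for p in pma_promoters:
        pct = _window_pct(icm_paternal, p.window, min_cpgs)
        if pct is None:
            out.append(PersistenceRecord(p.gene_id, None, "no-coverage"))
        elif pct < hypo_max:
            out.append(PersistenceRecord(p.gene_id, pct, "hypo"))
        elif pct < retained_min:
            out.append(PersistenceRecord(p.gene_id, pct, "intermediate"))
        else:
            out.append(PersistenceRecord(p.gene_id, pct, "retained"))
    return out


def uniparental_gain(
    child: SampleMethylome,
    gamete: SampleMethylome,
    promoters: list[PromoterRecord],
    gain_min: float = 20.0,
    min_cpgs: int = 2,
) -> list[str]:
    """Promoters gaining >= gain_min points in a uniparental embryo
    relative to the corresponding gamete (both total methylomes)."""
    gained: list[str] = []
    for p in promoters:
        c = _window_pct(child, p.window, min_cpgs)
        g = _window_pct(gamete, p.window, min_cpgs)
        if c is None or g is None:
            continue
        if c - g >= gain_min:
            gained.append(p.gene_id)
    return gained


def funnel_report(
    all_promoters: list[PromoterRecord],
    strain_labels: dict,
    cgi_h3k4_pass: list[PromoterRecord],
    assessable: list[PromoterRecord],
    pma_calls: list[PMACall],
) -> FunnelReport:
    """Per-stage counts and the per-promoter label trail."""
    n_consistent = sum(
        1 for v in strain_labels.values() if v.startswith("consistent")
    )
    counts = {
        "all_promoters": len(all_promoters),
        "consistent": n_consistent,
        "consistent_low": sum(
            1 for v in strain_labels.values() if v == "consistent-low"
        ),
        "strain_specific_a": sum(
            1 for v in strain_labels.values() if v == "strain-specific-hypo-a"
        ),
        "strain_specific_b": sum(
            1 for v in strain_labels.values() if v == "strain-specific-hypo-b"
        ),
        "cgi_h3k4_pass": len(cgi_h3k4_pass),
        "allele_assessable": len(assessable),
        "pma_called": len(pma_calls),
    }
    labels = {p.gene_id: sorted(p.filter_labels) for p in all_promoters}
    return FunnelReport(counts=counts, labels=labels)
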