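"""Genome-wide calling of paternal DNA-methylation acquisition (PMA).

A 600-bp sliding bin is scored as PMA when its sperm (paternal gamete)
methylation is below ``hypo_max`` (default 20 %%) and the 2-cell paternal
level exceeds it by at least ``gain_min`` percentage points (default 30).
Only bins informative in *both* methylomes enter the comparison: bins
without co-informative coverage are excluded from both the PMA set and the
hypomethylated denominator.  Adjacent/overlapping PMA bins are merged into
maximal regions and categorised as "TSS" when they touch any annotated
TSS +/- 300 bp window, else "Other".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_annotation import GenomeInterval
from .methylome import RegionMethylation, SampleMethylome, region_methylation
from .stats_util import TestResult, chi_square_gof

__all__ = [
    "PMACall",
    "call_pma_bins",
    "merge_pma_regions",
    "pma_summary",
    "annotation_enrichment",
]


@dataclass
class PMACall:
    region: GenomeInterval
    gamete_pct: float
    embryo_pct: float
    category: str = "Other"  # TSS | Other
    source: str = "bin"  # bin | promoter

    @property
    def gain(self) -> float:
        return self.embryo_pct - self.gamete_pct


def call_pma_bins(
    sperm_bins: list[RegionMethylation],
    embryo_bins: list[RegionMethylation],
    hypo_max: float = 20.0,
    gain_min: float = 30.0,
) -> tuple[list[PMACall], int]:
    """Score co-informative bins; returns (PMA calls, hypomethylated count).

    The denominator is the number of co-informative bins hypomethylated in
    sperm (< hypo_max); the PMA calls are its subset with gain >= gain_min.
    """
    if len(sperm_bins) != len(embryo_bins):
        raise ValueError("bin lists differ in length")
    calls: list[PMACall] = []
    n_hypo = 0
    for sb, eb in zip(sperm_bins, embryo_bins):
        if sb.region != eb.region:
            raise ValueError("mismatched bin definitions between samples")
        if not (sb.informative and eb.informative):
            continue
        if sb.mean_pct < hypo_max:
            n_hypo += 1
            if eb.mean_pct - sb.mean_pct >= gain_min:
                calls.append(PMACall(sb.region, sb.mean_pct, eb.mean_pct))
    return calls, n_hypo


def merge_pma_regions(
    pma_bins: list[PMACall],
    tss_windows: list[GenomeInterval],
    sperm: SampleMethylome | None = None,
    embryo: SampleMethylome | None = None,
    min_cpgs: int = 2,
) -> list[PMACall]:
    """Merge overlapping PMA bins into maximal regions and categorise them.

    Levels over the merged interval are recomputed from the methylomes when
    provided, else averaged over the constituent bins.  A merged region is
    "TSS" if it overlaps any TSS window by >= 1 bp.
    """
    if not pma_bins:
        return []
    bins = sorted(pma_bins, key=lambda c: (c.region.chrom, c.region.start))
    groups: list[list[PMACall]] = [[bins[0]]]
    cur_end = bins[0].region.end
    for c in bins[1:]:
        if c.region.chrom == groups[-1][0].region.chrom and c.region.start <= cur_end:
            groups[-1].append(c)
            cur_end = max(cur_end, c.region.end)
        else:
            groups.append([c])
            cur_end = c.region.end
    out: list[PMACall] = []
    for grp in groups:
        chrom = grp[0].region.chrom
        start = min(g.region.start for g in grp)
        end = max(g.region.end for g in grp)
        region = GenomeInterval(chrom, start, end)
        if sperm is not None and embryo is not None:
            g_pct = region_methylation(sperm, region, min_cpgs).mean_pct
            e_pct = region_methylation(embryo, region, min_cpgs).mean_pct
            if g_pct is None or e_pct is None:  # fall back to bin averages
                g_pct = float(np.mean([g.gamete_pct for g in grp]))
                e_pct = float(np.mean([g.embryo_pct for g in grp]))
        else:
            g_pct = float(np.mean([g.gamete_pct for g in grp]))
            e_pct = float(np.mean([g.embryo_pct for g in grp]))
        category = "TSS" if any(region.overlaps(w) for w in tss_windows) else "Other"
        out.append(PMACall(region, g_pct, e_pct, category=category, source="bin"))
    return out


def pma_summary(
    merged_regions: list[PMACall], n_pma_bins: int, n_hypo_bins: int
) -> dict:
    """Total PMA bp, PMA fraction of hypomethylated bins, category counts."""
    if n_hypo_bins <= 0:
        raise ValueError("hypomethylated bin count must be > 0")
    total_bp = int(sum(len(c.region) for c in merged_regions))
    by_cat = {"TSS": 0, "Other": 0}
    for c in merged_regions:
        by_cat[c.category] += 1
    return {
        "total_bp": total_bp,
        "n_regions": len(merged_regions),
        "n_pma_bins": n_pma_bins,
        "n_hypomethylated_bins": n_hypo_bins,
        "pma_fraction_pct": 100.0 * n_pma_bins / n_hypo_bins,
        "n_tss": by_cat["TSS"],
        "n_other": by_cat["Other"],
    }


# precedence for assigning PMA base pairs to exclusive annotation classes
CLASS_PRECEDENCE = ("TSS", "enhancer", "intragenic", "intergenic")


def _interval_arrays(intervals: list[GenomeInterval]) -> dict:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: _merge_pairs(v) for c, v in by_chrom.items()}


def _merge_pairs(pairs: list[tuple[int, int]]) -> np.ndarray:
    pairs = sorted(pairs)
    merged = [list(pairs[0])]
    for s, e in pairs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def _subtract_pairs(pairs: np.ndarray, minus: np.ndarray) -> np.ndarray:
    """Interval-list subtraction on merged, sorted (start, end) arrays."""
    if pairs.size == 0:
        return pairs.reshape(0, 2)
    if minus.size == 0:
        return pairs
    out = []
    for s, e in pairs:
        cursor = s
        for ms, me_ in minus:
            if me_ <= cursor or ms >= e:
                continue
            if ms > cursor:
                out.append((cursor, ms))
            cursor = max(cursor, me_)
            if cursor >= e:
                break
        if cursor < e:
            out.append((cursor, e))
    return (np.asarray(out, dtype=np.int64).reshape(-1, 2)
            if out else np.empty((0, 2), dtype=np.int64))


def annotation_enrichment(
    merged_regions: list[PMACall],
    annotation_classes: dict,
) -> tuple[TestResult, dict]:
    """Chi-squared enrichment of PMA base pairs over annotation classes.

    ``annotation_classes`` maps class name (TSS, enhancer, intragenic,
    intergenic) to its interval list; together the classes cover the
    mappable genome.  Each PMA base pair is assigned to the highest-
    precedence overlapping class; expected proportions are the genome-wide
    class sizes.
    """
    if not merged_regions:
        raise ValueError("no PMA regions to test")
    unknown = set(annotation_classes) - set(CLASS_PRECEDENCE)
    if unknown:
        raise ValueError(f"unknown annotation classes: {sorted(unknown)}")
    arrays = {k: _interval_arrays(v) for k, v in annotation_classes.items()}
    observed: dict[str, int] = {k: 0 for k in CLASS_PRECEDENCE if k in arrays}
    for call in merged_regions:
        region = call.region
        length = len(region)
        remaining = [(region.start, region.end)]
        assigned = 0
        for cls in CLASS_PRECEDENCE:
            if cls not in arrays or not remaining:
                continue
            pairs = arrays[cls].get(region.chrom, np.empty((0, 2), dtype=np.int64))
            next_remaining: list[tuple[int, int]] = []
            for rs, re_ in remaining:
                cursor = rs
                for cs, ce in pairs:
                    if ce <= cursor or cs >= re_:
                        continue
                    s, e = max(cs, cursor), min(ce, re_)
                    if s > cursor:
                        next_remaining.append((cursor, s))
                    observed[cls] += e - s
                    assigned += e - s
                    cursor = e
                if cursor < re_:
                    next_remaining.append((cursor, re_))
            remaining = next_remaining
        if assigned < length:
            raise ValueError(
                f"annotation classes do not cover PMA region "
                f"{region.chrom}:{region.start}-{region.end}"
            )
    # genome-wide class sizes under the same precedence carve-up: a class's
    # effective bp excludes bp claimed by higher-precedence classes
    genome_bp = {k: 0 for k in observed}
    chroms = {c for k in observed for c in arrays[k]}
    for chrom in chroms:
        claimed = np.empty((0, 2), dtype=np.int64)
        for cls in CLASS_PRECEDENCE:
            if cls not in arrays:
                continue
            pairs = arrays[cls].get(chrom, np.empty((0, 2), dtype=np.int64))
            effective = _subtract_pairs(pairs, claimed)
            genome_bp[cls] += int((effective[:, 1] - effective[:, 0]).sum())
            if pairs.size:
                claimed = _merge_pairs(
                    [tuple(p) for p in claimed] + [tuple(p) for p in pairs]
                )
    total_genome = sum(genome_bp.values())
    classes = list(observed)
    proportions = [genome_bp[k] / total_genome for k in classes]
    counts = [observed[k] for k in classes]
    result = chi_square_gof(counts, proportions)
    table = {
        "classes": classes,
        "observed_bp": counts,
        "expected_proportion": proportions,
        "observed_proportion": [c / sum(counts) for c in counts],
    }
    return result, table
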