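"""Window-based histone-mark scoring (RPKM) and enrichment flags.

H3K4me3 is scored over TSS +/- 300 bp (enriched at RPKM >= 1),
H3K27me3 over TSS +/- 10 kb domains (RPKM >= 0.5) and H3K9me3 over
arbitrary regions (RPKM >= 1).  A read counts toward a window if it
overlaps it by at least one base pair; fractional assignment is available
via ``mode="midpoint"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_annotation import GenomeInterval
from .stats_util import TestResult, welch_ttest

__all__ = [
    "MarkReadSet",
    "score_mark",
    "h3k27me3_domain_flag",
    "h3k9me3_flag",
    "compare_mark_between_sets",
]

MARKS = ("H3K4me3", "H3K9me3", "H3K27me3")


@dataclass
class MarkReadSet:
    """Aligned-read intervals for one ChIP library.

    ``library_size`` is the total number of mapped reads used for RPKM
    normalisation; it is at least the number of stored reads (reads on
    unanalysed chromosomes still count toward depth).
    """

    mark: str
    sample_id: str
    allele: str = "total"
    reads: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end"]))
    library_size: int = 0

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}; expected one of {MARKS}")
        if self.library_size < len(self.reads):
            raise ValueError("library_size smaller than stored read count")
        self.reads = self.reads.sort_values(
            ["chrom", "start"], kind="mergesort"
        ).reset_index(drop=True)
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.reads.groupby("chrom", sort=False):
            self._index[str(chrom)] = (
                sub["start"].to_numpy(), sub["end"].to_numpy()
            )

    def count_overlapping(self, region: GenomeInterval, mode: str = "any") -> int:
        if region.chrom not in self._index:
            return 0
        starts, ends = self._index[region.chrom]
        if mode == "any":
            return int(((starts < region.end) & (ends > region.start)).sum())
        if mode == "midpoint":
            mid = (starts + ends) // 2
            return int(((mid >= region.start) & (mid < region.end)).sum())
        raise ValueError(f"unknown overlap mode {mode!r}")


def score_mark(reads: MarkReadSet, region: GenomeInterval, mode: str = "any") -> float:
    """RPKM of a read set over a region: n * 1e9 / (library_size * length)."""
    if reads.library_size <= 0:
        raise ValueError("library_size must be > 0")
    n = reads.count_overlapping(region, mode=mode)
    return n * 1e9 / (reads.library_size * len(region))


def h3k27me3_domain_flag(
    reads: MarkReadSet,
    tss: int,
    chrom: str,
    chrom_length: int,
    flank: int = 10_000,
    min_rpkm: float = 0.5,
) -> bool:
    """True iff the TSS +/- flank domain scores RPKM >= min_rpkm."""
    region = GenomeInterval(chrom, max(0, tss - flank), min(chrom_length, tss + flank))
    return score_mark(reads, region) >= min_rpkm


def h3k9me3_flag(reads: MarkReadSet, region: GenomeInterval,
                 min_rpkm: float = 1.0) -> bool:
    """True iff the region scores RPKM >= min_rpkm (inclusive)."""
    return score_mark(reads, region) >= min_rpkm


def compare_mark_between_sets(scores_a, scores_b) -> TestResult:
    """Welch two-sided t-test between two per-promoter score vectors.

    For a "change" comparison pass per-promoter deltas (e.g. 2C paternal
    minus sperm) as the score vectors.
    """
    return welch_ttest(scores_a, scores_b)
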