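"""Sequence-derived annotation: CpG sites, CpG islands, promoter windows
and promoter CpG-density classes.

Coordinates are 0-based, half-open throughout the package; BED output is
native, 1-based inputs (GTF-like tables, coverage files) are converted on
read. ``N`` bases count toward interval length but never toward C/G/CpG
tallies.

A CpG island here is any maximal interval with GC content > 50 %%,
observed/expected CpG ratio > 0.6 and length > 200 bp.  Promoters are
classified by the obs/exp CpG ratio of the TSS +/- ``flank`` window into
high / intermediate / low density; high-plus-intermediate promoters are the
"CGI promoters" used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GenomeInterval",
    "GeneModel",
    "PromoterRecord",
    "enumerate_cpg_sites",
    "cpg_ratio",
    "gc_content",
    "detect_cgis",
    "promoter_window",
    "classify_promoter",
]


@dataclass(frozen=True)
class GenomeInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: TSS is the first transcribed base on the gene
    strand (for minus-strand genes that is the rightmost exonic base)."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple  # tuple of (start, end), 0-based half-open, sorted

    @property
    def tss(self) -> int:
        if self.strand == "-":
            return self.exons[-1][1] - 1
        return self.exons[0][0]

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class PromoterRecord:
    """A TSS with its window and the annotation the filter funnel needs."""

    gene_id: str
    tss: GenomeInterval
    window: GenomeInterval
    cpg_ratio: float
    gc_content: float
    density_class: str  # high | intermediate | low
    is_cgi_promoter: bool
    h3k4me3_rpkm: float | None = None
    n_exonic_variants: int = 0
    n_window_variants: int = 0
    filter_labels: set = field(default_factory=set)


def _seq_array(sequence: str) -> np.ndarray:
    return np.frombuffer(sequence.upper().encode("ascii"), dtype="S1")


def enumerate_cpg_sites(sequence: str) -> np.ndarray:
    """0-based positions of the plus-strand C of every CpG dinucleotide."""
    if len(sequence) < 2:
        return np.empty(0, dtype=np.int64)
    arr = _seq_array(sequence)
    hits = (arr[:-1] == b"C") & (arr[1:] == b"G")
    return np.flatnonzero(hits).astype(np.int64)


def gc_content(sequence: str) -> float:
    """Fraction of G+C over the full sequence length (Ns dilute)."""
    if not sequence:
        raise ValueError("empty sequence")
    arr = _seq_array(sequence)
    return float(((arr == b"C") | (arr == b"G")).sum() / len(arr))


def cpg_ratio(sequence: str) -> float:
    """Observed/expected CpG ratio: obs CpG count / (#C * #G / L).

    Returns 0 when the sequence contains no C or no G.
    """
    if not sequence:
        raise ValueError("empty sequence")
    arr = _seq_array(sequence)
    n_c = int((arr == b"C").sum())
    n_g = int((arr == b"G").sum())
    if n_c * n_g == 0:
        return 0.0
    obs = int(((arr[:-1] == b"C") & (arr[1:] == b"G")).sum()) if len(arr) > 1 else 0
    expected = n_c * n_g / len(arr)
    return obs / expected


def _window_ok(seq: str, min_gc: float, min_ratio: float) -> bool:
    return gc_content(seq) > min_gc and cpg_ratio(seq) > min_ratio


def detect_cgis(
    sequence: str,
    chrom: str = "chr1",
    *,
    min_gc: float = 0.50,
    min_obs_exp: float = 0.60,
    min_length: int = 200,
    window: int = 200,
    step: int = 1,
) -> list[GenomeInterval]:
    """Maximal CpG islands satisfying all three criteria.

    Strategy: slide a ``window``-bp window, flag windows meeting the GC and
    obs/exp criteria, merge overlapping flagged windows into maximal runs,
    trim each run to its outermost CpG dinucleotides (an island starts and
    ends on a CpG), and finally re-verify all three criteria on every
    emitted interval.  Islands are returned sorted and non-overlapping.
    """
    n = len(sequence)
    if n < min_length:
        return []
    arr = _seq_array(sequence)
    is_c = (arr == b"C").astype(np.int64)
    is_g = (arr == b"G").astype(np.int64)
    is_cpg = np.zeros(n, dtype=np.int64)
    is_cpg[:-1] = (arr[:-1] == b"C") & (arr[1:] == b"G")
    csum_c = np.concatenate([[0], np.cumsum(is_c)])
    csum_g = np.concatenate([[0], np.cumsum(is_g)])
    csum_cpg = np.concatenate([[0], np.cumsum(is_cpg)])
    starts = np.arange(0, n - window + 1, step)
    ends = starts + window
    n_c = csum_c[ends] - csum_c[starts]
    n_g = csum_g[ends] - csum_g[starts]
    # CpGs fully inside the window: the C at the last window base pairs with
    # a G outside, so exclude it
    obs = csum_cpg[ends - 1] - csum_cpg[starts]
    gc_ok = (n_c + n_g) / window > min_gc
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n_c * n_g > 0, obs * window / (n_c * n_g), 0.0)
    ok = gc_ok & (ratio > min_obs_exp)
    flagged = [(int(s), int(s) + window) for s in starts[ok]]
    if not flagged:
        return []
    # merge overlapping/adjacent flagged windows into maximal runs
    merged: list[list[int]] = [list(flagged[0])]
    for s, e in flagged[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    cpgs = enumerate_cpg_sites(sequence)
    out: list[GenomeInterval] = []
    for s, e in merged:
        inside = cpgs[(cpgs >= s) & (cpgs + 2 <= e)]
        if inside.size == 0:
            continue
        s, e = int(inside[0]), int(inside[-1]) + 2
        if e - s <= min_length:
            continue
        if _window_ok(sequence[s:e], min_gc, min_obs_exp):  # re-verify post hoc
            out.append(GenomeInterval(chrom, s, e))
    return out


def promoter_window(
    tss: int, chrom: str, chrom_length: int, flank: int = 300, strand: str = "."
) -> GenomeInterval:
    """Symmetric TSS +/- flank window, clipped to the chromosome."""
    if flank <= 0:
        raise ValueError("flank must be > 0 (zero-width windows forbidden)")
    if not (0 <= tss < chrom_length):
        raise ValueError(f"TSS {tss} outside chromosome {chrom} [0, {chrom_length})")
    return GenomeInterval(
        chrom, max(0, tss - flank), min(chrom_length, tss + flank), strand
    )


def classify_promoter(
    gene: GeneModel,
    genome: dict,
    flank: int = 300,
    cgi_threshold: float = 0.12,
    high_threshold: float = 0.75,
) -> PromoterRecord:
    """Build a PromoterRecord with CpG-density class for one gene.

    density_class is ``high`` if the window's obs/exp CpG ratio is >=
    ``high_threshold``, ``intermediate`` if >= ``cgi_threshold`` (inclusive),
    else ``low``; CGI promoters are the non-low classes.
    """
    seq = genome[gene.chrom]
    win = promoter_window(gene.tss, gene.chrom, len(seq), flank, gene.strand)
    wseq = seq[win.start : win.end]
    ratio = cpg_ratio(wseq)
    gc = gc_content(wseq)
    if ratio >= high_threshold:
        cls = "high"
    elif ratio >= cgi_threshold:
        cls = "intermediate"
    else:
        cls = "low"
    return PromoterRecord(
        gene_id=gene.gene_id,
        tss=GenomeInterval(gene.chrom, gene.tss, gene.tss + 1, gene.strand),
        window=win,
        cpg_ratio=ratio,
        gc_content=gc,
        density_class=cls,
        is_cgi_promoter=cls != "low",
    )
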