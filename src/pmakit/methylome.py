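"""Per-CpG methylation call tables and region / sliding-bin methylation.

A :class:`SampleMethylome` holds destranded, coverage-filtered per-CpG
calls for one sample x allele.  Methylation over a region is the
*unweighted* mean of per-CpG levels, and a region is only *informative*
(scoreable) when it holds at least ``min_cpgs`` covered CpGs of which at
least one pair is separated by more than one sequencing read length — two
CpGs closer than a read length can be covered by the very same reads and
carry no independent evidence.

Input files use the bisulfite coverage dialect
``chrom  start(1-based)  end  methylation%%  count_methylated  count_unmethylated``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_annotation import GenomeInterval

__all__ = [
    "SampleMethylome",
    "RegionMethylation",
    "read_cpg_calls",
    "region_methylation",
    "genome_bins",
    "bin_methylation",
    "global_methylation_change",
]

_COV_COLUMNS = ["chrom", "start", "end", "pct", "meth", "unmeth"]


@dataclass
class SampleMethylome:
    """Destranded per-CpG calls for one sample x allele.

    ``calls`` columns: chrom (str), pos (0-based C of the CpG, int),
    meth, unmeth (read counts).  Positions are unique per chromosome and
    every stored call satisfies meth + unmeth >= min_informative_coverage.
    """

    sample_id: str
    allele: str  # total | maternal | paternal
    calls: pd.DataFrame
    read_length: int = 100
    min_informative_coverage: int = 5

    def __post_init__(self) -> None:
        if self.allele not in ("total", "maternal", "paternal"):
            raise ValueError(f"invalid allele {self.allele!r}")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        calls = self.calls.reset_index(drop=True)
        if len(calls) and calls.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate CpG positions in call table")
        self.calls = calls.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )

    @property
    def levels(self) -> pd.Series:
        """Per-CpG methylation level in percent."""
        c = self.calls
        return 100.0 * c["meth"] / (c["meth"] + c["unmeth"])

    def positions(self, chrom: str) -> np.ndarray:
        c = self.calls
        return c.loc[c["chrom"] == chrom, "pos"].to_numpy()


@dataclass
class RegionMethylation:
    region: GenomeInterval
    mean_pct: float | None
    n_informative: int
    informative: bool


def _destrand(df: pd.DataFrame) -> pd.DataFrame:
    """Merge plus/minus-strand records of one CpG by summing counts.

    A record at position p+1 is treated as the minus-strand G of the CpG
    whose C sits at p whenever a record at p exists on the same chromosome;
    lone records are kept at their own position (their C anchors a CpG we
    cannot see the partner of).
    """
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    same_chrom = df["chrom"].shift(1) == df["chrom"]
    adjacent = (df["pos"] - df["pos"].shift(1)) == 1
    is_minus = (same_chrom & adjacent).to_numpy()
    # a record can only absorb into a *plus* anchor, not chain: pos p+2
    # following p, p+1 starts a new CpG
    anchor = np.arange(len(df))
    for i in range(1, len(df)):
        if is_minus[i] and anchor[i - 1] == i - 1:
            anchor[i] = i - 1
    out = df.copy()
    out["anchor"] = anchor
    grouped = out.groupby("anchor", sort=True).agg(
        chrom=("chrom", "first"), pos=("pos", "first"), meth=("meth", "sum"),
        unmeth=("unmeth", "sum"),
    )
    return grouped.reset_index(drop=True)


def read_cpg_calls(
    path,
    sample_id: str,
    allele: str = "total",
    *,
    min_coverage: int = 5,
    read_length: int = 100,
    destrand: bool = True,
) -> SampleMethylome:
    """Read a coverage-dialect table into a :class:`SampleMethylome`.

    1-based starts are shifted to 0-based, plus/minus records of one CpG
    are merged by summing counts, and calls with total coverage below
    ``min_coverage`` are dropped.  A stated percentage disagreeing with the
    counts by more than 0.5 points raises a warning; counts win.
    """
    try:
        df = pd.read_csv(
            path, sep=r"\s+", names=_COV_COLUMNS, comment="#", header=None,
            dtype={"chrom": str},
        )
        df = df.astype({"start": int, "end": int, "pct": float, "meth": int,
                        "unmeth": int})
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed coverage file {path}: {exc}") from exc
    if ((df["meth"] < 0) | (df["unmeth"] < 0)).any():
        raise ValueError(f"negative read counts in {path}")
    total = df["meth"] + df["unmeth"]
    nonzero = total > 0
    implied = np.where(nonzero, 100.0 * df["meth"] / total.where(nonzero, 1), 0.0)
    bad = nonzero & (np.abs(implied - df["pct"]) > 0.5)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} records in {path} have a methylation % "
            "inconsistent with their counts; counts win",
            stacklevel=2,
        )
    calls = pd.DataFrame(
        {"chrom": df["chrom"], "pos": df["start"] - 1, "meth": df["meth"],
         "unmeth": df["unmeth"]}
    )
    calls = calls[(calls["meth"] + calls["unmeth"]) > 0]
    if destrand:
        calls = _destrand(calls)
    calls = calls[(calls["meth"] + calls["unmeth"]) >= min_coverage]
    return SampleMethylome(
        sample_id=sample_id,
        allele=allele,
        calls=calls.reset_index(drop=True),
        read_length=read_length,
        min_informative_coverage=min_coverage,
    )


def region_methylation(
    methylome: SampleMethylome, region: GenomeInterval, min_cpgs: int = 2
) -> RegionMethylation:
    """Mean methylation over a region, with the informativeness rule.

    Informative iff the region holds >= ``min_cpgs`` calls and the two
    extreme call positions are more than one read length apart.
    """
    c = methylome.calls
    sel = c[(c["chrom"] == region.chrom) & (c["pos"] >= region.start)
            & (c["pos"] < region.end)]
    n = len(sel)
    informative = bool(
        n >= min_cpgs
        and (sel["pos"].max() - sel["pos"].min()) > methylome.read_length
    )
    mean_pct = None
    if informative:
        lv = 100.0 * sel["meth"] / (sel["meth"] + sel["unmeth"])
        mean_pct = float(lv.mean())
    return RegionMethylation(region, mean_pct, n, informative)


def genome_bins(
    chrom_sizes: dict, width: int = 600, overlap: int = 100
) -> list[GenomeInterval]:
    """Overlapping genome-wide bins (step = width - overlap).

    Bins start at 0; the final bin is clipped to the chromosome end and
    dropped if shorter than the step.
    """
    if not width > overlap >= 0:
        raise ValueError("require width > overlap >= 0")
    step = width - overlap
    bins: list[GenomeInterval] = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, step):
            end = min(start + width, size)
            if end - start < step:
                continue
            bins.append(GenomeInterval(chrom, start, end))
    return bins


def bin_methylation(
    methylome: SampleMethylome, bins: list[GenomeInterval], min_cpgs: int = 2
) -> list[RegionMethylation]:
    """Vectorised :func:`region_methylation` over many sorted bins."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    c = methylome.calls
    for chrom, sub in c.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        lv = (100.0 * sub["meth"] / (sub["meth"] + sub["unmeth"])).to_numpy()
        cum = np.concatenate([[0.0], np.cumsum(lv)])
        by_chrom[str(chrom)] = (pos, cum)
    out: list[RegionMethylation] = []
    rl = methylome.read_length
    for b in bins:
        if b.chrom not in by_chrom:
            out.append(RegionMethylation(b, None, 0, False))
            continue
        pos, cum = by_chrom[b.chrom]
        lo = int(np.searchsorted(pos, b.start, side="left"))
        hi = int(np.searchsorted(pos, b.end, side="left"))
        n = hi - lo
        informative = n >= min_cpgs and (pos[hi - 1] - pos[lo]) > rl
        mean_pct = float((cum[hi] - cum[lo]) / n) if informative else None
        out.append(RegionMethylation(b, mean_pct, n, bool(informative)))
    return out


def global_methylation_change(
    bins_a: list[RegionMethylation], bins_b: list[RegionMethylation]
) -> float:
    """Mean (b - a) level over co-informative bins, in percentage points."""
    if len(bins_a) != len(bins_b):
        raise ValueError("bin lists must align")
    deltas = [
        b.mean_pct - a.mean_pct
        for a, b in zip(bins_a, bins_b)
        if a.informative and b.informative
    ]
    if not deltas:
        raise ValueError("no co-informative bins")
    return float(np.mean(deltas))
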