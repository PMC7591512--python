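"""Miniature F1-hybrid multi-stage dataset with known ground truth.

Emulates the C57BL/6J (maternal) x DBA/2J (paternal) hybrid design: two
haplotypes differing only at substitution sites, stage-specific true
methylomes (sperm of both strains, GV/MII oocyte, 2-cell, ICM,
androgenetic and parthenogenetic blastocysts, maternal-Dnmt3a-knockout
2-cell), binomial read sampling at configurable coverage, histone-mark
read tracks and allele-resolved expression counts.  A configurable subset
of CGI promoters carries a planted paternal 2-cell methylation gain (PMA)
and a subset of those a planted paternal upregulation in knockout embryos,
so recall/precision of every downstream caller can be measured against the
truth manifest.

Sequence composition is CpG-suppressed outside promoters (a first-order
Markov chain with a low G-after-C probability, mimicking genomic CpG
depletion), while promoter windows are seeded CpG-rich or -intermediate so
CpG-island detection and density classes have true positives.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .chromatin_association import MarkReadSet
from .expression_analysis import ExpressionRecord
from .genome_annotation import GeneModel, GenomeInterval, enumerate_cpg_sites
from .methylome import SampleMethylome

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "MethProfile",
    "generate_truth",
    "simulate_methylome",
    "simulate_chip_track",
    "simulate_expression_counts",
    "write_dataset",
]

BASES = np.array([b"A", b"C", b"G", b"T"])


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic dataset."""

    n_chroms: int = 2
    chrom_length: int = 260_000
    n_genes: int = 200
    n_planted_pma: int = 20
    n_planted_de: int = 5
    snv_rate: float = 0.005  # per bp, roughly the B6xDBA SNV density
    coverage_mean: float = 15.0  # reads per CpG per allele
    read_length: int = 100
    planted_gain: float = 0.40  # paternal 2C promoter gain at planted genes
    overdispersion: float = 0.0  # beta-binomial rho; 0 = pure binomial
    oocyte_hyper_fraction: float = 0.15
    n_gdmrs_maternal: int = 6
    n_gdmrs_paternal: int = 3
    promoter_hypo: float = 0.02  # sperm CGI promoters ~2%
    oocyte_hyper_level: float = 0.85
    background: dict = field(default_factory=lambda: {
        "sperm": 0.80, "oocyte": 0.40,
        "2C_maternal": 0.32, "2C_paternal": 0.40,
        "ICM_maternal": 0.25, "ICM_paternal": 0.25,
        "andro": 0.20, "partheno": 0.25,
        "matKO_maternal": 0.05, "matKO_paternal": 0.40,
    })
    # expression
    expr_baseline_mean: float = 100.0  # per-allele NB mean
    expr_dispersion: float = 0.05
    expr_library_size: int = 1_000_000
    expr_replicates: int = 2
    planted_fold: float = 4.0
    de_stage: str = "4C"
    de_allele: str = "paternal"
    # ChIP
    chip_library_size: int = 1_000_000
    chip_promoter_rpkm: float = 16.0
    chip_domain_rpkm: float = 2.0
    chip_background_rpkm: float = 0.05
    seed: int = 42

    def validate(self) -> None:
        if self.n_planted_pma > self.n_genes:
            raise ValueError("n_planted_pma exceeds n_genes")
        if self.n_planted_de > self.n_planted_pma:
            raise ValueError("n_planted_de exceeds n_planted_pma")
        if not (0 <= self.snv_rate < 1):
            raise ValueError("snv_rate must be in [0, 1)")
        if self.coverage_mean < 0:
            raise ValueError("coverage_mean must be >= 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        if not (0 <= self.planted_gain <= 1):
            raise ValueError("planted_gain must be a fraction")
        if not (0 <= self.overdispersion < 1):
            raise ValueError("overdispersion must be in [0, 1)")
        for k, v in self.background.items():
            if not (0 <= v <= 1):
                raise ValueError(f"background[{k}] outside [0, 1]")


# gene slot layout: promoter +/-300 around a TSS centred in a fixed-size
# slot, with the gene body confined to the slot
_SLOT = 2400
_MARGIN = 1000


@dataclass
class MethProfile:
    """Piecewise-constant true methylation: interval features over a
    background level.  Feature intervals must not overlap."""

    background: float
    features: list  # (chrom, start, end, fraction)

    def value(self, chrom: str, pos: int) -> float:
        for c, s, e, v in self.features:
            if c == chrom and s <= pos < e:
                return v
        return self.background

    def values(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        out = np.full(positions.shape, self.background, dtype=float)
        for c, s, e, v in self.features:
            if c == chrom:
                out[(positions >= s) & (positions < e)] = v
        return out


@dataclass
class TruthSet:
    """Everything downstream callers can be graded against."""

    genome: dict  # haplotype -> {chrom: sequence}
    genes: list  # GeneModel
    promoter_class_truth: dict  # gene_id -> high | intermediate | low
    snvs: list  # (chrom, pos, ref_base, alt_base)
    true_meth: dict  # (sample_id, allele) -> MethProfile
    planted_pma: list  # gene ids
    planted_de: list  # (gene_id, stage, allele, fold)
    oocyte_hyper: list  # gene ids hypermethylated in oocytes
    persistence_truth: dict  # planted gene_id -> hypo|intermediate|retained
    gdmrs: list  # (name, GenomeInterval, origin)
    expr_baseline: dict  # gene_id -> per-allele NB mean
    h3k4me3_enriched: list  # gene ids with sperm H3K4me3
    h3k27me3_domain: list  # gene ids inside 2C H3K27me3 domains
    config: SimulationConfig
    seed: int

    @property
    def chrom_sizes(self) -> dict:
        return {c: len(s) for c, s in self.genome["maternal_ref"].items()}

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def promoter_window(self, gene_id: str, flank: int = 300) -> GenomeInterval:
        g = self.gene(gene_id)
        size = self.chrom_sizes[g.chrom]
        return GenomeInterval(
            g.chrom, max(0, g.tss - flank), min(size, g.tss + flank), g.strand
        )

    def to_manifest(self) -> dict:
        """JSON-able truth manifest (no leakage into standard-format files)."""
        return {
            "seed": self.seed,
            "genes": [
                {"gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
                 "tss": g.tss, "exons": [list(e) for e in g.exons],
                 "promoter_class": self.promoter_class_truth[g.gene_id]}
                for g in self.genes
            ],
            "n_snvs": len(self.snvs),
            "planted_pma": list(self.planted_pma),
            "planted_de": [list(t) for t in self.planted_de],
            "oocyte_hyper": list(self.oocyte_hyper),
            "persistence_truth": dict(self.persistence_truth),
            "gdmrs": [
                {"name": n, "chrom": iv.chrom, "start": iv.start,
                 "end": iv.end, "origin": o}
                for n, iv, o in self.gdmrs
            ],
            "h3k4me3_enriched": list(self.h3k4me3_enriched),
            "h3k27me3_domain": list(self.h3k27me3_domain),
            "true_meth": {
                f"{sid}.{allele}": {
                    "background": prof.background,
                    "features": [list(f) for f in prof.features],
                }
                for (sid, allele), prof in sorted(self.true_meth.items())
            },
            "expr_baseline": dict(sorted(self.expr_baseline.items())),
            "config": asdict(self.config),
        }


def _sub_rng(seed: int, *tags: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, tag...)."""
    keys = [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng([seed, *keys])


def _markov_seq(rng: np.random.Generator, length: int, p_base: np.ndarray,
                p_g_after_c: float) -> np.ndarray:
    """CpG-tunable sequence: base composition p_base (A,C,G,T) with the
    G-after-C probability forced to p_g_after_c (CpG suppression or
    enrichment)."""
    after_c = p_base.copy()
    other = after_c[[0, 1, 3]]
    after_c[[0, 1, 3]] = other / other.sum() * (1 - p_g_after_c)
    after_c[2] = p_g_after_c
    draws = rng.random(length)
    cum_base = np.cumsum(p_base)
    cum_after_c = np.cumsum(after_c)
    out = np.empty(length, dtype=np.int8)
    prev_c = False
    for i in range(length):
        cum = cum_after_c if prev_c else cum_base
        b = int(np.searchsorted(cum, draws[i], side="right"))
        b = min(b, 3)
        out[i] = b
        prev_c = b == 1
    return out


_COMPOSITION = {
    # p_base over (A, C, G, T) and P(G | previous C): obs/exp CpG ratio is
    # roughly p_g_after_c / p_G
    # background: ~1 CpG / 60 bp at GC 0.42, near genomic CpG density;
    # low-class promoter windows are distinctly CpG-poor
    "background": (np.array([0.29, 0.21, 0.21, 0.29]), 0.08),
    "low": (np.array([0.29, 0.21, 0.21, 0.29]), 0.005),
    "intermediate": (np.array([0.25, 0.25, 0.25, 0.25]), 0.08),
    "high": (np.array([0.20, 0.30, 0.30, 0.20]), 0.30),
    "gdmr": (np.array([0.25, 0.25, 0.25, 0.25]), 0.08),
}


def _compose(rng: np.random.Generator, length: int, kind: str) -> np.ndarray:
    p_base, pgc = _COMPOSITION[kind]
    return _markov_seq(rng, length, p_base, pgc)


def _count_cpgs(codes: np.ndarray) -> int:
    return int(((codes[:-1] == 1) & (codes[1:] == 2)).sum())


def generate_truth(config: SimulationConfig) -> TruthSet:
    """Build the full ground-truth object (pure; writes nothing)."""
    config.validate()
    rng = _sub_rng(config.seed, "genome")
    n_slots_needed = config.n_genes + config.n_gdmrs_maternal + config.n_gdmrs_paternal
    slots_per_chrom = (config.chrom_length - 2 * _MARGIN) // _SLOT
    if slots_per_chrom * config.n_chroms < n_slots_needed:
        raise ValueError(
            f"chrom_length {config.chrom_length} too small: "
            f"{n_slots_needed} slots needed, "
            f"{slots_per_chrom * config.n_chroms} available"
        )

    # assign slots round-robin across chromosomes
    slots = []  # (chrom, slot_start)
    per_chrom = [0] * config.n_chroms
    for i in range(n_slots_needed):
        c = i % config.n_chroms
        slots.append((f"chr{c + 1}", _MARGIN + per_chrom[c] * _SLOT))
        per_chrom[c] += 1

    # promoter density classes; planted PMA genes drawn from CGI classes
    class_rng = _sub_rng(config.seed, "classes")
    classes = class_rng.choice(
        ["high", "intermediate", "low"], size=config.n_genes, p=[0.35, 0.35, 0.30]
    )
    gene_ids = [f"gene{i:04d}" for i in range(config.n_genes)]
    cgi_idx = [i for i, c in enumerate(classes) if c != "low"]
    if len(cgi_idx) < config.n_planted_pma:
        raise ValueError("not enough CGI promoters to host planted PMA genes")
    planted_idx = sorted(
        class_rng.choice(cgi_idx, size=config.n_planted_pma, replace=False)
    )
    planted = [gene_ids[i] for i in planted_idx]
    remaining_cgi = [i for i in cgi_idx if i not in set(planted_idx)]
    n_hyper = int(round(config.oocyte_hyper_fraction * len(remaining_cgi)))
    hyper_idx = sorted(
        class_rng.choice(remaining_cgi, size=n_hyper, replace=False)
    ) if n_hyper else []
    oocyte_hyper = [gene_ids[i] for i in hyper_idx]

    # chromosome sequences as int8 codes (0=A 1=C 2=G 3=T)
    chrom_codes = {
        f"chr{c + 1}": _compose(rng, config.chrom_length, "background")
        for c in range(config.n_chroms)
    }

    genes: list[GeneModel] = []
    strands = class_rng.choice(["+", "-"], size=config.n_genes)
    for i in range(config.n_genes):
        chrom, slot_start = slots[i]
        tss = slot_start + _SLOT // 2
        # seed the promoter window with class-matched composition; planted
        # genes are resampled until the window holds >= 4 CpGs
        for _ in range(50):
            codes = _compose(rng, 600, classes[i])
            if gene_ids[i] not in planted or _count_cpgs(codes) >= 4:
                break
        chrom_codes[chrom][tss - 300 : tss + 300] = codes
        if strands[i] == "+":
            exons = ((tss, tss + 300), (tss + 500, tss + 1100))
        else:
            exons = ((tss - 1099, tss - 499), (tss - 299, tss + 1))
        genes.append(GeneModel(gene_ids[i], chrom, str(strands[i]), exons))

    # gDMR intervals occupy the remaining slots
    gdmrs: list[tuple] = []
    for j in range(config.n_gdmrs_maternal + config.n_gdmrs_paternal):
        chrom, slot_start = slots[config.n_genes + j]
        s = slot_start + (_SLOT - 600) // 2
        chrom_codes[chrom][s : s + 600] = _compose(rng, 600, "gdmr")
        origin = "maternal" if j < config.n_gdmrs_maternal else "paternal"
        gdmrs.append((f"gDMR_{origin}_{j}", GenomeInterval(chrom, s, s + 600),
                      origin))

    maternal = {c: _codes_to_seq(v) for c, v in chrom_codes.items()}

    # SNVs: substitutions only, never touching a CpG dinucleotide and never
    # creating one, so both haplotypes share the same CpG set
    snv_rng = _sub_rng(config.seed, "snvs")
    snvs: list[tuple] = []
    cpg_member: dict[str, np.ndarray] = {}
    for chrom, seq in maternal.items():
        cpgs = enumerate_cpg_sites(seq)
        member = np.zeros(len(seq), dtype=bool)
        member[cpgs] = True
        member[cpgs + 1] = True
        cpg_member[chrom] = member
    forced: list[tuple] = []
    for g in genes:
        win = (max(0, g.tss - 300), g.tss + 300)
        forced.append((g.chrom, win))  # one SNV in every promoter window
        ex = g.exons[1]
        forced.append((g.chrom, (ex[0], ex[1])))  # one exonic SNV per gene
    taken: set = set()
    for chrom, (lo, hi) in forced:
        pos = _pick_snv_pos(snv_rng, chrom_codes[chrom], cpg_member[chrom],
                            lo, hi, taken)
        if pos is not None:
            taken.add((chrom, pos))
    for chrom, codes in chrom_codes.items():
        n_random = snv_rng.poisson(config.snv_rate * len(codes))
        cand = snv_rng.integers(1, len(codes) - 1, size=n_random)
        chrom_taken = {p for (c, p) in taken if c == chrom}
        for pos in np.unique(cand):
            pos = int(pos)
            if {pos - 1, pos, pos + 1} & chrom_taken or cpg_member[chrom][pos]:
                continue
            taken.add((chrom, pos))
            chrom_taken.add(pos)
    for chrom, pos in sorted(taken):
        codes = chrom_codes[chrom]
        alt = _choose_alt(snv_rng, codes, pos)
        if alt is None:
            continue
        snvs.append((chrom, pos, _code_to_base(codes[pos]), _code_to_base(alt)))

    paternal_codes = {c: v.copy() for c, v in chrom_codes.items()}
    base_to_code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for chrom, pos, _ref, alt in snvs:
        paternal_codes[chrom][pos] = base_to_code[alt]
    paternal = {c: _codes_to_seq(v) for c, v in paternal_codes.items()}

    # persistence truth: planted genes cycle retained / intermediate / hypo
    persistence_values = {"retained": 0.30, "intermediate": 0.10, "hypo": 0.02}
    persistence_truth = {
        gid: ("retained", "intermediate", "hypo")[i % 3]
        for i, gid in enumerate(planted)
    }

    windows = {}
    for g in genes:
        windows[g.gene_id] = (g.chrom, max(0, g.tss - 300), g.tss + 300)

    hypo = config.promoter_hypo
    gain = hypo + config.planted_gain
    hyper = config.oocyte_hyper_level
    bg = config.background

    def prof(background_key: str, values: dict, gdmr_values: dict) -> MethProfile:
        feats = []
        for gid, (chrom, s, e) in windows.items():
            if gid in values:
                feats.append((chrom, s, e, values[gid]))
        for name, iv, origin in gdmrs:
            feats.append((iv.chrom, iv.start, iv.end, gdmr_values[origin]))
        return MethProfile(bg[background_key], feats)

    cgi_ids = [gene_ids[i] for i in cgi_idx]
    base_hypo = {gid: hypo for gid in cgi_ids}  # low promoters ride background

    def with_overrides(**over) -> dict:
        d = dict(base_hypo)
        d.update(over)
        return d

    planted_gain_vals = {gid: gain for gid in planted}
    hyper_vals = {gid: hyper for gid in oocyte_hyper}
    icm_pat_vals = {
        gid: persistence_values[persistence_truth[gid]] for gid in planted
    }

    true_meth: dict[tuple, MethProfile] = {}
    sperm = prof("sperm", dict(base_hypo),
                 {"maternal": hypo, "paternal": 0.90})
    true_meth[("sperm_B6", "total")] = sperm
    true_meth[("sperm_DBA", "total")] = sperm
    oocyte = prof("oocyte", with_overrides(**hyper_vals),
                  {"maternal": 0.90, "paternal": hypo})
    true_meth[("GV_oocyte", "total")] = oocyte
    true_meth[("MII_oocyte", "total")] = oocyte
    true_meth[("2C", "maternal")] = prof(
        "2C_maternal",
        with_overrides(**{gid: 0.60 for gid in oocyte_hyper}),
        {"maternal": 0.85, "paternal": hypo},
    )
    true_meth[("2C", "paternal")] = prof(
        "2C_paternal", with_overrides(**planted_gain_vals),
        {"maternal": hypo, "paternal": 0.85},
    )
    true_meth[("ICM", "maternal")] = prof(
        "ICM_maternal",
        with_overrides(**{gid: 0.40 for gid in oocyte_hyper}),
        {"maternal": 0.85, "paternal": hypo},
    )
    true_meth[("ICM", "paternal")] = prof(
        "ICM_paternal", with_overrides(**icm_pat_vals),
        {"maternal": hypo, "paternal": 0.85},
    )
    true_meth[("androgenetic", "total")] = prof(
        "andro", with_overrides(**planted_gain_vals),
        {"maternal": hypo, "paternal": 0.85},
    )
    true_meth[("parthenogenetic", "total")] = prof(
        "partheno", with_overrides(**hyper_vals),
        {"maternal": 0.85, "paternal": hypo},
    )
    true_meth[("matKO_2C", "maternal")] = prof(
        "matKO_maternal", dict(base_hypo),
        {"maternal": 0.05, "paternal": hypo},
    )
    true_meth[("matKO_2C", "paternal")] = prof(
        "matKO_paternal", dict(base_hypo),  # planted gains removed
        {"maternal": hypo, "paternal": 0.85},
    )
    for sid in ("2C", "ICM", "matKO_2C"):
        true_meth[(sid, "total")] = _average_profiles(
            true_meth[(sid, "maternal")], true_meth[(sid, "paternal")]
        )

    # relative per-gene factors; scaled by config.expr_baseline_mean at
    # simulation time so coverage-style experiments can rescale depth
    expr_rng = _sub_rng(config.seed, "expression")
    expr_baseline = {
        gid: float(expr_rng.lognormal(0.0, 0.5)) for gid in gene_ids
    }
    planted_de = [
        (gid, config.de_stage, config.de_allele, config.planted_fold)
        for gid in planted[: config.n_planted_de]
    ]

    truth = TruthSet(
        genome={"maternal_ref": maternal, "paternal_ref": paternal},
        genes=genes,
        promoter_class_truth=dict(zip(gene_ids, (str(c) for c in classes))),
        snvs=snvs,
        true_meth=true_meth,
        planted_pma=planted,
        planted_de=planted_de,
        oocyte_hyper=oocyte_hyper,
        persistence_truth=persistence_truth,
        gdmrs=gdmrs,
        expr_baseline=expr_baseline,
        h3k4me3_enriched=cgi_ids,
        h3k27me3_domain=list(planted),
        config=config,
        seed=config.seed,
    )
    _check_truth_invariants(truth)
    return truth


def _check_truth_invariants(truth: TruthSet) -> None:
    sperm = truth.true_meth[("sperm_DBA", "total")]
    two_c = truth.true_meth[("2C", "paternal")]
    for gid in truth.planted_pma:
        g = truth.gene(gid)
        s = sperm.value(g.chrom, g.tss)
        e = two_c.value(g.chrom, g.tss)
        if not (s < 0.20 and e - s >= 0.30):
            raise AssertionError(
                f"planted gene {gid} violates PMA truth: sperm={s}, 2C={e}"
            )
    for g in truth.genes:
        size = truth.chrom_sizes[g.chrom]
        for s, e in g.exons:
            if not (0 <= s < e <= size):
                raise AssertionError(f"exon of {g.gene_id} outside chromosome")


def _average_profiles(a: MethProfile, b: MethProfile) -> MethProfile:
    """Allele-agnostic profile: per-feature and background means.  Both
    profiles carry the same feature intervals by construction."""
    feats = []
    b_map = {(c, s, e): v for c, s, e, v in b.features}
    for c, s, e, v in a.features:
        feats.append((c, s, e, (v + b_map[(c, s, e)]) / 2.0))
    return MethProfile((a.background + b.background) / 2.0, feats)


def _codes_to_seq(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode("ascii")


def _code_to_base(code: int) -> str:
    return "ACGT"[int(code)]


def _pick_snv_pos(rng, codes, cpg_member, lo, hi, taken):
    order = rng.permutation(np.arange(max(1, lo), min(hi, len(codes) - 1)))
    chrom_taken = {p for (_, p) in taken}
    for pos in order:
        pos = int(pos)
        # adjacency guard: two neighbouring substitutions could jointly
        # create a CpG present on only one haplotype
        if cpg_member[pos] or {pos - 1, pos, pos + 1} & chrom_taken:
            continue
        if _choose_alt(rng, codes, pos) is not None:
            return pos
    return None


def _choose_alt(rng, codes, pos):
    """Alt base differing from ref that neither breaks nor creates a CpG."""
    ref = codes[pos]
    left_c = pos > 0 and codes[pos - 1] == 1
    right_g = pos + 1 < len(codes) and codes[pos + 1] == 2
    options = [b for b in range(4) if b != ref
               and not (left_c and b == 2) and not (right_g and b == 1)]
    if not options:
        return None
    return int(rng.choice(options))


def simulate_methylome(
    truth: TruthSet, sample_id: str, allele: str,
    config: SimulationConfig | None = None,
    min_coverage: int = 1,
) -> SampleMethylome:
    """Draw per-CpG calls: coverage ~ Poisson(coverage_mean), methylated
    reads ~ Binomial(coverage, true fraction) (beta-binomial when
    overdispersion > 0).  Zero-coverage CpGs are omitted."""
    config = config or truth.config
    if (sample_id, allele) not in truth.true_meth:
        raise KeyError(f"unknown sample/allele: {sample_id}/{allele}")
    profile = truth.true_meth[(sample_id, allele)]
    rng = _sub_rng(config.seed, "meth", sample_id, allele)
    frames = []
    for chrom, seq in truth.genome["maternal_ref"].items():
        pos = enumerate_cpg_sites(seq)
        cov = rng.poisson(config.coverage_mean, size=pos.size)
        keep = cov > 0
        pos, cov = pos[keep], cov[keep]
        frac = profile.values(chrom, pos)
        if config.overdispersion > 0:
            rho = config.overdispersion
            conc = (1 - rho) / rho
            frac = np.clip(frac, 1e-9, 1 - 1e-9)
            frac = rng.beta(frac * conc, (1 - frac) * conc)
        meth = rng.binomial(cov, frac)
        frames.append(pd.DataFrame(
            {"chrom": chrom, "pos": pos, "meth": meth, "unmeth": cov - meth}
        ))
    calls = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=["chrom", "pos", "meth", "unmeth"]))
    calls = calls[(calls["meth"] + calls["unmeth"]) >= min_coverage]
    return SampleMethylome(
        sample_id=sample_id, allele=allele, calls=calls.reset_index(drop=True),
        read_length=config.read_length, min_informative_coverage=min_coverage,
    )


# ChIP library design: which windows are enriched, per (mark, sample, allele)
def _chip_enriched_windows(truth: TruthSet, mark: str, sample_id: str,
                           allele: str) -> list[tuple]:
    """(gene_id, window, target kind) for enriched loci of a track."""
    out = []
    if mark == "H3K4me3":
        if sample_id == "sperm":
            enriched = set(truth.h3k4me3_enriched)
        elif sample_id == "2C" and allele == "paternal":
            # planted PMA promoters lose paternal H3K4me3 in 2C embryos
            enriched = set(truth.h3k4me3_enriched) - set(truth.planted_pma)
        else:
            enriched = set(truth.h3k4me3_enriched)
        for gid in sorted(enriched):
            out.append((gid, truth.promoter_window(gid), "promoter"))
    elif mark == "H3K9me3":
        for gid in sorted(truth.planted_pma):
            out.append((gid, truth.promoter_window(gid), "promoter"))
    elif mark == "H3K27me3":
        for gid in sorted(truth.h3k27me3_domain):
            out.append((gid, truth.promoter_window(gid, flank=10_000), "domain"))
    else:
        raise ValueError(f"unknown mark {mark!r}")
    return out


def simulate_chip_track(
    truth: TruthSet, mark: str, sample_id: str, allele: str = "total",
    config: SimulationConfig | None = None,
) -> MarkReadSet:
    """Read intervals + library size such that enriched loci score above
    the configured RPKM target and background stays well below it."""
    config = config or truth.config
    rng = _sub_rng(config.seed, "chip", mark, sample_id, allele)
    lib = config.chip_library_size
    rl = config.read_length
    rows = []
    for chrom, size in truth.chrom_sizes.items():
        lam = config.chip_background_rpkm * lib * size / 1e9
        n_bg = rng.poisson(lam)
        starts = rng.integers(0, max(1, size - rl), size=n_bg)
        for s in starts:
            rows.append((chrom, int(s), int(s) + rl))
    for _gid, win, kind in _chip_enriched_windows(truth, mark, sample_id, allele):
        target = (config.chip_promoter_rpkm if kind == "promoter"
                  else config.chip_domain_rpkm)
        lam = target * lib * len(win) / 1e9
        n = rng.poisson(lam)
        starts = rng.integers(max(0, win.start - rl + 1), win.end, size=n)
        for s in starts:
            rows.append((win.chrom, int(s), int(s) + rl))
    reads = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return MarkReadSet(mark=mark, sample_id=sample_id, allele=allele,
                       reads=reads, library_size=lib)


def simulate_expression_counts(
    truth: TruthSet, stage: str, genotype: str,
    config: SimulationConfig | None = None,
) -> list[ExpressionRecord]:
    """Allele-resolved NB replicate counts for every gene at one stage.

    Planted upregulation multiplies the (stage, allele) mean in matKO
    only; the other allele and all WT conditions keep gene baselines."""
    config = config or truth.config
    if genotype not in ("WT", "matKO"):
        raise ValueError(f"genotype must be WT or matKO, got {genotype!r}")
    if stage not in ("2C", "4C", "ICM"):
        raise ValueError(f"unsupported stage {stage!r}")
    rng = _sub_rng(config.seed, "expr", stage, genotype)
    planted = {
        (gid, st, al): fold for gid, st, al, fold in truth.planted_de
    }
    records: list[ExpressionRecord] = []
    libs = [config.expr_library_size] * config.expr_replicates
    for g in truth.genes:
        base = config.expr_baseline_mean * truth.expr_baseline[g.gene_id]
        allele_counts = {}
        for allele in ("maternal", "paternal"):
            mean = base
            if genotype == "matKO":
                mean *= planted.get((g.gene_id, stage, allele), 1.0)
            disp = config.expr_dispersion
            if disp > 0 and mean > 0:
                lam = rng.gamma(1.0 / disp, mean * disp,
                                size=config.expr_replicates)
            else:
                lam = np.full(config.expr_replicates, mean)
            counts = rng.poisson(lam)
            allele_counts[allele] = counts
            records.append(ExpressionRecord(
                gene_id=g.gene_id, stage=stage, genotype=genotype,
                allele=allele, replicate_counts=[int(c) for c in counts],
                library_sizes=list(libs), exon_length_bp=g.exon_length,
            ))
        total = allele_counts["maternal"] + allele_counts["paternal"]
        records.append(ExpressionRecord(
            gene_id=g.gene_id, stage=stage, genotype=genotype, allele="total",
            replicate_counts=[int(c) for c in total],
            library_sizes=list(libs), exon_length_bp=g.exon_length,
        ))
    return records


# ---------------------------------------------------------------------------
# file emission (standard formats; truth only in truth.json)

SAMPLE_ALLELES = [
    ("sperm_B6", "total"), ("sperm_DBA", "total"),
    ("GV_oocyte", "total"), ("MII_oocyte", "total"),
    ("2C", "maternal"), ("2C", "paternal"), ("2C", "total"),
    ("ICM", "maternal"), ("ICM", "paternal"), ("ICM", "total"),
    ("androgenetic", "total"), ("parthenogenetic", "total"),
    ("matKO_2C", "maternal"), ("matKO_2C", "paternal"), ("matKO_2C", "total"),
]

CHIP_TRACKS = [
    ("H3K4me3", "sperm", "total"),
    ("H3K4me3", "2C", "paternal"),
    ("H3K9me3", "zygote", "paternal"),
    ("H3K27me3", "2C", "total"),
]


def write_fasta(path, sequences: dict, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_dataset(truth: TruthSet, outdir, config: SimulationConfig | None = None):
    """Emit the dataset in standard formats plus the truth manifest."""
    from pathlib import Path

    config = config or truth.config
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for hap in ("maternal", "paternal"):
        write_fasta(out / f"genome.{hap}.fa", truth.genome[f"{hap}_ref"])
    genes_rows = [
        {"gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
         "tss": g.tss,
         "exons": ";".join(f"{s}-{e}" for s, e in g.exons)}
        for g in truth.genes
    ]
    pd.DataFrame(genes_rows).to_csv(out / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(truth.snvs, columns=["chrom", "pos", "ref", "alt"]).to_csv(
        out / "snvs.tsv", sep="\t", index=False
    )
    with open(out / "gdmrs.bed", "w") as fh:
        for name, iv, origin in truth.gdmrs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{origin}\n")
    for sid, allele in SAMPLE_ALLELES:
        m = simulate_methylome(truth, sid, allele, config)
        df = m.calls.copy()
        total = df["meth"] + df["unmeth"]
        cov = pd.DataFrame({
            "chrom": df["chrom"], "start": df["pos"] + 1, "end": df["pos"] + 1,
            "pct": (100.0 * df["meth"] / total).round(6),
            "meth": df["meth"], "unmeth": df["unmeth"],
        })
        cov.to_csv(out / f"{sid}.{allele}.cov.tsv", sep="\t", index=False,
                   header=False)
    lib_rows = []
    for mark, sid, allele in CHIP_TRACKS:
        track = simulate_chip_track(truth, mark, sid, allele, config)
        bed = out / f"{mark}.{sid}.{allele}.reads.bed"
        track.reads.to_csv(bed, sep="\t", index=False, header=False)
        lib_rows.append({"mark": mark, "sample": sid, "allele": allele,
                         "library_size": track.library_size})
    pd.DataFrame(lib_rows).to_csv(out / "libsize.tsv", sep="\t", index=False)
    for stage in ("4C", "ICM"):
        for genotype in ("WT", "matKO"):
            recs = simulate_expression_counts(truth, stage, genotype, config)
            rows = [
                {"gene_id": r.gene_id, "allele": r.allele,
                 **{f"count_rep{i + 1}": c
                    for i, c in enumerate(r.replicate_counts)},
                 **{f"lib_rep{i + 1}": l
                    for i, l in enumerate(r.library_sizes)},
                 "exon_length_bp": r.exon_length_bp}
                for r in recs
            ]
            pd.DataFrame(rows).to_csv(
                out / f"counts.{stage}.{genotype}.tsv", sep="\t", index=False
            )
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_manifest(), fh, indent=1, sort_keys=True)
    return out
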