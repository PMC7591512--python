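import dataclasses

import pytest

from pmakit.synthetic_data import (
    SimulationConfig,
    generate_truth,
    simulate_methylome,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_truth(default_config):
    """Full-size study-condition fixture (200 genes, 20 planted PMA,
    15x coverage, seed 42)."""
    return generate_truth(default_config)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_chroms=2, chrom_length=90_000, n_genes=60, n_planted_pma=6,
        n_planted_de=3, seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config)


@pytest.fixture(scope="session")
def default_methylomes(default_truth):
    """The methylomes the promoter funnel needs, at study coverage."""
    t = default_truth
    return {
        "sperm_B6": simulate_methylome(t, "sperm_B6", "total", min_coverage=5),
        "sperm_DBA": simulate_methylome(t, "sperm_DBA", "total", min_coverage=5),
        "2C_paternal": simulate_methylome(t, "2C", "paternal", min_coverage=1),
        "ICM_paternal": simulate_methylome(t, "ICM", "paternal", min_coverage=1),
    }


def run_promoter_funnel(truth, config=None, embryo_sample=("2C", "paternal"),
                        coverage_mean=None):
    """Shared helper: full promoter funnel on a truth set; returns
    (promoter records, called PMA gene ids)."""
    from pmakit import chromatin_association as ca
    from pmakit import promoter_pipeline as pp
    from pmakit.genome_annotation import classify_promoter
    from pmakit.synthetic_data import simulate_chip_track

    config = config or truth.config
    if coverage_mean is not None:
        config = dataclasses.replace(config, coverage_mean=coverage_mean)
    genome = truth.genome["maternal_ref"]
    promoters = [classify_promoter(g, genome) for g in truth.genes]
    k4 = simulate_chip_track(truth, "H3K4me3", "sperm", "total", config)
    for p in promoters:
        p.h3k4me3_rpkm = ca.score_mark(k4, p.window)
    sperm_b6 = simulate_methylome(truth, "sperm_B6", "total", config,
                                  min_coverage=5)
    sperm_dba = simulate_methylome(truth, "sperm_DBA", "total", config,
                                   min_coverage=5)
    embryo = simulate_methylome(truth, embryo_sample[0], embryo_sample[1],
                                config, min_coverage=1)
    labels = pp.strain_consistency_filter(sperm_b6, sperm_dba, promoters)
    low = [p for p in promoters if labels[p.gene_id] == "consistent-low"]
    cgi = pp.cgi_h3k4_filter(low)
    variants = [(c, p) for c, p, _, _ in truth.snvs]
    assessable = pp.allele_coverage_filter(cgi, variants, sperm_dba, embryo)
    pp.call_promoter_pma(assessable, sperm_dba, embryo)
    called = {p.gene_id for p in assessable if "pma" in p.filter_labels}
    return promoters, called
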