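import pytest

import ppsv


@pytest.fixture(scope="session")
def full_cohort():
    """Synthetic cohort at the study's sample sizes (113 AFR / 57 EUR)."""
    return ppsv.generate_cohort(ppsv.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def full_cohort_result(full_cohort):
    c = full_cohort
    return ppsv.prioritize(
        c.sites, c.genes, c.known_table, c.score_panels, c.gene_sets,
        c.roles, enhancers=c.enhancers,
    )


@pytest.fixture(scope="session")
def toy_genes():
    """Two genes on a 50 kb toy chromosome, with UTR-bearing exons."""
    g1 = ppsv.GeneModel(
        gene_id="gA", gene_name="GA", canonical_transcript="gA.t1",
        chrom="chr1", strand="+", tx_start=10_000, tx_end=19_999,
        exons=[(10_000, 10_499), (12_000, 12_499), (14_000, 14_499),
               (16_000, 16_499), (18_000, 18_499)],
        cds_start=10_250, cds_end=18_250, canonical=True,
    )
    g2 = ppsv.GeneModel(
        gene_id="gB", gene_name="GB", canonical_transcript="gB.t1",
        chrom="chr1", strand="-", tx_start=30_000, tx_end=39_999,
        exons=[(30_000, 30_499), (33_000, 33_499), (36_000, 36_499),
               (39_500, 39_999)],
        cds_start=30_250, cds_end=39_750, canonical=True,
    )
    return [g1, g2]
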