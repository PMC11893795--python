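"""Genotype QC cascade and allele-frequency estimation."""

import copy
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ppsv
from ppsv.genotypes import (
    CohortSite,
    Genotype,
    RARITY_COMMON,
    RARITY_LOW,
    RARITY_RARE,
    rarity_class,
)
from ppsv.model import SVRecord, SVType


def make_site(
    gts,
    svtype=SVType.DEL,
    fts=None,
    gqs=None,
    ancestries=None,
    pass_ratio=None,
    site_filter="PASS",
    chrom="chr1",
):
    n = len(gts)
    samples = [f"s{i}" for i in range(n)]
    fts = fts or ["PASS" if svtype not in (SVType.INV, SVType.TRA) else None] * n
    gqs = gqs or [60] * n
    ancestries = ancestries or ["AFR"] * n
    chrom2 = chrom if svtype is not SVType.TRA else "chr9"
    sv = SVRecord("site", chrom, 1000, chrom2, 2000, svtype)
    return CohortSite(
        sv=sv,
        samples=samples,
        genotypes=[Genotype(gt, ft, gq) for gt, ft, gq in zip(gts, fts, gqs)],
        ancestry=dict(zip(samples, ancestries)),
        pass_ratio=pass_ratio,
        site_filter=site_filter,
    )


class TestSiteFilter:
    def test_all_pass_site_retained(self):
        site = make_site(["0/1"] * 170)
        assert ppsv.site_filter([site]) == [site]

    @pytest.mark.parametrize("ratio,kept", [(0.49, 0), (0.50, 1)])
    def test_pass_ratio_boundary_inclusive(self, ratio, kept):
        site = make_site(["0/1"] * 10, pass_ratio=ratio)
        assert len(ppsv.site_filter([site])) == kept

    def test_site_level_filter_failure_removes(self):
        site = make_site(["0/1"] * 10, pass_ratio=1.0, site_filter="lowconf")
        assert ppsv.site_filter([site]) == []

    def test_recomputes_ratio_from_ft_when_absent(self):
        fts = ["PASS"] * 4 + ["fail"] * 6
        site = make_site(["0/1"] * 10, fts=fts)
        assert ppsv.site_filter([site]) == []
        assert site.pass_ratio == pytest.approx(0.4)


class TestGenotypeMasking:
    def test_failing_ft_becomes_missing(self):
        site = make_site(["0/1", "0/0"], fts=["other", "PASS"])
        ppsv.mask_genotypes(site)
        assert site.genotypes[0].gt is None
        assert site.genotypes[1].gt == "0/0"

    @pytest.mark.parametrize("gq,expect_missing", [(19, True), (20, False)])
    def test_breakend_sites_masked_by_gq_boundary(self, gq, expect_missing):
        site = make_site(["0/1"], svtype=SVType.TRA, gqs=[gq])
        ppsv.mask_genotypes(site)
        assert (site.genotypes[0].gt is None) is expect_missing

    def test_all_pass_site_unchanged(self):
        site = make_site(["0/1", "1/1", "0/0"])
        before = [g.gt for g in site.genotypes]
        ppsv.mask_genotypes(site)
        assert [g.gt for g in site.genotypes] == before


class TestMissingnessFilter:
    def _mixed(self, miss_afr, miss_eur, n_afr=20, n_eur=20):
        gts = [None] * miss_afr + ["0/0"] * (n_afr - miss_afr)
        gts += [None] * miss_eur + ["0/0"] * (n_eur - miss_eur)
        anc = ["AFR"] * n_afr + ["EUR"] * n_eur
        return make_site(gts, ancestries=anc)

    def test_either_group_over_threshold_removes(self):
        site = self._mixed(miss_afr=0, miss_eur=5)  # 25% EUR missing
        assert ppsv.missingness_filter([site]) == []

    def test_exactly_twenty_percent_retained(self):
        site = self._mixed(miss_afr=4, miss_eur=4)  # 20% in both
        assert len(ppsv.missingness_filter([site])) == 1

    def test_no_missingness_retained(self):
        site = self._mixed(0, 0)
        assert len(ppsv.missingness_filter([site])) == 1

    def test_missing_ancestry_labels_fatal(self):
        site = make_site(["0/0"] * 4)
        site.ancestry = {}
        with pytest.raises(ValueError):
            ppsv.missingness_filter([site])


class TestFrequencies:
    def test_two_carriers_among_113_africans(self):
        gts = ["0/1"] * 2 + ["0/0"] * 111
        rec = ppsv.compute_frequencies(make_site(gts))
        assert rec.maf_afr == pytest.approx(2 / 226)
        assert round(rec.maf_afr, 3) == 0.009
        assert rec.carriers_afr == 2 and rec.n_alleles_afr == 226

    def test_single_carrier_among_113_africans(self):
        gts = ["0/1"] + ["0/0"] * 112
        rec = ppsv.compute_frequencies(make_site(gts))
        assert round(rec.maf_afr, 3) == 0.004

    def test_fixed_alt_site_flagged_for_removal(self):
        rec = ppsv.compute_frequencies(make_site(["1/1"] * 10))
        assert rec.af_overall == 1.0 and rec.remove_af1

    def test_all_missing_is_undefined(self):
        rec = ppsv.compute_frequencies(make_site([None] * 10))
        assert rec.undefined and rec.af_overall is None

    def test_denominator_excludes_missing_alleles(self):
        gts = ["0/1", None, "0/0", "0/0"]
        rec = ppsv.compute_frequencies(make_site(gts))
        assert rec.n_alleles_afr == 6
        assert rec.af_afr == pytest.approx(1 / 6)

    def test_haploid_chromosomes_count_one_allele_per_sample(self):
        gts = ["1"] + ["0"] * 9
        rec = ppsv.compute_frequencies(make_site(gts, chrom="chrX"))
        assert rec.n_alleles_afr == 10
        assert rec.af_afr == pytest.approx(0.1)

    def test_af_recovery_within_binomial_error(self):
        """Estimated AF covers the planted truth at ~95% over replicates."""
        rng = np.random.default_rng(42)
        af, n = 0.05, 113
        half_width = 1.96 * np.sqrt(af * (1 - af) / (2 * n))
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            alt = rng.binomial(2, af, size=n)
            gts = [("0/0", "0/1", "1/1")[a] for a in alt]
            rec = ppsv.compute_frequencies(make_site(gts))
            hits += abs(rec.af_afr - af) <= half_width
        assert 0.90 <= hits / n_rep <= 0.995


class TestRarityClasses:
    @pytest.mark.parametrize(
        "maf,expected",
        [(0.0, RARITY_RARE), (0.01, RARITY_RARE), (0.0100001, RARITY_LOW),
         (0.05, RARITY_LOW), (0.0500001, RARITY_COMMON), (0.5, RARITY_COMMON)],
    )
    def test_boundaries(self, maf, expected):
        assert rarity_class(maf) == expected

    def test_exclusive_rare_boundary_option(self):
        assert rarity_class(0.01, rare_boundary_exclusive=True) == RARITY_LOW

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.0, max_value=0.5, allow_nan=False))
    def test_classes_partition_the_maf_range(self, maf):
        assert rarity_class(maf) in (RARITY_RARE, RARITY_LOW, RARITY_COMMON)


class TestCascadeIdempotence:
    def test_applying_cascade_twice_equals_once(self, full_cohort):
        sites = copy.deepcopy(full_cohort.sites[:80])

        def cascade(ss):
            ss = ppsv.site_filter(ss)
            for s in ss:
                ppsv.mask_genotypes(s)
            return ppsv.missingness_filter(ss)

        once = cascade(sites)
        snapshot = [
            (s.sv.id, [g.gt for g in s.genotypes]) for s in once
        ]
        twice = cascade(once)
        assert [
            (s.sv.id, [g.gt for g in s.genotypes]) for s in twice
        ] == snapshot


class TestRankSum:
    def test_identical_distributions_give_p_near_one(self):
        counts = [9000, 9100, 9200, 9300, 8950] * 4
        res = ppsv.per_genome_sv_count_test(counts, counts)
        assert res.p_value > 0.9
        assert res.median_a == res.median_b

    def test_fully_separated_groups_at_cohort_sizes(self):
        res = ppsv.per_genome_sv_count_test([9000] * 113, [7500] * 57)
        assert res.median_a - res.median_b == 1500
        assert res.p_value < 1e-6

    def test_agrees_with_exact_permutation_oracle_at_small_n(self):
        rng = np.random.default_rng(5)
        a = list(rng.integers(50, 100, size=5))
        b = list(rng.integers(60, 110, size=4))
        res = ppsv.per_genome_sv_count_test(a, b)

        # exact permutation distribution of the rank-sum statistic,
        # with mid-ranks for ties
        pooled = a + b
        vals = sorted(pooled)
        rank_of = {}
        i = 0
        while i < len(vals):
            j = i
            while j < len(vals) and vals[j] == vals[i]:
                j += 1
            mid = (i + j + 1) / 2
            rank_of[vals[i]] = mid
            i = j
        def u_stat(group):
            r = sum(rank_of[v] for v in group)
            return r - len(group) * (len(group) + 1) / 2
        observed = u_stat(a)
        n_a = len(a)
        count = total = 0
        mean_u = n_a * len(b) / 2
        for combo in itertools.combinations(range(len(pooled)), n_a):
            u = u_stat([pooled[i] for i in combo])
            total += 1
            if abs(u - mean_u) >= abs(observed - mean_u) - 1e-9:
                count += 1
        p_exact = count / total
        assert res.p_value == pytest.approx(p_exact, abs=0.08)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ppsv.per_genome_sv_count_test([1], [2, 3])
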