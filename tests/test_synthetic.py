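"""Synthetic cohort generator: determinism, planted truth, noise knobs."""

import hashlib
import os

import numpy as np
import pytest

import ppsv
from ppsv.simulate import CallerNoise, PlantedSV, SimulationConfig, default_planted
from ppsv.model import SVType


def small_config(seed=3, **kw):
    planted = [
        p for p in default_planted() if p.carriers_afr <= 2 and p.carriers_eur <= 1
    ][:6]
    defaults = dict(seed=seed, n_afr=12, n_eur=6, n_background_svs=40,
                    planted=planted)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def _bundle_digest(root):
    h = hashlib.sha256()
    for dirpath, dirnames, filenames in sorted(os.walk(root)):
        dirnames.sort()
        for name in sorted(filenames):
            path = os.path.join(dirpath, name)
            h.update(os.path.relpath(path, root).encode())
            with open(path, "rb") as fh:
                h.update(fh.read())
    return h.hexdigest()


class TestDeterminism:
    def test_same_seed_gives_byte_identical_bundles(self, tmp_path):
        cfg = small_config(seed=5)
        d1, d2 = str(tmp_path / "b1"), str(tmp_path / "b2")
        samples = [f"AFR{i:04d}" for i in range(2)]
        ppsv.generate_cohort(cfg, out_dir=d1, caller_vcf_samples=samples)
        ppsv.generate_cohort(small_config(seed=5), out_dir=d2,
                             caller_vcf_samples=samples)
        assert _bundle_digest(d1) == _bundle_digest(d2)

    def test_different_seed_differs(self):
        a = ppsv.generate_cohort(small_config(seed=1))
        b = ppsv.generate_cohort(small_config(seed=2))
        ga = [g.gt for g in a.sites[0].genotypes]
        gb = [g.gt for g in b.sites[0].genotypes]
        assert a.truth.by_id().keys() == b.truth.by_id().keys()
        assert ga != gb or a.caller_calls != b.caller_calls


class TestPlantedTruth:
    def test_exact_carrier_counts_in_genotyped_sites(self, full_cohort):
        truth = full_cohort.truth.by_id()
        by_id = {s.sv.id: s for s in full_cohort.sites}
        plan = {p.sv_id: p for p in full_cohort.config.planted}
        for sv_id, t in truth.items():
            site = by_id[sv_id]
            het = [
                s for s, g in zip(site.samples, site.genotypes) if g.gt == "0/1"
            ]
            assert sorted(het) == sorted(t.carriers)
            p = plan[sv_id]
            n_afr = sum(1 for s in t.carriers if s.startswith("AFR"))
            n_eur = sum(1 for s in t.carriers if s.startswith("EUR"))
            assert (n_afr, n_eur) == (p.carriers_afr, p.carriers_eur)

    def test_planted_maf_reaches_study_value(self, full_cohort):
        t = full_cohort.truth.by_id()["sv_P_DEL_TSG"]
        assert t.true_maf_afr == pytest.approx(2 / 226)
        assert round(t.true_maf_afr, 3) == 0.009

    def test_infeasible_config_rejected(self):
        planted = [PlantedSV("X", SVType.DEL, "pLoF", carriers_afr=50)]
        with pytest.raises(ValueError):
            SimulationConfig(n_afr=10, n_eur=5, planted=planted)

    def test_clinvar_control_counts(self, full_cohort):
        sigs = [e.clinical_significance for e in full_cohort.known_table]
        assert sigs.count("pathogenic") + sigs.count("likely_pathogenic") == 3
        assert sigs.count("benign") == 10


class TestCallerNoise:
    def test_noiseless_callers_recover_every_carried_sv(self):
        cfg = small_config(
            seed=9,
            caller_noise=CallerNoise(jitter_sd=0, drop_rate_a=0, drop_rate_b=0,
                                     nonpass_rate=0, fp_per_sample=0),
        )
        cohort = ppsv.generate_cohort(cfg)
        for sample in cohort.samples:
            carried = {
                site.sv.id
                for site in cohort.sites
                for s, g in zip(site.samples, site.genotypes)
                if s == sample and g.gt is not None and "1" in g.gt
            }
            calls_a, _ = cohort.caller_calls[sample]
            simple_a, orphans = ppsv.resolve_breakends(calls_a)
            simple_b, _ = ppsv.resolve_breakends(cohort.caller_calls[sample][1])
            assert not orphans
            res = ppsv.match_calls(simple_a, simple_b)
            assert len(res.concordant) == len(carried)
            recovered = {
                (r.chrom1, r.pos1, r.chrom2, r.pos2, r.svtype)
                for r in res.concordant
            }
            truth_coords = {
                (site.sv.chrom1, site.sv.pos1, site.sv.chrom2, site.sv.pos2,
                 site.sv.svtype)
                for site in cohort.sites if site.sv.id in carried
            }
            assert recovered == truth_coords

    def test_jitter_beyond_tolerance_loses_concordance(self):
        cfg = small_config(
            seed=9,
            caller_noise=CallerNoise(jitter_sd=300, drop_rate_a=0, drop_rate_b=0,
                                     nonpass_rate=0, fp_per_sample=0),
        )
        cohort = ppsv.generate_cohort(cfg)
        total = matched = 0
        for sample in cohort.samples:
            calls_a, calls_b = cohort.caller_calls[sample]
            sa, _ = ppsv.resolve_breakends(calls_a)
            sb, _ = ppsv.resolve_breakends(calls_b)
            res = ppsv.match_calls(sa, sb)
            matched += len(res.concordant)
            total += max(len(sa), len(sb))
        assert total > 0
        assert matched < total  # concordance sensitivity drops below 1


class TestTruthCompare:
    def test_noiseless_pipeline_is_perfect(self, full_cohort, full_cohort_result):
        metrics = ppsv.truth_compare(
            full_cohort_result.final_classes(), full_cohort.truth
        )
        assert metrics["final"]["sensitivity"] == 1.0
        assert metrics["final"]["specificity"] == 1.0

    def test_benign_decoys_never_reach_final(self, full_cohort, full_cohort_result):
        final = full_cohort_result.final_pp()
        for t in full_cohort.truth.planted:
            if t.expected_final not in ("PP_SV", "cautionary"):
                assert t.sv_id not in final

    def test_empty_truth_is_error(self, full_cohort_result):
        empty = ppsv.GroundTruth(planted=[], background_ids=[])
        with pytest.raises(ValueError):
            ppsv.truth_compare(full_cohort_result.final_classes(), empty)


class TestVAFCalibration:
    def test_depth_vaf_unbiased_over_carriers(self, full_cohort):
        cohort = full_cohort
        estimates = {"DEL": [], "DUP": [], "BP": []}
        truth = cohort.truth.by_id()
        site_by_id = {s.sv.id: s for s in cohort.sites}
        for (sv_id, sample), tracks in cohort.depth_tracks.items():
            sv = site_by_id[sv_id].sv
            if sv.svtype in (SVType.DEL, SVType.DUP):
                est = ppsv.vaf_depth(sv, tracks[0])
                estimates[sv.svtype.value].append(est.vaf - truth[sv_id].true_vaf)
            else:
                est = ppsv.vaf_breakpoint(
                    sv, cohort.evidence[(sv_id, sample)], tracks
                )
                estimates["BP"].append(est.vaf - truth[sv_id].true_vaf)
        for key, errs in estimates.items():
            assert errs, f"no {key} carriers with depth data"
            assert abs(np.mean(errs)) < 0.08

    def test_planted_loh_states_recovered(self, full_cohort):
        cohort = full_cohort
        genes = {g.gene_id: g for g in cohort.genes}
        for t in cohort.truth.planted:
            if t.expected_final not in ("PP_SV", "cautionary") or not t.carriers:
                continue
            patient = t.carriers[0]
            gene = genes[t.gene_id]
            call = ppsv.classify_loh(
                gene.gene_id, (gene.chrom, gene.tx_start, gene.tx_end),
                cohort.cn_segments.get(patient, []),
            )
            assert call.status == t.loh
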