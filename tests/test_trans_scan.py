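"""Trio scan: pLoF pair discovery, transmission phasing, candidate
filtering and cohort summaries."""

import numpy as np
import pytest
from scipy.stats import poisson

from regent.core import GenomeInterval, ThresholdConfig, TranscriptModel
from regent.core import VariantRecord
from regent.regions import derive_gene_regions, RegionClass
from regent.simulate import (SimConfig, TrioSim, make_toy_reference,
                             make_trio_cohort, write_trio_vcf)
from regent.trans_scan import (AnnotationKeys, SamplePlofPair, SiteGenotypes,
                               TrioRecord, filtering_allele_frequency,
                               find_plof_pairs, load_trio_vcf,
                               mendelian_error_rate, phase_by_transmission,
                               run_trio_scan, scan_in_trans_noncoding,
                               summarize_scan, transmitting_parent)

TRIO = TrioRecord("P", "F", "M")


def site(pos, info=None, pro=(0, 1), fa=(0, 0), mo=(0, 0), ad_pro=(15, 15)):
    v = VariantRecord("chr1", pos, "A", "T", info=dict(info or {}))
    gt = {"P": pro, "F": fa, "M": mo}
    ad = {"P": ad_pro,
          "F": (15, 15) if any(fa or ()) else (30, 0),
          "M": (15, 15) if any(mo or ()) else (30, 0)}
    return SiteGenotypes(v, gt, ad)


PLOF_INFO = {"GENE": "G1", "LOF": "HC", "AF": 0.001}


class TestFindPlofPairs:
    def test_qualifying_plof_kept(self):
        pairs = find_plof_pairs([site(100, PLOF_INFO, fa=(0, 1))], TRIO, {"G1"})
        assert len(pairs) == 1
        assert pairs[0].gene_id == "G1" and pairs[0].plof_parent == "father"

    def test_bad_allele_balance_excluded(self):
        s = site(100, PLOF_INFO, fa=(0, 1), ad_pro=(6, 24))  # balance 0.80
        assert find_plof_pairs([s], TRIO, {"G1"}) == []

    def test_two_plofs_same_gene_excluded(self):
        sites = [site(100, PLOF_INFO, fa=(0, 1)),
                 site(200, PLOF_INFO, mo=(0, 1))]
        assert find_plof_pairs(sites, TRIO, {"G1"}) == []

    def test_af_above_cutoff_excluded(self):
        info = dict(PLOF_INFO, AF=0.02)
        assert find_plof_pairs([site(100, info, fa=(0, 1))], TRIO, {"G1"}) == []

    def test_low_confidence_lof_excluded(self):
        info = dict(PLOF_INFO, LOF="LC")
        assert find_plof_pairs([site(100, info, fa=(0, 1))], TRIO, {"G1"}) == []

    def test_af_or_mode_passes_on_any_source(self):
        keys = AnnotationKeys(af=("AF_A", "AF_B"))
        info = {"GENE": "G1", "LOF": "HC", "AF_A": 0.01, "AF_B": 0.001}
        sites = [site(100, info, fa=(0, 1))]
        assert find_plof_pairs(sites, TRIO, {"G1"}, keys=keys) == []
        assert len(find_plof_pairs(sites, TRIO, {"G1"}, keys=keys,
                                   af_mode="or")) == 1


class TestPhasing:
    """Enumeration of trio genotype configurations."""

    def test_opposite_parents_in_trans(self):
        s1 = site(100, fa=(0, 1))
        s2 = site(200, mo=(0, 1))
        assert phase_by_transmission(s1, s2, TRIO) == "in_trans"

    def test_same_parent_in_cis(self):
        s1 = site(100, fa=(0, 1))
        s2 = site(200, fa=(0, 1))
        assert phase_by_transmission(s1, s2, TRIO) == "in_cis"

    def test_apparent_de_novo_unknown(self):
        s1 = site(100, fa=(0, 1))
        s2 = site(200)  # absent in both parents
        assert phase_by_transmission(s1, s2, TRIO) == "unknown"

    def test_both_parents_carriers_ambiguous(self):
        s = site(100, fa=(0, 1), mo=(0, 1))
        assert transmitting_parent(s, TRIO) is None

    def test_non_diploid_excluded(self):
        s = site(100, pro=(1,), fa=(0, 1))
        assert transmitting_parent(s, TRIO) is None

    def test_missing_genotype_unknown(self):
        s1 = site(100, fa=(0, 1))
        s2 = site(200, mo=(0, 1))
        s2.gt["F"] = None
        assert phase_by_transmission(s1, s2, TRIO) == "unknown"

    def test_mendelian_error_rate(self):
        consistent = site(100, fa=(0, 1))
        violating = site(200, pro=(1, 1))  # hom alt, parents hom ref
        assert mendelian_error_rate([consistent], TRIO) == 0.0
        assert mendelian_error_rate([consistent, violating], TRIO) == 0.5


class TestFilteringAlleleFrequency:
    def test_matches_poisson_confidence_bound(self):
        # lower bound of the one-sided 95% CI: P(X >= AC | AN*faf) == 0.05
        for ac, an in [(5, 10000), (2, 5000), (20, 100000)]:
            faf = filtering_allele_frequency(ac, an, None)
            assert poisson.sf(ac - 1, faf * an) == pytest.approx(0.05, rel=1e-6)

    def test_zero_count_is_zero(self):
        assert filtering_allele_frequency(0, 10000, 0.5) == 0.0

    def test_fallback_to_point_af(self):
        assert filtering_allele_frequency(None, None, 0.003) == 0.003

    def test_faf_below_point_af(self):
        assert filtering_allele_frequency(5, 10000, None) < 5 / 10000


class TestScanCandidates:
    @pytest.fixture()
    def gene_setup(self):
        t = TranscriptModel(
            "T1", "G1", "G1", "chr1", "+",
            [GenomeInterval("chr1", 1000, 1200),
             GenomeInterval("chr1", 2000, 2300)],
            cds_start=1100, cds_end=2200)
        rs = derive_gene_regions(t, "core200")
        pair = SamplePlofPair("P", "G1",
                              VariantRecord("chr1", 1150, "A", "T"), "father")
        return rs, pair

    def _cand(self, pos, score=None, af=0.001, nhom=0, mo=(0, 1), fa=(0, 0)):
        info = {"GENE": "G1", "AF": af, "NHOMALT": nhom}
        if score is not None:
            info["SPLICEAI"] = score
        return site(pos, info, fa=fa, mo=mo)

    def test_splice_filter_scope_is_intronic_only(self, gene_setup):
        rs, pair = gene_setup
        sites = [self._cand(1500, score=0.35),   # intron, passes
                 self._cand(1600, score=0.05),   # intron, dropped by filter
                 self._cand(900, score=None)]    # promoter, no score, kept
        out = scan_in_trans_noncoding(pair, sites, TRIO, rs,
                                      apply_splice_filter=True)
        got = {(c.variant.pos, c.region_class) for c in out.candidates}
        assert got == {(1500, RegionClass.intron),
                       (900, RegionClass.promoter)}

    def test_filter_monotonicity(self, gene_setup):
        rs, pair = gene_setup
        sites = [self._cand(1500, score=0.35), self._cand(1600, score=0.05)]
        off = scan_in_trans_noncoding(pair, sites, TRIO, rs,
                                      apply_splice_filter=False)
        n_off = len(off.candidates)
        on = scan_in_trans_noncoding(pair, sites, TRIO, rs,
                                     apply_splice_filter=True)
        assert n_off >= len(on.candidates)

    def test_same_parent_variant_not_a_candidate(self, gene_setup):
        rs, pair = gene_setup
        sites = [self._cand(1500, score=0.9, mo=(0, 0), fa=(0, 1))]
        out = scan_in_trans_noncoding(pair, sites, TRIO, rs)
        assert out.candidates == []

    def test_homozygote_count_blocks(self, gene_setup):
        rs, pair = gene_setup
        out = scan_in_trans_noncoding(pair, [self._cand(1500, nhom=3)],
                                      TRIO, rs)
        assert out.candidates == []

    def test_af_blocks(self, gene_setup):
        rs, pair = gene_setup
        out = scan_in_trans_noncoding(pair, [self._cand(1500, af=0.02)],
                                      TRIO, rs)
        assert out.candidates == []

    def test_coding_variant_never_a_candidate(self, gene_setup):
        rs, pair = gene_setup
        out = scan_in_trans_noncoding(pair, [self._cand(1150)], TRIO, rs)
        assert out.candidates == []


class TestSummaries:
    def test_empty_cohort_all_zero(self):
        s = summarize_scan([])
        assert (s.n_pairs, s.fraction_with_candidate,
                s.mean_candidates_per_pair, s.max_per_pair) == (0, 0.0, 0.0, 0)

    def test_planted_counts_arithmetic(self):
        from regent.trans_scan import InTransCandidate

        def pair_with(n):
            p = SamplePlofPair("P", "G", VariantRecord("chr1", 1, "A", "T"),
                               "father")
            p.candidates = [InTransCandidate(
                VariantRecord("chr1", 10 + i, "A", "T"),
                RegionClass.intron, "mother", 0.0, 0, 0.5)
                for i in range(n)]
            return p

        s = summarize_scan([pair_with(0), pair_with(1), pair_with(3)])
        assert s.mean_candidates_per_pair == pytest.approx(4 / 3)
        assert s.fraction_with_candidate == pytest.approx(2 / 3)
        assert s.max_per_pair == 3
        assert sum(s.per_region.values()) == 4


class TestCohortRecovery:
    def test_truth_table_recovery_and_no_cis_leak(self):
        cfg = SimConfig(seed=17, n_trios=40)
        ref = make_toy_reference(cfg)
        sims, truth = make_trio_cohort(cfg, ref)
        rsets = ref.region_sets("core200")
        genes = {t.gene_id for t in ref.transcripts}
        pairs = []
        for sim in sims:
            pairs += run_trio_scan(sim.sites, sim.trio, genes, rsets)
        recovered = {(p.proband_id, c.variant.pos)
                     for p in pairs for c in p.candidates}
        planted = {(r.trio, r.pos) for r in truth.itertuples()
                   if r.kind == "in_trans" and r.passes_af}
        cis = {(r.trio, r.pos) for r in truth.itertuples()
               if r.kind == "in_cis"}
        assert recovered == planted
        assert recovered & cis == set()

    def test_vcf_round_trip(self, tmp_path):
        cfg = SimConfig(seed=23, n_trios=3)
        ref = make_toy_reference(cfg)
        sims, _ = make_trio_cohort(cfg, ref)
        sim = sims[0]
        path = tmp_path / "trio.vcf"
        write_trio_vcf(sim, str(path))
        loaded = load_trio_vcf(str(path), sim.trio)
        assert len(loaded) == len(sim.sites)
        orig = {s.variant.pos: s for s in sim.sites}
        for s in loaded:
            o = orig[s.variant.pos]
            assert s.gt == {k: tuple(v) for k, v in o.gt.items()}
            assert s.ad == o.ad
            assert s.variant.info.get("GENE") == o.variant.info.get("GENE")

    def test_mendelian_guard_aborts_bad_trio(self):
        bad = [site(100, PLOF_INFO, pro=(1, 1))] * 10  # systematic violations
        assert run_trio_scan(bad, TRIO, {"G1"}, {}) == []
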