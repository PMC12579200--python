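"""Mendelian-violation detection and the candidate filter cascade."""

import pytest

from dnvkit import discovery
from dnvkit.discovery import (
    DNVFilterConfig,
    apply_filters,
    classify_deleteriousness,
    detect_mendelian_candidates,
    per_proband_cap,
    summarize_candidates,
    trail_outcome,
)
from dnvkit.variants import GenotypeCall, Pedigree, Trio, VariantSite

TRIO = Trio(family_id="FAM0", proband="P0", father="F0", mother="M0")
PED = Pedigree(trios=[TRIO])


def _call(gt, ad_ref, ad_alt, gq=99, mbq=30, strands=True):
    kwargs = {}
    if strands:
        kwargs = dict(
            ad_ref_fwd=ad_ref // 2,
            ad_ref_rev=ad_ref - ad_ref // 2,
            ad_alt_fwd=ad_alt // 2,
            ad_alt_rev=ad_alt - ad_alt // 2,
        )
    return GenotypeCall(
        genotype=gt, gq=gq, dp=ad_ref + ad_alt, ad_ref=ad_ref, ad_alt=ad_alt,
        min_base_q=mbq, **kwargs
    )


def _trio_site(proband, father, mother, pos=100, **site_kwargs):
    defaults = dict(
        chrom="chr1", pos=pos, ref="A", alt="G", gene="G1",
        consequence_class="missense", population_af="absent", cadd_phred=25.0,
    )
    defaults.update(site_kwargs)
    site = VariantSite(**defaults)
    site.calls = {"P0": proband, "F0": father, "M0": mother}
    return site


class TestDetect:
    def test_het_proband_homref_parents_is_candidate(self):
        site = _trio_site(_call("het", 10, 10), _call("homref", 30, 0), _call("homref", 30, 0))
        cands = detect_mendelian_candidates([site], PED)
        assert len(cands) == 1 and cands[0].proband == "P0"

    @pytest.mark.parametrize("proband_gt", ["homref", "homalt"])
    def test_non_het_proband_is_not_candidate(self, proband_gt):
        ad = (0, 30) if proband_gt == "homalt" else (30, 0)
        site = _trio_site(_call(proband_gt, *ad), _call("homref", 30, 0), _call("homref", 30, 0))
        assert detect_mendelian_candidates([site], PED) == []

    def test_missing_member_skips_site(self):
        site = _trio_site(_call("het", 10, 10), _call("missing", 30, 0), _call("homref", 30, 0))
        assert detect_mendelian_candidates([site], PED) == []

    def test_candidates_cover_all_spiked_truth(self, small_cohort):
        cands = detect_mendelian_candidates(
            small_cohort["sites"], small_cohort["pedigree"]
        )
        found = {(c.proband, c.site.key) for c in cands}
        truth = {(p, k) for p, k, _ in small_cohort["truth"].dnvs}
        assert truth <= found


class TestCascade:
    def _run(self, site):
        cands = detect_mendelian_candidates([site], PED)
        return apply_filters(cands, [site], PED)[0]

    def test_proband_support_boundary_kept(self):
        # 6/20 = 0.30 passes on the >= boundary
        cand = self._run(
            _trio_site(_call("het", 14, 6), _call("homref", 30, 0), _call("homref", 30, 0))
        )
        assert trail_outcome(cand, "proband_support") == "pass"
        low = self._run(
            _trio_site(_call("het", 15, 5), _call("homref", 30, 0), _call("homref", 30, 0))
        )
        assert trail_outcome(low, "proband_support") == "fail"

    def test_parent_support_boundary(self):
        # father 2/20 = 0.10 > 0.05 fails; exactly 1/20 = 0.05 is kept
        cand = self._run(
            _trio_site(_call("het", 10, 10), _call("homref", 18, 2), _call("homref", 30, 0))
        )
        assert trail_outcome(cand, "parent_support") == "fail"
        assert cand.status == "fail"
        edge = self._run(
            _trio_site(_call("het", 10, 10), _call("homref", 19, 1), _call("homref", 30, 0))
        )
        assert trail_outcome(edge, "parent_support") == "pass"

    def test_af_filter_absent_passes_common_fails(self):
        ok = self._run(
            _trio_site(_call("het", 10, 10), _call("homref", 30, 0), _call("homref", 30, 0))
        )
        assert trail_outcome(ok, "population_af") == "pass"
        common = self._run(
            _trio_site(
                _call("het", 10, 10), _call("homref", 30, 0), _call("homref", 30, 0),
                population_af=0.02,
            )
        )
        assert trail_outcome(common, "population_af") == "fail"

    def test_class_filter(self):
        other = self._run(
            _trio_site(
                _call("het", 10, 10), _call("homref", 30, 0), _call("homref", 30, 0),
                consequence_class="other",
            )
        )
        assert trail_outcome(other, "class") == "fail"

    def test_base_quality_and_not_evaluable(self):
        low = self._run(
            _trio_site(
                _call("het", 10, 10, mbq=19), _call("homref", 30, 0), _call("homref", 30, 0)
            )
        )
        assert trail_outcome(low, "base_quality") == "fail"
        site = _trio_site(
            _call("het", 10, 10, mbq=None, strands=False),
            _call("homref", 30, 0),
            _call("homref", 30, 0),
        )
        cand = self._run(site)
        assert trail_outcome(cand, "base_quality") == "not-evaluable"
        assert trail_outcome(cand, "strand_bias") == "not-evaluable"
        assert cand.status == "pass"  # not-evaluable never fails a candidate

    def test_strand_bias_extreme_fails(self):
        proband = GenotypeCall(
            genotype="het", gq=99, dp=80, ad_ref=40, ad_alt=40,
            ad_ref_fwd=20, ad_ref_rev=20, ad_alt_fwd=40, ad_alt_rev=0,
            min_base_q=30,
        )
        cand = self._run(
            _trio_site(proband, _call("homref", 30, 0), _call("homref", 30, 0))
        )
        assert trail_outcome(cand, "strand_bias") == "fail"

    def test_singleton_filter_counts_probands_only(self):
        ped = Pedigree(
            trios=[
                Trio("FAM0", "P0", "F0", "M0"),
                Trio("FAM1", "P1", "F1", "M1"),
            ]
        )
        site = VariantSite(
            chrom="chr1", pos=5, ref="A", alt="G", gene="G1",
            consequence_class="missense", population_af="absent",
        )
        site.calls = {
            "P0": _call("het", 10, 10), "F0": _call("homref", 30, 0),
            "M0": _call("homref", 30, 0), "P1": _call("het", 10, 10),
            "F1": _call("homref", 30, 0), "M1": _call("homref", 30, 0),
        }
        cands = detect_mendelian_candidates([site], ped)
        apply_filters(cands, [site], ped)
        assert len(cands) == 2
        assert all(trail_outcome(c, "singleton") == "fail" for c in cands)

    def test_pass_set_equals_independent_predicate_oracle(self, small_cohort):
        """The cascade's pass set must match an order-free evaluation of the
        same predicates (filter order is presentational only)."""
        sites = small_cohort["sites"]
        ped = small_cohort["pedigree"]
        config = DNVFilterConfig()
        cands = apply_filters(
            detect_mendelian_candidates(sites, ped), sites, ped, config
        )
        # independent oracle: evaluate predicates in a scrambled order
        proband_alt_carriers = {}
        probands = set(ped.probands)
        for site in sites:
            n = sum(
                1 for s, c in site.calls.items()
                if s in probands and c.genotype in ("het", "homalt")
            )
            proband_alt_carriers[site.key] = n
        trio_by_proband = {t.proband: t for t in ped.trios}
        for cand in cands:
            site = cand.site
            trio = trio_by_proband[cand.proband]
            p_call = site.calls[trio.proband]
            checks = []
            checks.append(
                p_call.min_base_q is None or p_call.min_base_q >= config.min_base_q
            )
            for parent in (trio.father, trio.mother):
                frac = site.calls[parent].alt_fraction
                checks.append(frac is None or frac <= config.max_parent_alt_fraction)
            checks.append(proband_alt_carriers[site.key] == 1)
            af = site.population_af
            checks.append(af is None or af == "absent" or af < config.max_af)
            checks.append(site.consequence_class in config.retained_classes)
            frac = p_call.alt_fraction
            checks.append(frac is None or frac >= config.min_proband_alt_fraction)
            sb = discovery._strand_bias_phred(p_call)
            checks.append(sb is None or sb < config.strand_bias_phred_max)
            assert (cand.status == "pass") == all(checks)

    def test_truth_recovery_and_artifact_rejection(self, small_cohort):
        sites = small_cohort["sites"]
        ped = small_cohort["pedigree"]
        truth = small_cohort["truth"]
        cands = apply_filters(detect_mendelian_candidates(sites, ped), sites, ped)
        passing = {(c.proband, c.site.key) for c in cands if c.status == "pass"}
        assert {(p, k) for p, k, _ in truth.dnvs} <= passing
        artifact_keys = {(p, k) for p, k, _ in truth.artifacts}
        artifact_cands = [c for c in cands if (c.proband, c.site.key) in artifact_keys]
        assert len(artifact_cands) == len(artifact_keys)
        assert all(
            trail_outcome(c, "parent_support") == "fail" for c in artifact_cands
        )

    def test_no_passing_duplicates_share_position(self, small_cohort):
        sites = small_cohort["sites"]
        ped = small_cohort["pedigree"]
        cands = apply_filters(detect_mendelian_candidates(sites, ped), sites, ped)
        passing = [c for c in cands if c.status == "pass"]
        keys = [(c.site.chrom, c.site.pos, c.site.alt) for c in passing]
        assert len(keys) == len(set(keys))


class TestCapAndTiers:
    def test_per_proband_cap_flags(self):
        cands = [
            discovery.CandidateDNV(proband="P0", site=None, status="pass")
            for _ in range(6)
        ]
        assert per_proband_cap(cands) == ["P0"]
        assert per_proband_cap([]) == []

    def test_table1_has_no_capped_probands(self, table1_candidates):
        assert per_proband_cap(table1_candidates) == []

    @pytest.mark.parametrize(
        "cadd,tier", [(29.8, "top1pct"), (20.0, "standard"), (None, "unscored")]
    )
    def test_deleteriousness_tiers(self, cadd, tier):
        site = VariantSite(chrom="chr1", pos=1, ref="A", alt="G", cadd_phred=cadd)
        cand = discovery.CandidateDNV(proband="P0", site=site)
        classify_deleteriousness([cand])
        assert cand.tier == tier

    def test_table1_top1pct_count(self, table1_candidates):
        classify_deleteriousness(table1_candidates)
        assert sum(c.tier == "top1pct" for c in table1_candidates) == 13


class TestSummarize:
    def test_table1_histogram_and_classes(self, table1_candidates):
        histogram, class_counts = summarize_candidates(table1_candidates, 36)
        assert histogram == {0: 15, 1: 10, 2: 9, 3: 2}
        assert class_counts == {
            "missense": 17, "splice": 3, "synonymous": 14, "nonsense": 0
        }

    def test_empty_set(self):
        histogram, class_counts = summarize_candidates([], 36)
        assert histogram == {0: 36}
        assert set(class_counts.values()) == {0}
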