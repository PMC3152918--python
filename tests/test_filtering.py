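"""Inclusion criteria, region exclusion, and parsimony polarization."""

import numpy as np
import pytest

from mutcontext import (
    RegionIndex,
    SimulationConfig,
    check_criteria,
    exclude_by_region,
    filter_snps,
    polarize,
    simulate,
)
from mutcontext.filtering import (
    CHIMP_MISMATCH_LIMIT,
    GAP_OR_N,
    NEAR_FLANK_MISMATCH,
    NO_OUTGROUP_MATCH,
    NOT_BIALLELIC,
    ORANG_MISMATCH_LIMIT,
    UNALIGNED,
    PolarizationError,
)
from mutcontext.records import CENTER

from conftest import BASE_WINDOW, make_snp, mutate_window

# window indices far from the center and outside the ±3 near-flank zone
FAR = [0, 1, 2, 3, 4, 5, 6, 14, 15, 16, 17, 18, 19, 20]


def _mismatch(window, n, offset=0):
    """Flip n far-flank positions to a different base."""
    flips = {}
    for i in FAR[offset : offset + n]:
        flips[i] = "A" if window[i] != "A" else "G"
    return mutate_window(window, flips)


class TestRegionExclusion:
    def test_gene_flank_boundary(self):
        genes = RegionIndex([("chr1", 6000, 7000)])
        inside = make_snp(pos=5000)
        outside = make_snp(pos=4999)
        assert exclude_by_region(inside, genes, None, flank_bp=1000)
        assert not exclude_by_region(outside, genes, None, flank_bp=1000)

    def test_cpg_island_excluded_without_flank(self):
        cpg = RegionIndex([("chr1", 900, 1100)])
        assert exclude_by_region(make_snp(pos=1000), None, cpg)
        assert not exclude_by_region(make_snp(pos=1101), None, cpg)

    def test_unknown_chromosome_not_excluded(self):
        genes = RegionIndex([("chr2", 0, 10_000)])
        assert not exclude_by_region(make_snp(pos=1000), genes, None)


class TestCriteria:
    def test_clean_record_accepted(self, clean_snp):
        decision = check_criteria(clean_snp)
        assert decision.accepted and decision.reason_codes == ()

    def test_outgroup_disagreement_rejected(self):
        snp = make_snp(orang=mutate_window(BASE_WINDOW, {CENTER: "T"}))
        assert NO_OUTGROUP_MATCH in check_criteria(snp).reason_codes

    def test_outgroup_base_outside_alleles_rejected(self):
        both_g = mutate_window(BASE_WINDOW, {CENTER: "G"})
        snp = make_snp(chimp=both_g, orang=both_g)
        assert NO_OUTGROUP_MATCH in check_criteria(snp).reason_codes

    def test_chimp_mismatch_threshold_is_one(self):
        assert check_criteria(make_snp(chimp=_mismatch(BASE_WINDOW, 1))).accepted
        decision = check_criteria(make_snp(chimp=_mismatch(BASE_WINDOW, 2)))
        assert CHIMP_MISMATCH_LIMIT in decision.reason_codes

    def test_orang_mismatch_threshold_is_six(self):
        assert check_criteria(make_snp(orang=_mismatch(BASE_WINDOW, 6))).accepted
        decision = check_criteria(make_snp(orang=_mismatch(BASE_WINDOW, 7)))
        assert decision.reason_codes == (ORANG_MISMATCH_LIMIT,)

    def test_center_position_not_counted_as_mismatch(self):
        # outgroups carry the other allele at the center: legal, not a flank mismatch
        chimp = mutate_window(BASE_WINDOW, {CENTER: "T"})
        snp = make_snp(chimp=chimp, orang=chimp)
        assert check_criteria(snp).accepted

    def test_near_flank_mismatch_within_three_bp(self):
        for idx in (CENTER - 3, CENTER - 1, CENTER + 1, CENTER + 3):
            chimp = mutate_window(BASE_WINDOW, {idx: "A" if BASE_WINDOW[idx] != "A" else "G"})
            decision = check_criteria(make_snp(chimp=chimp))
            assert NEAR_FLANK_MISMATCH in decision.reason_codes, idx

    def test_gap_and_n_rejected(self):
        assert GAP_OR_N in check_criteria(
            make_snp(human=mutate_window(BASE_WINDOW, {3: "N"}))
        ).reason_codes
        assert GAP_OR_N in check_criteria(
            make_snp(orang=mutate_window(BASE_WINDOW, {3: "-"}))
        ).reason_codes

    def test_malformed_window_length_rejected_as_gap(self):
        decision = check_criteria(make_snp(chimp=BASE_WINDOW[:-1]))
        assert GAP_OR_N in decision.reason_codes

    def test_missing_outgroup_rejected(self):
        assert UNALIGNED in check_criteria(make_snp(orang=None)).reason_codes

    def test_non_biallelic_rejected(self):
        assert NOT_BIALLELIC in check_criteria(make_snp(alleles=("C", "C"))).reason_codes

    def test_all_failed_codes_reported(self):
        snp = make_snp(
            alleles=("C", "C"),
            chimp=_mismatch(BASE_WINDOW, 2),
            orang=_mismatch(BASE_WINDOW, 7),
        )
        codes = set(check_criteria(snp).reason_codes)
        assert {NOT_BIALLELIC, CHIMP_MISMATCH_LIMIT, ORANG_MISMATCH_LIMIT} <= codes

    def test_acceptance_monotone_in_mismatch_limits(self):
        """Raising the (5)/(6) limits never rejects a previously accepted SNP."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            snp = make_snp(
                chimp=_mismatch(BASE_WINDOW, int(rng.integers(0, 4))),
                orang=_mismatch(BASE_WINDOW, int(rng.integers(0, 9))),
            )
            loose = check_criteria(snp, chimp_mismatch_max=2, orang_mismatch_max=8)
            strict = check_criteria(snp)
            if strict.accepted:
                assert loose.accepted


class TestPolarize:
    def test_ancestral_is_outgroup_allele(self, clean_snp):
        rec = polarize(clean_snp)
        assert rec.ancestral == "C" and rec.derived == "T"

    def test_ag_snp_with_g_outgroups(self):
        g_center = mutate_window(BASE_WINDOW, {CENTER: "G"})
        snp = make_snp(alleles=("A", "G"), human=g_center, chimp=g_center, orang=g_center)
        rec = polarize(snp)
        assert rec.ancestral == "G" and rec.derived == "A"

    def test_window_is_ancestralized(self):
        c_out = BASE_WINDOW  # center C
        human = mutate_window(BASE_WINDOW, {CENTER: "A"})  # reference shows derived
        rec = polarize(make_snp(alleles=("A", "C"), human=human, chimp=c_out, orang=c_out))
        assert rec.window[CENTER] == rec.ancestral == "C"

    def test_rejected_record_raises(self):
        with pytest.raises(PolarizationError):
            polarize(make_snp(orang=None))


class TestOnSyntheticData:
    def test_zero_divergence_accepts_all_and_recovers_truth(self):
        cfg = SimulationConfig(
            genome_length=100_000, chimp_divergence=0.0, orang_divergence=0.0, seed=5
        )
        result = simulate(cfg)
        assert result.snps, "simulation produced no SNPs"
        accepted, rejections = filter_snps(result.snps)
        assert len(accepted) == len(result.snps) and not rejections
        truth = {(c, p): a for c, p, a in result.truth.ancestral_alleles}
        for rec in accepted:
            assert rec.ancestral == truth[(rec.chrom, rec.pos)]

    def test_conservation_of_record_counts(self, cg_sim):
        accepted, rejections = filter_snps(cg_sim.snps)
        assert len(accepted) + sum(rejections.values()) == len(cg_sim.snps)
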