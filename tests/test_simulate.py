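"""Synthetic-data generator: determinism, planted effects, region BEDs."""

import numpy as np
import pytest

from mutcontext import (
    RegionIndex,
    SimulationConfig,
    context_site_fraction,
    expected_observed_bias,
    filter_snps,
    simulate,
)
from mutcontext.filtering import exclude_by_region
from mutcontext.simulate import (
    SimulationConfigError,
    emit_region_beds,
    read_truth,
    resolve_effects,
    write_outputs,
)


class TestConfig:
    def test_composition_must_sum_to_one(self):
        with pytest.raises(SimulationConfigError):
            SimulationConfig(base_composition=(0.5, 0.5, 0.5, 0.5))

    def test_multipliers_must_be_positive(self):
        with pytest.raises(SimulationConfigError):
            SimulationConfig(planted_effects={"C>T|1,CG": -1.0})

    def test_strand_mirroring_adds_complement(self):
        cfg = SimulationConfig(planted_effects={"C>T|1,CG": 5.0})
        assert resolve_effects(cfg) == {"C>T|1,CG": 5.0, "G>A|2,CG": 5.0}

    def test_mirror_conflict_is_error(self):
        cfg = SimulationConfig(
            planted_effects={"C>T|1,CG": 5.0, "G>A|2,CG": 4.0}
        )
        with pytest.raises(SimulationConfigError):
            resolve_effects(cfg)

    def test_no_mirroring_when_strand_asymmetric(self):
        cfg = SimulationConfig(
            planted_effects={"C>T|1,CG": 5.0}, strand_symmetric=False
        )
        assert resolve_effects(cfg) == {"C>T|1,CG": 5.0}


class TestDeterminism:
    def test_same_seed_same_output(self):
        cfg = SimulationConfig(genome_length=50_000, seed=9)
        r1, r2 = simulate(cfg), simulate(cfg)
        assert r1.genome == r2.genome
        assert r1.snps == r2.snps
        assert r1.truth.multipliers == r2.truth.multipliers

    def test_written_outputs_byte_identical(self, tmp_path):
        cfg = SimulationConfig(genome_length=30_000, seed=2)
        p1 = write_outputs(simulate(cfg), tmp_path / "a")
        p2 = write_outputs(simulate(cfg), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seed_different_snps(self):
        a = simulate(SimulationConfig(genome_length=50_000, seed=1))
        b = simulate(SimulationConfig(genome_length=50_000, seed=2))
        assert a.snps != b.snps


class TestMutationModel:
    def test_snp_yield_tracks_baseline_rate(self, null_sim_small):
        cfg = null_sim_small.config
        expected = cfg.genome_length * 3 * cfg.baseline_rate
        assert len(null_sim_small.snps) == pytest.approx(expected, rel=0.1)

    def test_every_snp_records_truth(self, null_sim_small):
        assert len(null_sim_small.truth.ancestral_alleles) == len(null_sim_small.snps)
        for snp, (chrom, pos, anc) in zip(
            null_sim_small.snps, null_sim_small.truth.ancestral_alleles
        ):
            assert (snp.chrom, snp.pos) == (chrom, pos)
            assert anc in snp.alleles
            assert snp.human_window[10] == anc  # windows are ancestral sequence

    def test_null_bias_near_one(self, null_sim_small):
        from mutcontext import (
            bias_standard_error,
            count_mutation_contexts,
            flank_word_freqs,
            mutation_bias,
            parse_context,
        )

        accepted, _ = filter_snps(null_sim_small.snps)
        counts = count_mutation_contexts(accepted, max_len=2)
        freqs = flank_word_freqs(accepted, max_len=2)
        for ctx_id in ("C>T|1,CG", "A>G|2,TA", "T>C|1,TG"):
            ctx = parse_context(ctx_id)
            bias = mutation_bias(ctx, counts, freqs)
            sub_id = f"{ctx.src}>{ctx.dst}|1,{ctx.src}"
            se = bias_standard_error(counts.get(ctx), counts.get(sub_id), bias)
            assert abs(bias - 1.0) < 3 * se, ctx_id

    def test_planted_multiplier_scales_realized_rate(self, cg_sim):
        """Realized context-specific mutation fractions match the rate model."""
        genome = cg_sim.genome["chr1"]
        cg_c_sites = genome.count("CG")
        c_sites = genome.count("C")
        muts = [
            (pos, anc)
            for _, pos, anc in cg_sim.truth.ancestral_alleles
        ]
        derived = {s.pos: s for s in cg_sim.snps}
        n_ct_cg = n_ct_other = 0
        for pos, anc in muts:
            if anc != "C":
                continue
            snp = derived[pos]
            der = snp.alleles[0] if snp.alleles[1] == anc else snp.alleles[1]
            if der != "T":
                continue
            if pos + 1 < len(genome) and genome[pos + 1] == "G":
                n_ct_cg += 1
            else:
                n_ct_other += 1
        rate_cg = n_ct_cg / cg_c_sites
        rate_other = n_ct_other / (c_sites - cg_c_sites)
        ratio = rate_cg / rate_other
        se = ratio * np.sqrt(1 / n_ct_cg + 1 / n_ct_other)
        assert abs(ratio - 5.0) < 3 * se


class TestRegionBeds:
    def test_default_beds_empty(self, tmp_path):
        genes, cpg = emit_region_beds(SimulationConfig(genome_length=30_000), tmp_path)
        assert genes.read_text() == "" and cpg.read_text() == ""

    def test_gene_covering_half_genome_excludes_half(self):
        n = 200_000
        cfg = SimulationConfig(genome_length=n, seed=3, gene_regions=((0, n // 2),))
        result = simulate(cfg)
        genes = RegionIndex([(cfg.chrom, 0, n // 2)])
        excluded = sum(
            exclude_by_region(s, genes, None, flank_bp=1000) for s in result.snps
        )
        frac = excluded / len(result.snps)
        expected = (n / 2 + 1000) / n
        se = np.sqrt(expected * (1 - expected) / len(result.snps))
        assert abs(frac - expected) < 3 * se

    def test_gene_covering_everything_accepts_nothing(self):
        n = 50_000
        cfg = SimulationConfig(genome_length=n, seed=4, gene_regions=((0, n),))
        result = simulate(cfg)
        genes = RegionIndex([(cfg.chrom, 0, n)])
        accepted, rejections = filter_snps(result.snps, genes=genes)
        assert not accepted
        assert rejections["REGION_EXCLUDED"] == len(result.snps)


class TestTruthRoundtrip:
    def test_truth_file_roundtrip(self, tmp_path):
        cfg = SimulationConfig(
            genome_length=30_000, planted_effects={"T>C|2,ATTG": 3.5}, seed=6
        )
        result = simulate(cfg)
        paths = write_outputs(result, tmp_path)
        truth = read_truth(paths["truth"])
        assert truth.multipliers == result.truth.multipliers
        assert truth.ancestral_alleles == result.truth.ancestral_alleles


def test_attenuation_helpers():
    # with f -> 0 the observed bias approaches the planted multiplier
    assert expected_observed_bias(5.0, 0.0) == 5.0
    assert expected_observed_bias(5.0, 0.25) == pytest.approx(5.0 / 2.0)
    f = context_site_fraction("C>T|1,CG", (0.25, 0.25, 0.25, 0.25))
    assert f == pytest.approx(0.25)
    f4 = context_site_fraction("T>C|2,ATTG", (0.25, 0.25, 0.25, 0.25))
    assert f4 == pytest.approx(0.25**3)
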