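"""Simulator unit and property tests: GC, heterozygosity, renderings, reads."""

import numpy as np
import pandas as pd
import pytest

from haplodepth import SimulationConfig
from haplodepth.seqs import gc_fraction, to_str
from haplodepth.simulate import (
    apply_true_duplication,
    diverge_haplotypes,
    expected_pair_count,
    generate_ancestor,
    make_marker_loci,
    render_assemblies,
    simulate_genome,
    simulate_reads,
    truth_depth,
)


class TestAncestor:
    def test_gc_content_target(self):
        seq = generate_ancestor(100_000, 0.3221, seed=1)
        assert abs(gc_fraction(seq) - 0.3221) < 0.01

    def test_gc_count_within_binomial_noise(self):
        seq = generate_ancestor(10_000, 0.5, seed=3)
        gc = gc_fraction(seq) * 10_000
        sd = np.sqrt(10_000 * 0.25)
        assert abs(gc - 5000) <= 3 * sd

    def test_seed_determinism(self):
        a = generate_ancestor(5000, 0.5, seed=7)
        b = generate_ancestor(5000, 0.5, seed=7)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, generate_ancestor(5000, 0.5, seed=8))

    @pytest.mark.parametrize("length,gc", [(0, 0.5), (-5, 0.5), (100, 0.0), (100, 1.0)])
    def test_invalid_arguments(self, length, gc):
        with pytest.raises(ValueError):
            generate_ancestor(length, gc, seed=1)


class TestDivergence:
    def test_snv_count_binomial(self):
        cfg = SimulationConfig(
            snv_rate=0.004, indel_rate=0.0004, homozygous_block_fraction=0.0, seed=5
        )
        anc = {"scf1": generate_ancestor(1_000_000, 0.32, seed=5)}
        genome = diverge_haplotypes(anc, cfg)
        n_snv = int((genome.truth_variants["type"] == "SNV").sum())
        # 4000 expected, 3 binomial SD ~ 190
        assert abs(n_snv - 4000) <= 190

    @pytest.mark.parametrize("rate", [0.001, 0.004, 0.01])
    def test_heterozygosity_recovery(self, rate):
        cfg = SimulationConfig(
            snv_rate=rate, indel_rate=0.0, homozygous_block_fraction=0.0, seed=11
        )
        L = 300_000
        genome = diverge_haplotypes({"s": generate_ancestor(L, 0.32, seed=11)}, cfg)
        n = int((genome.truth_variants["type"] == "SNV").sum())
        sd = np.sqrt(L * rate * (1 - rate))
        assert abs(n - L * rate) <= 3 * sd

    def test_zero_rate_identity(self):
        cfg = SimulationConfig(snv_rate=0.0, indel_rate=0.0, homozygous_block_fraction=0.0)
        anc = {"scf1": generate_ancestor(20_000, 0.4, seed=2)}
        genome = diverge_haplotypes(anc, cfg)
        assert np.array_equal(genome.hap1["scf1"], genome.hap2["scf1"])
        assert len(genome.truth_variants) == 0

    def test_variants_confined_outside_homozygous_block(self):
        cfg = SimulationConfig(
            snv_rate=0.01, indel_rate=0.001, homozygous_block_fraction=0.5, seed=3
        )
        genome = diverge_haplotypes({"s": generate_ancestor(50_000, 0.4, seed=3)}, cfg)
        (_, hs, he), = genome.homozygous_blocks[["scaffold", "start", "end"]].itertuples(
            index=False
        )
        pos = genome.truth_variants["pos"].to_numpy()
        assert ((pos < hs) | (pos >= he)).all()
        # identical sequence within the block (block coordinates are on hap1;
        # indels before the block shift hap2, so compare through the coord map)
        s2, e2 = genome.hap2_pos("s", hs), genome.hap2_pos("s", he)
        assert np.array_equal(genome.hap1["s"][hs:he], genome.hap2["s"][s2:e2])

    def test_phase_blocks_inside_heterozygous_intervals(self):
        cfg = SimulationConfig(homozygous_block_fraction=0.4, phased_fraction=0.8, seed=9)
        genome = diverge_haplotypes({"s": generate_ancestor(60_000, 0.4, seed=9)}, cfg)
        (_, hs, he), = genome.homozygous_blocks[["scaffold", "start", "end"]].itertuples(
            index=False
        )
        for _, bs, be in genome.phase_blocks[["scaffold", "start", "end"]].itertuples(
            index=False
        ):
            assert be <= hs or bs >= he  # no overlap with the homozygous block

    def test_genome_seed_determinism(self):
        cfg = SimulationConfig(n_autosomes=2, scaffold_length=20_000, seed=21)
        g1, g2 = simulate_genome(cfg), simulate_genome(cfg)
        for name in g1.scaffolds:
            assert np.array_equal(g1.hap2[name], g2.hap2[name])
        pd.testing.assert_frame_equal(g1.truth_variants, g2.truth_variants)


@pytest.fixture(scope="module")
def genome():
    cfg = SimulationConfig(n_autosomes=2, n_x_scaffolds=0, scaffold_length=50_000, seed=4)
    return simulate_genome(cfg), cfg


class TestRenderings:
    def test_zero_artifact_fraction_identity(self, genome):
        g, cfg = genome
        loci = make_marker_loci(g, 10, gene_length=1000, seed=1)
        cfg0 = SimulationConfig(**{**cfg.to_dict(), "artifact_fraction": 0.0})
        collapsed, artifact = render_assemblies(g, loci, cfg0)
        assert set(artifact.sequences) == set(collapsed.sequences)
        assert artifact.total_length == collapsed.total_length

    def test_artifact_count_and_double_presence(self, genome):
        g, cfg = genome
        loci = make_marker_loci(g, 20, gene_length=1000, seed=1)
        cfg3 = SimulationConfig(**{**cfg.to_dict(), "artifact_fraction": 0.3})
        collapsed, artifact = render_assemblies(g, loci, cfg3)
        labels = artifact.duplication_truth["label"]
        assert (labels == "haplotype_artifact").sum() == 6  # round(0.3 * 20)
        extra = set(artifact.sequences) - set(collapsed.sequences)
        assert len(extra) == 6
        # each artifact locus sequence present twice in the artifact rendering
        for _, row in artifact.duplication_truth.iterrows():
            if row["label"] != "haplotype_artifact":
                continue
            alt_name = f"{row['scaffold']}_alt_{row['start']}_{row['end']}"
            assert alt_name in artifact.sequences

    def test_length_bookkeeping_exact(self, genome):
        g, cfg = genome
        loci = make_marker_loci(g, 20, gene_length=1000, seed=1)
        cfg3 = SimulationConfig(**{**cfg.to_dict(), "artifact_fraction": 0.3})
        collapsed, artifact = render_assemblies(g, loci, cfg3)
        appended = sum(
            len(artifact.sequences[n])
            for n in set(artifact.sequences) - set(collapsed.sequences)
        )
        assert artifact.total_length - collapsed.total_length == appended

    def test_artifact_without_loci_raises(self, genome):
        g, cfg = genome
        with pytest.raises(ValueError):
            render_assemblies(g, [], SimulationConfig(
                **{**cfg.to_dict(), "artifact_fraction": 0.5}
            ))


class TestTrueDuplication:
    def test_empty_is_identity(self, small_genome):
        assert apply_true_duplication(small_genome, []) is small_genome

    def test_haplotypes_grow_by_locus_length(self, small_genome):
        locus = ("scf1", 5000, 7000)
        dup = apply_true_duplication(small_genome, [locus])
        p1 = dup.physical_haplotype(1)
        p2 = dup.physical_haplotype(2)
        assert len(p1["scf1"]) == small_genome.scaffold_length("scf1") + 2000
        # no indels in this fixture, so hap2 grows identically
        assert len(p2["scf1"]) == len(small_genome.hap2["scf1"]) + 2000
        # the tandem copy duplicates the locus sequence
        assert np.array_equal(p1["scf1"][5000:7000], p1["scf1"][7000:9000])

    def test_overlapping_loci_rejected(self, small_genome):
        with pytest.raises(ValueError):
            apply_true_duplication(small_genome, [("scf1", 100, 500), ("scf1", 400, 900)])


class TestReads:
    def test_pair_count_and_truth_depth(self, small_config, small_genome):
        reads = simulate_reads(small_genome, "female", small_config)
        total = 2 * sum(len(s) for s in small_genome.hap1.values())
        assert reads.n_pairs == expected_pair_count(
            small_config.coverage, total, small_config.read_length
        )
        lengths = {n: small_genome.scaffold_length(n) for n in small_genome.scaffolds}
        depth = truth_depth(reads, lengths)
        interior = depth["scf1"][1000:-1000]
        assert abs(interior.mean() - 30.0) < 3.0

    def test_error_free_reads_are_exact_substrings(self, small_config, small_genome):
        reads = simulate_reads(small_genome, "female", small_config)
        rl = small_config.read_length
        hap = {1: small_genome.physical_haplotype(1), 2: small_genome.physical_haplotype(2)}
        from haplodepth.seqs import revcomp

        for i in [0, 11, 503, reads.n_pairs - 1]:
            src = hap[int(reads.haplotype[i])][reads.scaffold[i]]
            r1 = reads.r1[i]
            window = src[reads.r1_start[i] : reads.r1_start[i] + rl]
            if reads.r1_is_reverse[i]:
                assert np.array_equal(r1, revcomp(window))
            else:
                assert np.array_equal(r1, window)

    def test_male_has_no_second_x_copy(self):
        cfg = SimulationConfig(
            n_autosomes=1, n_x_scaffolds=1, scaffold_length=20_000,
            error_rate=0.0, seed=3,
        )
        genome = simulate_genome(cfg)
        male = simulate_reads(genome, "male", cfg)
        x_reads = male.haplotype[male.scaffold == "scfX1"]
        assert x_reads.size > 0
        assert (x_reads == 1).all()
        female = simulate_reads(genome, "female", cfg)
        assert (female.haplotype[female.scaffold == "scfX1"] == 2).any()

    def test_male_x_depth_half_of_autosomes(self):
        cfg = SimulationConfig(
            n_autosomes=2, n_x_scaffolds=1, scaffold_length=40_000,
            error_rate=0.0, indel_rate=0.0, seed=6,
        )
        genome = simulate_genome(cfg)
        male = simulate_reads(genome, "male", cfg)
        lengths = {n: genome.scaffold_length(n) for n in genome.scaffolds}
        depth = truth_depth(male, lengths)
        aut = depth["scf1"][1000:-1000].mean()
        x = depth["scfX1"][1000:-1000].mean()
        assert abs(aut - 30.0) < 3.0
        assert abs(x - 15.0) < 3.0

    def test_read_seed_determinism(self, small_config, small_genome):
        a = simulate_reads(small_genome, "female", small_config)
        b = simulate_reads(small_genome, "female", small_config)
        assert np.array_equal(a.r1, b.r1)
        assert np.array_equal(a.r2_start, b.r2_start)


class TestMarkerLoci:
    def test_non_overlapping_and_in_bounds(self, small_genome):
        loci = make_marker_loci(small_genome, 20, gene_length=800, seed=2)
        assert len(loci) == 20
        by_scf = {}
        for scf, s, e in loci:
            assert 0 <= s < e <= small_genome.scaffold_length(scf)
            by_scf.setdefault(scf, []).append((s, e))
        for ivs in by_scf.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))
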