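"""Placer, depth-track and pileup tests, including brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from haplodepth import SimulationConfig
from haplodepth.placement import (
    Alignments,
    depth_track,
    load_alignments,
    pileup_counts,
    place_reads,
    write_alignments_bam,
)
from haplodepth.seqs import revcomp, to_array, to_str
from haplodepth.simulate import generate_ancestor, simulate_genome, simulate_reads

from conftest import brute_force_depth


def _manual_alignments(ref_lengths, rows, read_matrix=None):
    """rows: (ref_id, pos, strand, mapq, read_id)"""
    refs = list(ref_lengths)
    return Alignments(
        references=refs,
        ref_lengths=ref_lengths,
        ref_id=np.array([r[0] for r in rows], dtype=np.int32),
        pos=np.array([r[1] for r in rows], dtype=np.int64),
        strand=np.array([r[2] for r in rows], dtype=bool),
        mapq=np.array([r[3] for r in rows], dtype=np.int16),
        nm=np.zeros(len(rows), dtype=np.int32),
        read_id=np.array([r[4] for r in rows]),
        read_matrix=read_matrix,
    )


class TestPlacer:
    def test_unique_read_gets_mapq60_at_truth_coordinate(self):
        seq = generate_ancestor(10_000, 0.5, seed=1)
        read = seq[1234 : 1234 + 150]
        aln = place_reads(read[None, :], {"scf": seq})
        assert len(aln) == 1
        assert aln.pos[0] == 1234 and aln.mapq[0] == 60 and not aln.strand[0]

    def test_reverse_complement_read_recovered(self):
        seq = generate_ancestor(10_000, 0.5, seed=2)
        read = revcomp(seq[400:550])
        aln = place_reads(read[None, :], {"scf": seq})
        assert aln.pos[0] == 400 and bool(aln.strand[0])

    def test_tie_between_identical_copies_is_mapq0(self):
        seq = generate_ancestor(5_000, 0.5, seed=3)
        assembly = {"a": seq, "b": seq.copy()}
        read = seq[100:250]
        aln = place_reads(read[None, :], assembly, seed=5)
        assert len(aln) == 1
        assert aln.mapq[0] == 0

    def test_short_read_raises(self):
        seq = generate_ancestor(1000, 0.5, seed=1)
        with pytest.raises(ValueError):
            place_reads(seq[:20][None, :], {"s": seq})

    def test_truth_recovery_on_collapsed_rendering(self, small_config, small_genome):
        """Error-free reads recover their truth coordinates almost always."""
        reads = simulate_reads(small_genome, "female", small_config)
        aln = place_reads(reads, small_genome.hap1, seed=1)
        n_reads = 2 * reads.n_pairs
        truth_start = np.concatenate([reads.r1_start, reads.r2_start])
        truth_scf = np.concatenate([reads.scaffold, reads.scaffold])
        placed_scf = np.array([aln.references[i] for i in aln.ref_id])
        correct = (
            (aln.pos == truth_start[aln.read_id])
            & (placed_scf == truth_scf[aln.read_id])
        ).sum()
        assert correct / n_reads >= 0.99

    def test_determinism(self, small_config, small_genome):
        reads = simulate_reads(small_genome, "female", small_config)
        a = place_reads(reads, small_genome.hap1, seed=9)
        b = place_reads(reads, small_genome.hap1, seed=9)
        assert np.array_equal(a.pos, b.pos) and np.array_equal(a.mapq, b.mapq)


class TestDepthTrack:
    def test_single_read_depth(self):
        aln = _manual_alignments({"s": 1000}, [(0, 100, False, 60, 0)])
        track = depth_track(aln, read_length=150)
        assert track.depths["s"][100:250].sum() == 150
        assert track.depths["s"].sum() == 150

    def test_mask_containment_vs_overlap(self):
        rows = [(0, 100, False, 60, 0), (0, 400, False, 60, 1)]
        aln = _manual_alignments({"s": 1000}, rows)
        # read at 400 fully inside mask [350, 600); read at 100 only overlaps [200, 260)
        track = depth_track(aln, mask=[("s", 350, 600), ("s", 200, 260)], read_length=150)
        assert track.depths["s"][100:250].sum() == 150
        assert track.depths["s"][400:550].sum() == 0

    def test_mask_unknown_scaffold_raises(self):
        aln = _manual_alignments({"s": 1000}, [(0, 0, False, 60, 0)])
        with pytest.raises(ValueError):
            depth_track(aln, mask=[("nope", 0, 10)], read_length=150)

    def test_random_instance_matches_interval_stabbing_oracle(self):
        rng = np.random.default_rng(0)
        lengths = {"a": 2000, "b": 1500}
        rows = [
            (int(rng.integers(0, 2)), 0, False, int(rng.choice([0, 60])), i)
            for i in range(50)
        ]
        rows = [
            (r, int(rng.integers(0, lengths["a" if r == 0 else "b"] - 150)), False, q, i)
            for i, (r, _, _, q, _) in enumerate(rows)
        ]
        aln = _manual_alignments(lengths, rows)
        track = depth_track(aln, min_mapq=1, read_length=150)
        placements = [
            ("a" if r == 0 else "b", p) for r, p, _, q, _ in rows if q >= 1
        ]
        oracle = brute_force_depth(placements, lengths, 150)
        for name in lengths:
            assert np.array_equal(track.depths[name], oracle[name])

    def test_conservation_and_mapq_monotonicity(self, small_config, small_genome):
        reads = simulate_reads(small_genome, "female", small_config)
        aln = place_reads(reads, small_genome.hap1, seed=1)
        t0 = depth_track(aln, min_mapq=0)
        t1 = depth_track(aln, min_mapq=1)
        t60 = depth_track(aln, min_mapq=60)
        rl = small_config.read_length
        assert t0.total() == len(aln) * rl  # exact conservation
        for name in t0.depths:
            assert (t1.depths[name] <= t0.depths[name]).all()
            assert (t60.depths[name] <= t1.depths[name]).all()

    def test_masking_is_monotone(self, small_config, small_genome):
        reads = simulate_reads(small_genome, "female", small_config)
        aln = place_reads(reads, small_genome.hap1, seed=1)
        plain = depth_track(aln, min_mapq=1)
        masked = depth_track(aln, min_mapq=1, mask=[("scf1", 2000, 9000)])
        for name in plain.depths:
            assert (masked.depths[name] <= plain.depths[name]).all()


class TestPileup:
    def test_all_reference_reads(self):
        ref = generate_ancestor(500, 0.5, seed=4)
        reads = np.vstack([ref[i * 10 : i * 10 + 150] for i in range(10)])
        rows = [(0, i * 10, False, 60, i) for i in range(10)]
        aln = _manual_alignments({"s": 500}, rows, read_matrix=reads)
        pc = pileup_counts(aln, {"s": ref}, sites=pd.DataFrame({"scaffold": ["s"], "pos": [100]}))
        row = pc.sites.iloc[0]
        assert row["alt_fwd"] == row["alt_rev"] == 0
        assert row["ref_fwd"] + row["ref_rev"] == 10

    def test_hand_built_pileup_matches_manual_count(self):
        """Six reads over a 40-bp reference with known mismatches."""
        ref = to_array("ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT")
        site = 16  # ref base 'A'
        reads = []
        rows = []
        for i, (start, alt, rev) in enumerate(
            [(0, None, False), (2, "C", False), (4, "C", True),
             (6, None, True), (8, "G", False), (10, None, False)]
        ):
            window = ref[start : start + 20].copy()
            if alt is not None:
                window[site - start] = ord(alt)
            reads.append(to_str(revcomp(window) if rev else window))
            rows.append((0, start, rev, 60, i))
        mat = np.vstack([to_array(s) for s in reads])
        aln = _manual_alignments({"s": 40}, rows, read_matrix=mat)
        pc = pileup_counts(aln, {"s": ref}, sites=pd.DataFrame({"scaffold": ["s"], "pos": [site]}))
        row = pc.sites.iloc[0]
        # 6 reads cover the site: 3 ref (2 fwd, 1 rev), alt 'C' 2 (1 fwd, 1 rev), 'G' 1
        assert row["ref"] == "A"
        assert row["alt"] == "C"
        assert (row["ref_fwd"], row["ref_rev"]) == (2, 1)
        assert (row["alt_fwd"], row["alt_rev"]) == (1, 1)
        total = row[["ref_fwd", "ref_rev", "alt_fwd", "alt_rev"]].sum()
        assert total <= 6  # site total never exceeds unfiltered depth

    def test_heterozygous_site_alt_fraction_near_half(self, small_config, small_genome):
        reads = simulate_reads(small_genome, "female", small_config)
        aln = place_reads(reads, small_genome.hap1, seed=1)
        truth = small_genome.truth_variants
        snvs = truth[truth["type"] == "SNV"].head(200)
        pc = pileup_counts(aln, small_genome.hap1, sites=snvs[["scaffold", "pos"]],
                           min_mapq=1)
        t = pc.sites
        baf = (t["alt_fwd"] + t["alt_rev"]) / (
            t[["ref_fwd", "ref_rev", "alt_fwd", "alt_rev"]].sum(axis=1)
        )
        assert abs(baf.mean() - 0.5) < 0.05

    def test_site_outside_scaffold_raises(self):
        ref = generate_ancestor(100, 0.5, seed=1)
        aln = _manual_alignments({"s": 100}, [(0, 0, False, 60, 0)],
                                 read_matrix=ref[:50][None, :])
        with pytest.raises(ValueError):
            pileup_counts(aln, {"s": ref}, sites=pd.DataFrame({"scaffold": ["s"], "pos": [500]}))


class TestBamRoundTrip:
    def test_write_and_reload(self, tmp_path, small_config, small_genome):
        reads = simulate_reads(small_genome, "female", small_config)
        sub = reads.reads_matrix()[:500]
        aln = place_reads(sub, small_genome.hap1, seed=2)
        path = tmp_path / "aln.bam"
        write_alignments_bam(aln, path)
        back = load_alignments(path)
        assert len(back) == len(aln)
        order_a = np.lexsort((aln.pos, aln.ref_id))
        assert np.array_equal(back.pos, aln.pos[order_a])
        assert np.array_equal(back.mapq, aln.mapq[order_a])
        assert np.array_equal(back.strand, aln.strand[order_a])

    def test_min_mapq_filter_on_load(self, tmp_path):
        seq = generate_ancestor(5_000, 0.5, seed=3)
        assembly = {"a": seq, "b": seq.copy()}  # everything multi-maps
        reads = np.vstack([seq[i : i + 150] for i in range(0, 1000, 100)])
        aln = place_reads(reads, assembly, seed=1)
        assert (aln.mapq == 0).all()
        path = tmp_path / "mq0.bam"
        write_alignments_bam(aln, path)
        assert len(load_alignments(path, min_mapq=1)) == 0
        assert len(load_alignments(path, min_mapq=0)) == len(aln)
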