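"""Read placement, filtered depth tracks and DP4-style pileup counts.

Two input routes produce the same containers:

* real mode — coordinate-sorted BAM files loaded through pysam
  (:func:`load_alignments`);
* synthetic mode — an exact-seed placer (:func:`place_reads`) applied to
  simulated read sets.  The placer builds a sorted 31-mer index of the
  assembly, collects candidate placements from seeds at both read ends and
  the middle, scores each candidate by ungapped full-length mismatch count,
  and assigns MAPQ 60 to unique best placements.  Score ties are resolved
  uniformly at random (seeded) and flagged MAPQ 0, the conventional marker
  for ambiguous multi-mapping placements.

The placer is deliberately not a general aligner: the diagnostics need depth
and ambiguity semantics, not gapped alignment, so reads spanning an indel
between haplotypes may go unplaced (a logged, acceptable loss).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqs import encode2bit, revcomp_matrix, to_array

logger = logging.getLogger(__name__)

_CHUNK = 200_000


# ---------------------------------------------------------------------------
# containers


@dataclass
class Alignments:
    """Ungapped read placements on an assembly.

    ``strand`` is True where the read aligns reverse-complemented.
    ``read_matrix`` holds the reads as sequenced (synthetic mode) and is
    required for pileup counting; ``read_id`` indexes into it.
    """

    references: list[str]
    ref_lengths: dict[str, int]
    ref_id: np.ndarray
    pos: np.ndarray
    strand: np.ndarray
    mapq: np.ndarray
    nm: np.ndarray
    read_id: np.ndarray
    read_matrix: np.ndarray | None = None

    def __len__(self) -> int:
        return self.pos.size

    @property
    def read_length(self) -> int:
        if self.read_matrix is None:
            raise ValueError("alignments carry no read sequences")
        return self.read_matrix.shape[1]

    def filtered(self, min_mapq: int = 0) -> "Alignments":
        keep = self.mapq >= min_mapq
        return Alignments(
            self.references,
            self.ref_lengths,
            self.ref_id[keep],
            self.pos[keep],
            self.strand[keep],
            self.mapq[keep],
            self.nm[keep],
            self.read_id[keep],
            self.read_matrix,
        )


@dataclass
class DepthTrack:
    """Per-base mapped read depth over an assembly, plus the filters applied."""

    depths: dict[str, np.ndarray]
    min_mapq: int = 0
    masked: bool = False

    def total(self) -> int:
        return int(sum(d.sum() for d in self.depths.values()))

    def mean(self, scaffold: str, start: int | None = None, end: int | None = None) -> float:
        d = self.depths[scaffold]
        return float(d[start:end].mean())

    def to_tsv(self, path, nonzero_only: bool = True) -> None:
        """Write (scaffold, 0-based pos, depth) rows, genomecov -dz style."""
        with open(path, "w") as fh:
            for name, d in self.depths.items():
                pos = np.flatnonzero(d) if nonzero_only else np.arange(d.size)
                for p in pos:
                    fh.write(f"{name}\t{p}\t{d[p]}\n")

    @classmethod
    def from_tsv(cls, path, scaffold_lengths: dict[str, int]) -> "DepthTrack":
        df = pd.read_csv(path, sep="\t", names=["scaffold", "pos", "depth"])
        depths = {n: np.zeros(L, dtype=np.int64) for n, L in scaffold_lengths.items()}
        for name, grp in df.groupby("scaffold"):
            depths[name][grp["pos"].to_numpy()] = grp["depth"].to_numpy()
        return cls(depths)


@dataclass
class PileupCounts:
    """Per-site strand-resolved reference/alternate depths (DP4 semantics)."""

    sites: pd.DataFrame  # scaffold, pos, ref, alt, ref_fwd, ref_rev, alt_fwd, alt_rev

    def __len__(self) -> int:
        return len(self.sites)


# ---------------------------------------------------------------------------
# k-mer index


class KmerIndex:
    """Sorted 2-bit k-mer index over a concatenated assembly."""

    def __init__(self, sequences: dict[str, np.ndarray], k: int = 31):
        if k < 1 or k > 31:
            raise ValueError("k must lie in 1..31")
        self.k = k
        self.names = list(sequences.keys())
        gap = 64  # N-gap between scaffolds; k-mers touching it are excluded
        parts, starts, ends = [], [], []
        offset = 0
        for name in self.names:
            seq = to_array(sequences[name])
            starts.append(offset)
            ends.append(offset + len(seq))
            parts.append(seq)
            parts.append(np.full(gap, ord("N"), dtype=np.uint8))
            offset += len(seq) + gap
        self.genome = np.concatenate(parts) if parts else np.zeros(0, np.uint8)
        self.starts = np.array(starts, dtype=np.int64)
        self.ends = np.array(ends, dtype=np.int64)
        self.lengths = {n: int(e - s) for n, s, e in zip(self.names, self.starts, self.ends)}

        code = encode2bit(self.genome)
        valid = code != 255
        n_win = self.genome.size - k + 1
        kmers = np.zeros(n_win, dtype=np.uint64)
        ok = np.ones(n_win, dtype=bool)
        for j in range(k):
            c = code[j : j + n_win]
            kmers |= c.astype(np.uint64) << np.uint64(2 * (k - 1 - j))
            ok &= valid[j : j + n_win]
        pos = np.flatnonzero(ok)
        kmers = kmers[pos]
        order = np.argsort(kmers, kind="stable")
        self._kmers = kmers[order]
        self._pos = pos[order]

    def encode_queries(self, mat: np.ndarray, offset: int) -> tuple[np.ndarray, np.ndarray]:
        """2-bit codes for the k-mer at ``offset`` of every row; invalid rows flagged."""
        k = self.k
        window = mat[:, offset : offset + k]
        code = encode2bit(window)
        ok = (code != 255).all(axis=1)
        q = np.zeros(mat.shape[0], dtype=np.uint64)
        for j in range(k):
            q |= code[:, j].astype(np.uint64) << np.uint64(2 * (k - 1 - j))
        return q, ok

    def lookup(self, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self._kmers, queries, side="left")
        hi = np.searchsorted(self._kmers, queries, side="right")
        return lo, hi

    def positions(self, lo: int, hi: int) -> np.ndarray:
        return self._pos[lo:hi]

    def scaffold_of(self, global_pos: np.ndarray) -> np.ndarray:
        """Index of the scaffold whose span starts at or before each position."""
        return np.searchsorted(self.starts, global_pos, side="right") - 1


# ---------------------------------------------------------------------------
# the exact-seed placer


def place_reads(
    reads,
    assembly,
    k: int = 31,
    seed: int = 0,
    max_mismatch_frac: float = 0.03,
    error_rate: float | None = None,
    max_hits_per_seed: int = 64,
    index: KmerIndex | None = None,
) -> Alignments:
    """Place a synthetic read set on an assembly rendering.

    ``reads`` is a :class:`~haplodepth.simulate.ReadSet` or a (n, L) uint8
    read matrix; ``assembly`` an :class:`~haplodepth.simulate.AssemblyRendering`
    or a name->sequence dict.  Each read gets its best-scoring (fewest
    mismatches) ungapped placement; ties are broken uniformly at random and
    marked MAPQ 0, unique bests get MAPQ 60.

    The mismatch budget is ``max(ceil(3*error_rate*L), ceil(max_mismatch_frac*L))``
    so that reads from a diverged haplotype (SNVs against the collapsed
    reference) are retained even in error-free simulations; keeping the
    fraction small also limits false mismatch columns from reads whose
    ungapped alignment overhangs an indel by a few bases.
    """
    from .simulate import AssemblyRendering, ReadSet

    if isinstance(reads, ReadSet):
        mat = reads.reads_matrix()
    else:
        mat = np.asarray(reads, dtype=np.uint8)
    if isinstance(assembly, AssemblyRendering):
        sequences = assembly.sequences
    else:
        sequences = assembly
    n_reads, rl = mat.shape
    if rl < k:
        raise ValueError(f"read length {rl} shorter than seed length {k}")

    idx = index if index is not None else KmerIndex(sequences, k=k)
    max_mm = int(np.ceil(max_mismatch_frac * rl))
    if error_rate is not None:
        max_mm = max(max_mm, int(np.ceil(3 * error_rate * rl)))

    rng = np.random.default_rng(seed)
    offsets = sorted({0, (rl - k) // 2, rl - k})
    genome = idx.genome
    col = np.arange(rl)

    out_read, out_pos, out_strand, out_mapq, out_nm, out_ref = [], [], [], [], [], []

    for c0 in range(0, n_reads, _CHUNK):
        sub = mat[c0 : c0 + _CHUNK]
        rc = revcomp_matrix(sub)
        cand_read, cand_pos, cand_strand = [], [], []
        for strand, oriented in ((0, sub), (1, rc)):
            for off in offsets:
                q, ok = idx.encode_queries(oriented, off)
                lo, hi = idx.lookup(q)
                counts = np.where(ok, hi - lo, 0)
                counts = np.where(counts <= max_hits_per_seed, counts, 0)
                # unique-hit seeds (the common case) gather vectorised
                ones = np.flatnonzero(counts == 1)
                if ones.size:
                    cand_read.append(ones)
                    cand_pos.append(idx._pos[lo[ones]] - off)
                    cand_strand.append(np.full(ones.size, strand, dtype=np.int8))
                multi = np.flatnonzero(counts > 1)
                if multi.size:
                    reps = counts[multi]
                    cand_read.append(np.repeat(multi, reps))
                    cand_pos.append(
                        np.concatenate([idx.positions(lo[i], hi[i]) for i in multi]) - off
                    )
                    cand_strand.append(
                        np.full(int(reps.sum()), strand, dtype=np.int8)
                    )
        if not cand_read:
            continue
        cread = np.concatenate(cand_read)
        cpos = np.concatenate(cand_pos)
        cstr = np.concatenate(cand_strand)

        # candidate must fit inside one scaffold
        scf = np.clip(idx.scaffold_of(cpos), 0, len(idx.starts) - 1)
        okc = (cpos >= idx.starts[scf]) & (cpos + rl <= idx.ends[scf])
        cread, cpos, cstr, scf = cread[okc], cpos[okc], cstr[okc], scf[okc]

        # dedupe (read, pos, strand) triples from multiple seeds
        key = (cread.astype(np.int64) << 1 | cstr) * np.int64(genome.size + rl) + cpos
        _, uniq = np.unique(key, return_index=True)
        cread, cpos, cstr, scf = cread[uniq], cpos[uniq], cstr[uniq], scf[uniq]

        # score: full-length ungapped mismatch count
        mm = np.empty(cread.size, dtype=np.int32)
        for e0 in range(0, cread.size, _CHUNK):
            sl = slice(e0, e0 + _CHUNK)
            ref = genome[cpos[sl][:, None] + col]
            fwd_rows = cstr[sl] == 0
            qseq = np.empty_like(ref)
            if fwd_rows.any():
                qseq[fwd_rows] = sub[cread[sl][fwd_rows]]
            if (~fwd_rows).any():
                qseq[~fwd_rows] = rc[cread[sl][~fwd_rows]]
            mm[sl] = (ref != qseq).sum(axis=1)

        good = mm <= max_mm
        cread, cpos, cstr, scf, mm = cread[good], cpos[good], cstr[good], scf[good], mm[good]
        if cread.size == 0:
            continue

        # per read: best score, tie handling
        order = np.lexsort((cpos, cstr, mm, cread))
        cread, cpos, cstr, scf, mm = (
            cread[order], cpos[order], cstr[order], scf[order], mm[order],
        )
        first = np.flatnonzero(np.r_[True, cread[1:] != cread[:-1]])
        grp_end = np.r_[first[1:], cread.size]
        best_mm = mm[first]
        # count candidates sharing the best score in each group (they are
        # contiguous at the group start because of the lexsort by mismatches)
        sizes = grp_end - first
        is_best = mm == np.repeat(best_mm, sizes)
        tie_count = np.add.reduceat(is_best.astype(np.int64), first)
        pick = first + rng.integers(0, tie_count)
        out_read.append(cread[pick] + c0)
        out_pos.append(cpos[pick] - idx.starts[scf[pick]])
        out_strand.append(cstr[pick].astype(bool))
        out_mapq.append(np.where(tie_count > 1, 0, 60).astype(np.int16))
        out_nm.append(mm[pick])
        out_ref.append(scf[pick].astype(np.int32))

    if out_read:
        read_id = np.concatenate(out_read)
        aln = Alignments(
            references=idx.names,
            ref_lengths=idx.lengths,
            ref_id=np.concatenate(out_ref),
            pos=np.concatenate(out_pos),
            strand=np.concatenate(out_strand),
            mapq=np.concatenate(out_mapq),
            nm=np.concatenate(out_nm),
            read_id=read_id,
            read_matrix=mat,
        )
    else:
        aln = Alignments(idx.names, idx.lengths, *(np.zeros(0, dtype=t) for t in
                         (np.int32, np.int64, bool, np.int16, np.int32, np.int64)),
                         read_matrix=mat)
    placed = len(aln)
    if placed < n_reads:
        logger.info("placed %d/%d reads (%.2f%%)", placed, n_reads, 100 * placed / n_reads)
    return aln


# ---------------------------------------------------------------------------
# BAM I/O (real mode)


def load_alignments(path, min_mapq: int = 0) -> Alignments:
    """Load primary, non-supplementary records from a sorted, indexed BAM."""
    import pysam

    bam = pysam.AlignmentFile(str(path), "rb")
    so = bam.header.get("HD", {}).get("SO", "unknown")
    if so != "coordinate":
        raise ValueError(f"BAM must be coordinate-sorted (SO={so})")
    if not bam.has_index():
        raise ValueError("BAM must be indexed")
    names = list(bam.references)
    lengths = dict(zip(names, bam.lengths))
    name_to_id = {n: i for i, n in enumerate(names)}

    ref_id, pos, strand, mapq, nm, seqs = [], [], [], [], [], []
    for rec in bam.fetch(until_eof=True):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.mapping_quality < min_mapq:
            continue
        ref_id.append(name_to_id[rec.reference_name])
        pos.append(rec.reference_start)
        strand.append(rec.is_reverse)
        mapq.append(rec.mapping_quality)
        nm.append(rec.get_tag("NM") if rec.has_tag("NM") else 0)
        seqs.append(rec.query_sequence or "")
    bam.close()

    mat = None
    if seqs and len({len(s) for s in seqs}) == 1 and len(seqs[0]) > 0:
        mat = np.vstack([to_array(s) for s in seqs])
        # pileups expect reads as sequenced; BAM stores them reference-oriented
        rev = np.array(strand, dtype=bool)
        if rev.any():
            mat[rev] = revcomp_matrix(mat[rev])
    return Alignments(
        references=names,
        ref_lengths=lengths,
        ref_id=np.array(ref_id, dtype=np.int32),
        pos=np.array(pos, dtype=np.int64),
        strand=np.array(strand, dtype=bool),
        mapq=np.array(mapq, dtype=np.int16),
        nm=np.array(nm, dtype=np.int32),
        read_id=np.arange(len(pos)),
        read_matrix=mat,
    )


def write_alignments_bam(aln: Alignments, path) -> None:
    """Write synthetic alignments to a coordinate-sorted, indexed BAM."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": aln.ref_lengths[n]} for n in aln.references],
    }
    order = np.lexsort((aln.pos, aln.ref_id))
    tmp = str(path)
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for i in order:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = f"read{int(aln.read_id[i])}"
            rec.reference_id = int(aln.ref_id[i])
            rec.reference_start = int(aln.pos[i])
            rec.mapping_quality = int(aln.mapq[i])
            rec.is_reverse = bool(aln.strand[i])
            if aln.read_matrix is not None:
                seq = aln.read_matrix[int(aln.read_id[i])]
                if aln.strand[i]:
                    seq = revcomp_matrix(seq[None, :])[0]
                rec.query_sequence = seq.tobytes().decode()
                rec.cigarstring = f"{seq.size}M"
                rec.query_qualities = pysam.qualitystring_to_array("?" * seq.size)
            rec.set_tag("NM", int(aln.nm[i]))
            out.write(rec)
    pysam.index(tmp)


# ---------------------------------------------------------------------------
# depth


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def depth_track(
    aln: Alignments,
    min_mapq: int = 0,
    mask: list[tuple[str, int, int]] | None = None,
    read_length: int | None = None,
) -> DepthTrack:
    """Per-base depth of retained alignments.

    Alignments below ``min_mapq`` are dropped, as are alignments *fully
    contained* within a mask interval (containment, not mere overlap —
    the strictest reading of removing reads inside repeat-masked regions).
    """
    rl = read_length if read_length is not None else aln.read_length
    keep = aln.mapq >= min_mapq
    ref_id, pos = aln.ref_id[keep], aln.pos[keep]

    if mask:
        by_scf: dict[str, list[tuple[int, int]]] = {}
        for scf, s, e in mask:
            if scf not in aln.ref_lengths:
                raise ValueError(f"mask references unknown scaffold {scf!r}")
            by_scf.setdefault(scf, []).append((s, e))
        keep2 = np.ones(pos.size, dtype=bool)
        for scf, ivs in by_scf.items():
            ivs = _merge_intervals(ivs)
            starts = np.array([s for s, _ in ivs])
            ends = np.array([e for _, e in ivs])
            rid = aln.references.index(scf)
            sel = ref_id == rid
            if not sel.any():
                continue
            p = pos[sel]
            j = np.searchsorted(starts, p, side="right") - 1
            contained = (j >= 0) & (ends[np.clip(j, 0, len(ends) - 1)] >= p + rl)
            keep2[np.flatnonzero(sel)[contained]] = False
        ref_id, pos = ref_id[keep2], pos[keep2]

    depths = {}
    for rid, name in enumerate(aln.references):
        L = aln.ref_lengths[name]
        diff = np.zeros(L + 1, dtype=np.int64)
        sel = ref_id == rid
        if sel.any():
            p = pos[sel]
            np.add.at(diff, p, 1)
            np.add.at(diff, np.minimum(p + rl, L), -1)
        depths[name] = np.cumsum(diff[:-1])
    return DepthTrack(depths, min_mapq=min_mapq, masked=bool(mask))


# ---------------------------------------------------------------------------
# pileup


def pileup_counts(
    aln: Alignments,
    assembly: dict[str, np.ndarray],
    sites: pd.DataFrame | None = None,
    min_mapq: int = 0,
) -> PileupCounts:
    """Strand-resolved DP4 tallies from ungapped alignments.

    The alternate allele at a site is the most frequent non-reference base
    observed there (ties broken alphabetically).  With ``sites=None`` every
    position carrying at least one non-reference base is reported; pass a
    DataFrame with ``scaffold``/``pos`` columns to tally specific sites
    (zero-mismatch sites then report DP4 = (fwd, rev, 0, 0)).
    """
    if aln.read_matrix is None:
        raise ValueError("pileup requires alignments carrying read sequences")
    rl = aln.read_length
    keep = np.flatnonzero(aln.mapq >= min_mapq)

    # strand-resolved depth tracks
    fwd_tracks, rev_tracks = {}, {}
    for rid, name in enumerate(aln.references):
        L = aln.ref_lengths[name]
        for tracks, want_rev in ((fwd_tracks, False), (rev_tracks, True)):
            diff = np.zeros(L + 1, dtype=np.int64)
            sel = keep[(aln.ref_id[keep] == rid) & (aln.strand[keep] == want_rev)]
            if sel.size:
                p = aln.pos[sel]
                np.add.at(diff, p, 1)
                np.add.at(diff, np.minimum(p + rl, L), -1)
            tracks[name] = np.cumsum(diff[:-1])

    # mismatch events (position, base, strand), chunked
    ev_pos: list[np.ndarray] = []
    ev_base: list[np.ndarray] = []
    ev_rev: list[np.ndarray] = []
    ev_rid: list[np.ndarray] = []
    refs = {name: to_array(seq) for name, seq in assembly.items()}
    col = np.arange(rl)
    for c0 in range(0, keep.size, _CHUNK):
        sel = keep[c0 : c0 + _CHUNK]
        rid, pos, strand = aln.ref_id[sel], aln.pos[sel], aln.strand[sel]
        qseq = aln.read_matrix[aln.read_id[sel]]
        if strand.any():
            qseq = qseq.copy()
            qseq[strand] = revcomp_matrix(qseq[strand])
        for r in np.unique(rid):
            rows = np.flatnonzero(rid == r)
            ref = refs[aln.references[r]][pos[rows][:, None] + col]
            mmr, mmc = np.nonzero(ref != qseq[rows])
            if mmr.size:
                ev_pos.append(pos[rows][mmr] + mmc)
                ev_base.append(qseq[rows][mmr, mmc])
                ev_rev.append(strand[rows][mmr])
                ev_rid.append(np.full(mmr.size, r, dtype=np.int32))

    name_to_id = {n: i for i, n in enumerate(aln.references)}
    max_l = max(aln.ref_lengths.values()) + 1 if aln.ref_lengths else 1

    if ev_pos:
        e_key = np.concatenate(ev_rid).astype(np.int64) * max_l + np.concatenate(ev_pos)
        e_base = encode2bit(np.concatenate(ev_base))
        e_rev = np.concatenate(ev_rev)
    else:
        e_key = np.zeros(0, dtype=np.int64)
        e_base = np.zeros(0, dtype=np.uint8)
        e_rev = np.zeros(0, dtype=bool)

    if sites is None:
        w_key = np.unique(e_key)
    else:
        s_rid = np.array([name_to_id.get(s, -1) for s in sites["scaffold"]], dtype=np.int64)
        s_pos = np.asarray(sites["pos"], dtype=np.int64)
        for s, rid_, p in zip(sites["scaffold"], s_rid, s_pos):
            if rid_ < 0 or not 0 <= p < aln.ref_lengths[aln.references[rid_]]:
                raise ValueError(f"site {s}:{p} outside assembly")
        w_key = np.unique(s_rid * max_l + s_pos)

    # per-site (base, strand) event tallies: shape (n_sites, 4, 2)
    counts = np.zeros((w_key.size, 4, 2), dtype=np.int64)
    if e_key.size and w_key.size:
        j = np.searchsorted(w_key, e_key)
        j_ok = (j < w_key.size) & (w_key[np.clip(j, 0, w_key.size - 1)] == e_key)
        flat = j[j_ok] * 8 + e_base[j_ok].astype(np.int64) * 2 + e_rev[j_ok]
        counts = np.bincount(flat, minlength=w_key.size * 8).reshape(w_key.size, 4, 2)

    rid_arr = (w_key // max_l).astype(np.int64)
    pos_arr = (w_key % max_l).astype(np.int64)
    scf_arr = np.array([aln.references[r] for r in rid_arr], dtype=object)
    ref_bytes = np.array(
        [refs[s][p] for s, p in zip(scf_arr, pos_arr)], dtype=np.uint8
    ) if w_key.size else np.zeros(0, dtype=np.uint8)
    ref_code = encode2bit(ref_bytes)

    per_base = counts.sum(axis=2)
    masked = per_base.copy()
    if w_key.size:
        masked[np.arange(w_key.size), np.clip(ref_code, 0, 3)] = -1
    alt_code = masked.argmax(axis=1) if w_key.size else np.zeros(0, dtype=np.int64)
    has_alt = w_key.size and (masked[np.arange(w_key.size), alt_code] > 0)
    has_alt = np.asarray(has_alt, dtype=bool) if w_key.size else np.zeros(0, dtype=bool)

    mm_fwd = counts[:, :, 0].sum(axis=1)
    mm_rev = counts[:, :, 1].sum(axis=1)
    sel = (np.arange(w_key.size), alt_code)
    alt_fwd = np.where(has_alt, counts[:, :, 0][sel], 0) if w_key.size else mm_fwd
    alt_rev = np.where(has_alt, counts[:, :, 1][sel], 0) if w_key.size else mm_rev

    dfwd = np.array([fwd_tracks[s][p] for s, p in zip(scf_arr, pos_arr)], dtype=np.int64)
    drev = np.array([rev_tracks[s][p] for s, p in zip(scf_arr, pos_arr)], dtype=np.int64)

    from .seqs import BASES

    out = pd.DataFrame(
        {
            "scaffold": scf_arr,
            "pos": pos_arr,
            "ref": [chr(b) for b in ref_bytes],
            "alt": [chr(BASES[c]) if h else "" for c, h in zip(alt_code, has_alt)],
            "ref_fwd": dfwd - mm_fwd,
            "ref_rev": drev - mm_rev,
            "alt_fwd": alt_fwd,
            "alt_rev": alt_rev,
        }
    )
    return PileupCounts(out)
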