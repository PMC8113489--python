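"""Synthetic diploid genomes, assembly renderings and sexed read sets.

This module emulates the data-generating process behind depth-based assembly
validation: a diploid individual whose two haplotypes differ by SNVs and
short indels (with long homozygous stretches from inbreeding), a collapsed
pseudo-haplotype assembly of that genome, an "artifact" assembly into which
the alternate haplotype of selected loci has been injected (the
megabubbles-scaffolding failure mode), genuine tandem duplications, and
paired-end read sets from male (hemizygous X) or female individuals.

Every operation is deterministic given its configuration and seed, and every
stochastic outcome is recorded in truth tables (variants, phase blocks,
duplication labels, read placements) so downstream diagnostics can be scored
exactly.

Coordinates are 0-based half-open throughout; haplotype 1 is the ancestor
sequence unchanged, so haplotype-1 coordinates coincide with collapsed
assembly coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .seqs import BASES, encode2bit, random_sequence, revcomp_matrix, to_array, to_str

#: flank appended around the alternate-haplotype copy of an artifact locus
ARTIFACT_FLANK = 1000

VARIANT_COLUMNS = ["scaffold", "pos", "ref", "alt", "type"]


def generate_ancestor(length: int, gc_content: float, seed: int) -> np.ndarray:
    """Random ancestral sequence with a target GC fraction.

    Returns a uint8 ASCII array; use :func:`haplodepth.seqs.to_str` for text.
    """
    rng = np.random.default_rng(seed)
    return random_sequence(length, gc_content, rng)


# ---------------------------------------------------------------------------
# diploid genome


@dataclass
class DiploidGenome:
    """Two haplotypes plus complete truth tables for one simulated individual.

    ``hap1``/``hap2`` hold the *pre-duplication* sequences; genuine tandem
    duplications registered in ``dup_loci`` are materialised on demand by
    :meth:`physical_haplotype`, which is what read simulation samples from.
    The collapsed assembly rendering deliberately keeps a single copy of each
    duplicated locus — the erroneous collapse whose depth signature the
    diagnostics are built to detect.
    """

    hap1: dict[str, np.ndarray]
    hap2: dict[str, np.ndarray]
    truth_variants: pd.DataFrame
    phase_blocks: pd.DataFrame
    sex_linkage: dict[str, str]
    dup_loci: list[tuple[str, int, int]] = field(default_factory=list)
    homozygous_blocks: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["scaffold", "start", "end"])
    )

    @property
    def scaffolds(self) -> list[str]:
        return list(self.hap1.keys())

    def scaffold_length(self, name: str) -> int:
        return len(self.hap1[name])

    def hap2_pos(self, scaffold: str, pos: int) -> int:
        """Map a haplotype-1 coordinate to the corresponding haplotype-2 one.

        Positions inside a deleted segment map to the deletion point.
        """
        tv = self.truth_variants
        rows = tv[(tv["scaffold"] == scaffold) & (tv["type"] == "indel")]
        offset = 0
        for p, ref, alt in zip(rows["pos"], rows["ref"], rows["alt"]):
            if ref == "":  # insertion in hap2 before hap1 base p
                if p <= pos:
                    offset += len(alt)
            else:  # deletion of hap1 bases [p, p+len(ref))
                if p + len(ref) <= pos:
                    offset -= len(ref)
                elif p <= pos:  # inside the deleted segment
                    offset -= pos - p
        return pos + offset

    def physical_haplotype(self, hap: int) -> dict[str, np.ndarray]:
        """Haplotype sequences with registered tandem duplications applied."""
        base = self.hap1 if hap == 1 else self.hap2
        if not self.dup_loci:
            return dict(base)
        by_scf: dict[str, list[tuple[int, int]]] = {}
        for scf, start, end in self.dup_loci:
            by_scf.setdefault(scf, []).append((start, end))
        out = {}
        for name, seq in base.items():
            loci = sorted(by_scf.get(name, []))
            if not loci:
                out[name] = seq
                continue
            parts, prev = [], 0
            for start, end in loci:
                if hap == 2:
                    start = self.hap2_pos(name, start)
                    end = self.hap2_pos(name, end)
                parts.append(seq[prev:end])
                parts.append(seq[start:end])  # the extra tandem copy
                prev = end
            parts.append(seq[prev:])
            out[name] = np.concatenate(parts)
        return out


def diverge_haplotypes(
    ancestors: dict[str, np.ndarray],
    config: SimulationConfig,
    sex_linkage: dict[str, str] | None = None,
) -> DiploidGenome:
    """Derive two haplotypes from ancestral scaffolds.

    Haplotype 1 is the ancestor unchanged; haplotype 2 receives heterozygous
    SNVs at ``snv_rate`` and short indels at ``indel_rate`` per base, all
    placed outside a single contiguous homozygous block per scaffold spanning
    ``homozygous_block_fraction`` of its length.  Phase blocks are the central
    ``phased_fraction`` of each heterozygous interval; the margins model
    heterozygous regions that remained unphased.
    """
    rng = np.random.default_rng(config.seed)
    if sex_linkage is None:
        sex_linkage = {n: ("X" if "X" in n else "autosome") for n in ancestors}

    hap1: dict[str, np.ndarray] = {}
    hap2: dict[str, np.ndarray] = {}
    var_rows: list[tuple] = []
    block_rows: list[tuple] = []
    hom_rows: list[tuple] = []

    for name, anc in ancestors.items():
        anc = to_array(anc)
        L = len(anc)
        hom_len = int(round(config.homozygous_block_fraction * L))
        if hom_len > L:
            raise ValueError(f"scaffold {name} shorter than one homozygous block")
        if hom_len > 0:
            hom_start = int(rng.integers(0, L - hom_len + 1))
            hom_rows.append((name, hom_start, hom_start + hom_len))
        else:
            hom_start = 0
        het = np.ones(L, dtype=bool)
        het[hom_start : hom_start + hom_len] = False

        snv_pos = np.flatnonzero((rng.random(L) < config.snv_rate) & het)

        # indels: thin to keep events separated and fully outside the block
        ind_pos = np.flatnonzero((rng.random(L) < config.indel_rate) & het)
        ind_len = rng.integers(1, config.max_indel + 1, size=ind_pos.size)
        ind_ins = rng.random(ind_pos.size) < 0.5
        keep, last_end = [], -(10**9)
        for i, p in enumerate(ind_pos):
            span = 0 if ind_ins[i] else int(ind_len[i])
            if p <= last_end + config.max_indel:
                continue
            if p + span > L or not het[p : p + max(span, 1)].all():
                continue
            keep.append(i)
            last_end = p + span
        ind_pos, ind_len, ind_ins = ind_pos[keep], ind_len[keep], ind_ins[keep]

        # SNVs may not sit inside deleted segments
        if ind_pos.size and snv_pos.size:
            bad = np.zeros(L, dtype=bool)
            for p, ln, ins in zip(ind_pos, ind_len, ind_ins):
                if not ins:
                    bad[p : p + ln] = True
            snv_pos = snv_pos[~bad[snv_pos]]

        h2 = anc.copy()
        if snv_pos.size:
            ref_code = encode2bit(anc[snv_pos])
            alt_code = (ref_code + rng.integers(1, 4, size=snv_pos.size)) % 4
            h2[snv_pos] = BASES[alt_code]
            for p, rc, ac in zip(snv_pos, ref_code, alt_code):
                var_rows.append(
                    (name, int(p), chr(BASES[rc]), chr(BASES[ac]), "SNV")
                )

        if ind_pos.size:
            parts, prev = [], 0
            for p, ln, ins in zip(ind_pos, ind_len, ind_ins):
                p, ln = int(p), int(ln)
                if ins:
                    inserted = random_sequence(ln, config.gc_content, rng)
                    parts.append(h2[prev:p])
                    parts.append(inserted)
                    prev = p
                    var_rows.append((name, p, "", to_str(inserted), "indel"))
                else:
                    parts.append(h2[prev:p])
                    prev = p + ln
                    var_rows.append((name, p, to_str(anc[p : p + ln]), "", "indel"))
            parts.append(h2[prev:])
            h2 = np.concatenate(parts)

        hap1[name] = anc
        hap2[name] = h2

        het_intervals = []
        if hom_len == 0:
            het_intervals.append((0, L))
        else:
            if hom_start > 0:
                het_intervals.append((0, hom_start))
            if hom_start + hom_len < L:
                het_intervals.append((hom_start + hom_len, L))
        for s, e in het_intervals:
            hl = e - s
            pl = int(round(config.phased_fraction * hl))
            if pl > 0:
                off = (hl - pl) // 2
                block_rows.append((name, s + off, s + off + pl))

    truth = pd.DataFrame(var_rows, columns=VARIANT_COLUMNS)
    truth = truth.sort_values(["scaffold", "pos"], kind="stable").reset_index(drop=True)
    blocks = pd.DataFrame(block_rows, columns=["scaffold", "start", "end"])
    hom = pd.DataFrame(hom_rows, columns=["scaffold", "start", "end"])
    return DiploidGenome(hap1, hap2, truth, blocks, sex_linkage, homozygous_blocks=hom)


def simulate_genome(config: SimulationConfig) -> DiploidGenome:
    """Convenience wrapper: ancestors for all scaffolds, then divergence.

    Autosomes are named ``scf1..scfN`` and X scaffolds ``scfX1..scfXM``.
    """
    rng = np.random.default_rng(config.seed + 17)
    ancestors: dict[str, np.ndarray] = {}
    linkage: dict[str, str] = {}
    for i in range(config.n_autosomes):
        name = f"scf{i + 1}"
        ancestors[name] = random_sequence(config.scaffold_length, config.gc_content, rng)
        linkage[name] = "autosome"
    for i in range(config.n_x_scaffolds):
        name = f"scfX{i + 1}"
        ancestors[name] = random_sequence(config.scaffold_length, config.gc_content, rng)
        linkage[name] = "X"
    return diverge_haplotypes(ancestors, config, sex_linkage=linkage)


def apply_true_duplication(
    genome: DiploidGenome, loci: list[tuple[str, int, int]]
) -> DiploidGenome:
    """Register genuine tandem duplications (copy number 2 in BOTH haplotypes).

    Returns a new genome; an empty locus list returns the genome unchanged.
    """
    if not loci:
        return genome
    combined = sorted(list(genome.dup_loci) + [tuple(x) for x in loci])
    prev_scf, prev_end = None, -1
    for scf, start, end in combined:
        if scf not in genome.hap1:
            raise ValueError(f"unknown scaffold {scf!r}")
        if not 0 <= start < end <= genome.scaffold_length(scf):
            raise ValueError(f"locus {scf}:{start}-{end} out of bounds")
        if scf == prev_scf and start < prev_end:
            raise ValueError("overlapping duplication loci")
        prev_scf, prev_end = scf, end
    return replace(genome, dup_loci=combined)


# ---------------------------------------------------------------------------
# assembly renderings


@dataclass
class AssemblyRendering:
    """One haploid representation of the genome, with duplication truth.

    ``duplication_truth`` labels every marker locus ``single``,
    ``haplotype_artifact`` or ``true_duplication``.
    """

    sequences: dict[str, np.ndarray]
    kind: str  # collapsed | artifact | true_dup
    duplication_truth: pd.DataFrame

    @property
    def total_length(self) -> int:
        return int(sum(len(s) for s in self.sequences.values()))


def render_assemblies(
    genome: DiploidGenome,
    marker_loci: list[tuple[str, int, int]],
    config: SimulationConfig,
    flank: int = ARTIFACT_FLANK,
) -> tuple[AssemblyRendering, AssemblyRendering]:
    """Build the collapsed and artifact renderings of a diploid genome.

    The collapsed rendering is haplotype 1, one copy per scaffold (truly
    duplicated loci erroneously collapsed to a single copy).  The artifact
    rendering additionally appends the haplotype-2 version of each selected
    artifact locus, plus ``flank`` bp of context, as an extra scaffold —
    mimicking injection of both haplotypes into one "haploid" assembly.
    """
    loci = sorted(tuple(x) for x in marker_loci)
    prev_scf, prev_end = None, -1
    for scf, start, end in loci:
        if scf not in genome.hap1:
            raise ValueError(f"unknown scaffold {scf!r}")
        if not 0 <= start < end <= genome.scaffold_length(scf):
            raise ValueError(f"marker locus {scf}:{start}-{end} out of bounds")
        if scf == prev_scf and start < prev_end:
            raise ValueError("marker loci must be non-overlapping")
        prev_scf, prev_end = scf, end

    def is_true_dup(locus):
        scf, s, e = locus
        return any(d[0] == scf and s < d[2] and d[1] < e for d in genome.dup_loci)

    labels = {loc: ("true_duplication" if is_true_dup(loc) else "single") for loc in loci}
    eligible = [loc for loc in loci if labels[loc] == "single"]
    if config.artifact_fraction > 0 and not loci:
        raise ValueError("artifact_fraction > 0 requires marker loci")
    n_artifact = int(round(config.artifact_fraction * len(loci)))
    n_artifact = min(n_artifact, len(eligible))
    rng = np.random.default_rng(config.seed + 7919)
    chosen_idx = rng.choice(len(eligible), size=n_artifact, replace=False) if n_artifact else []
    for i in sorted(int(j) for j in np.atleast_1d(chosen_idx)):
        labels[eligible[i]] = "haplotype_artifact"

    truth = pd.DataFrame(
        [(scf, s, e, labels[(scf, s, e)]) for scf, s, e in loci],
        columns=["scaffold", "start", "end", "label"],
    )

    collapsed = AssemblyRendering(dict(genome.hap1), "collapsed", truth)

    art_seqs = dict(genome.hap1)
    for scf, s, e in loci:
        if labels[(scf, s, e)] != "haplotype_artifact":
            continue
        s2 = genome.hap2_pos(scf, max(0, s - flank))
        e2 = genome.hap2_pos(scf, min(genome.scaffold_length(scf), e + flank))
        art_seqs[f"{scf}_alt_{s}_{e}"] = genome.hap2[scf][s2:e2]
    artifact = AssemblyRendering(art_seqs, "artifact", truth.copy())
    return collapsed, artifact


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class ReadSet:
    """Paired-end reads with full truth placements.

    ``r1``/``r2`` are (n_pairs, read_length) uint8 matrices of the sequenced
    bases.  Truth arrays give, per pair, the source copy (scaffold +
    haplotype), fragment start, and which mate was reverse-complemented.
    Coordinates refer to the *physical* source haplotype (tandem duplications
    applied), matching haplotype-1/collapsed coordinates whenever the source
    haplotype carries no indels or duplications.
    """

    sex: str
    read_length: int
    r1: np.ndarray
    r2: np.ndarray
    scaffold: np.ndarray  # per pair, object dtype
    haplotype: np.ndarray  # per pair, 1 or 2
    r1_start: np.ndarray
    r2_start: np.ndarray
    r1_is_reverse: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.r1.shape[0]

    def reads_matrix(self) -> np.ndarray:
        """All reads stacked (R1 block then R2 block), as sequenced."""
        return np.vstack([self.r1, self.r2])

    def truth_placements(self) -> pd.DataFrame:
        n = self.n_pairs
        ids = np.array([f"sim{i:08d}" for i in range(n)])
        df1 = pd.DataFrame(
            {
                "read": ids,
                "mate": 1,
                "scaffold": self.scaffold,
                "haplotype": self.haplotype,
                "start": self.r1_start,
                "strand": np.where(self.r1_is_reverse, "-", "+"),
            }
        )
        df2 = pd.DataFrame(
            {
                "read": ids,
                "mate": 2,
                "scaffold": self.scaffold,
                "haplotype": self.haplotype,
                "start": self.r2_start,
                "strand": np.where(self.r1_is_reverse, "+", "-"),
            }
        )
        return pd.concat([df1, df2], ignore_index=True)

    def write_fastq(self, path1, path2, quality_char: str = "?") -> None:
        qual = quality_char * self.read_length
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for i in range(self.n_pairs):
                name = f"sim{i:08d}"
                f1.write(f"@{name}/1\n{to_str(self.r1[i])}\n+\n{qual}\n")
                f2.write(f"@{name}/2\n{to_str(self.r2[i])}\n+\n{qual}\n")


def expected_pair_count(coverage: float, represented_length: int, read_length: int) -> int:
    """Pairs needed so two-copy regions reach ``coverage`` on a collapsed assembly.

    Each haplotype copy is sampled at coverage/2, hence the factor 4
    (2 mates x 2 copies).
    """
    return int(round(coverage * represented_length / (4.0 * read_length)))


def simulate_reads(
    genome: DiploidGenome, sex: str, config: SimulationConfig
) -> ReadSet:
    """Simulate a sexed paired-end read set from the physical diploid genome.

    Fragments are drawn uniformly from the haplotype copies present in the
    individual: males carry a single (haplotype-1) copy of each X scaffold,
    females two copies of everything.  Substitution errors are applied at
    ``error_rate`` per base.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if config.insert_mean < config.read_length:
        raise ValueError("insert_mean must be >= read_length")
    rl = config.read_length
    rng = np.random.default_rng(config.seed + (1009 if sex == "female" else 2003))

    phys1 = genome.physical_haplotype(1)
    phys2 = genome.physical_haplotype(2)
    copies: list[tuple[str, int, np.ndarray]] = []
    for name in genome.scaffolds:
        copies.append((name, 1, phys1[name]))
        if not (sex == "male" and genome.sex_linkage.get(name) == "X"):
            copies.append((name, 2, phys2[name]))

    lengths = np.array([len(c[2]) for c in copies], dtype=np.int64)
    total = int(lengths.sum())
    n_pairs = expected_pair_count(config.coverage, total, rl)

    copy_idx = rng.choice(len(copies), size=n_pairs, p=lengths / total)

    r1 = np.empty((n_pairs, rl), dtype=np.uint8)
    r2 = np.empty((n_pairs, rl), dtype=np.uint8)
    scaffold = np.empty(n_pairs, dtype=object)
    haplotype = np.empty(n_pairs, dtype=np.int8)
    r1_start = np.empty(n_pairs, dtype=np.int64)
    r2_start = np.empty(n_pairs, dtype=np.int64)
    r1_rev = np.empty(n_pairs, dtype=bool)

    offs = np.arange(rl)
    for ci, (name, hap, seq) in enumerate(copies):
        sel = np.flatnonzero(copy_idx == ci)
        if sel.size == 0:
            continue
        L = len(seq)
        ins = np.rint(rng.normal(config.insert_mean, config.insert_sd, sel.size))
        ins = np.clip(ins, rl, L).astype(np.int64)
        start = np.floor(rng.random(sel.size) * (L - ins + 1)).astype(np.int64)
        flip = rng.random(sel.size) < 0.5

        fwd = seq[start[:, None] + offs]
        rev_start = start + ins - rl
        rev = revcomp_matrix(seq[rev_start[:, None] + offs])

        r1[sel] = np.where(flip[:, None], rev, fwd)
        r2[sel] = np.where(flip[:, None], fwd, rev)
        scaffold[sel] = name
        haplotype[sel] = hap
        r1_start[sel] = np.where(flip, rev_start, start)
        r2_start[sel] = np.where(flip, start, rev_start)
        r1_rev[sel] = flip

    if config.error_rate > 0:
        for mat in (r1, r2):
            n_bases = mat.size
            n_err = rng.binomial(n_bases, config.error_rate)
            if n_err:
                flat = rng.integers(0, n_bases, size=n_err)
                rows, cols = flat // rl, flat % rl
                code = encode2bit(mat[rows, cols])
                mat[rows, cols] = BASES[(code + rng.integers(1, 4, size=n_err)) % 4]

    return ReadSet(sex, rl, r1, r2, scaffold, haplotype, r1_start, r2_start, r1_rev)


def truth_depth(readset: ReadSet, scaffold_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base depth implied by the truth placements, haplotypes combined.

    Exact in collapsed-assembly coordinates when the source genome carries no
    indels or tandem duplications (haplotype coordinates then coincide).
    """
    rl = readset.read_length
    out = {name: np.zeros(L + 1, dtype=np.int64) for name, L in scaffold_lengths.items()}
    for starts in (readset.r1_start, readset.r2_start):
        for name in scaffold_lengths:
            sel = readset.scaffold == name
            s = starts[sel]
            np.add.at(out[name], s, 1)
            np.add.at(out[name], np.minimum(s + rl, scaffold_lengths[name]), -1)
    return {name: np.cumsum(d[:-1]) for name, d in out.items()}


# ---------------------------------------------------------------------------
# marker loci


def make_marker_loci(
    genome: DiploidGenome,
    n_genes: int,
    gene_length: int = 2000,
    seed: int = 0,
    scaffolds: list[str] | None = None,
    margin: int = 5000,
) -> list[tuple[str, int, int]]:
    """Place non-overlapping marker-gene intervals across scaffolds.

    Genes are distributed proportionally to scaffold length and jittered
    within regular slots so placements are random but can never overlap.
    """
    names = scaffolds if scaffolds is not None else genome.scaffolds
    rng = np.random.default_rng(seed)
    lengths = np.array([genome.scaffold_length(n) for n in names], dtype=float)
    alloc = np.floor(n_genes * lengths / lengths.sum()).astype(int)
    for i in np.argsort(-(n_genes * lengths / lengths.sum() - alloc)):
        if alloc.sum() >= n_genes:
            break
        alloc[i] += 1
    loci = []
    for name, n_i in zip(names, alloc):
        if n_i == 0:
            continue
        usable = genome.scaffold_length(name) - 2 * margin
        spacing = usable / n_i
        if spacing < gene_length + 10:
            raise ValueError(f"scaffold {name} too short for {n_i} genes")
        for j in range(n_i):
            jitter = int(rng.integers(0, int(spacing - gene_length)))
            start = margin + int(j * spacing) + jitter
            loci.append((name, start, start + gene_length))
    return sorted(loci)


# ---------------------------------------------------------------------------
# truth-table writers (plain-text interchange)


def write_bed(path, intervals: list[tuple[str, int, int]] | pd.DataFrame) -> None:
    if isinstance(intervals, pd.DataFrame):
        intervals = list(intervals[["scaffold", "start", "end"]].itertuples(index=False))
    with open(path, "w") as fh:
        for scf, start, end in intervals:
            fh.write(f"{scf}\t{start}\t{end}\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_truth_tables(genome: DiploidGenome, outdir) -> None:
    """TSV/BED truth tables: variants, phase blocks, duplication loci."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome.truth_variants.to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
    write_bed(outdir / "phase_blocks.bed", genome.phase_blocks)
    write_bed(outdir / "true_duplications.bed", list(genome.dup_loci))
    pd.DataFrame(
        {
            "scaffold": genome.scaffolds,
            "length": [genome.scaffold_length(n) for n in genome.scaffolds],
            "linkage": [genome.sex_linkage[n] for n in genome.scaffolds],
        }
    ).to_csv(outdir / "scaffolds.tsv", sep="\t", index=False)
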