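"""SNV calling from DP4 pileups, B-allele frequency, phase-block concordance.

In a diploid individual, heterozygous SNVs should show a B-allele frequency
(alternate-read fraction) near 0.5.  Plotting BAF along scaffolds against
phase blocks distinguishes three situations: phased heterozygous blocks
(SNVs at BAF ~0.5 inside blocks), heterozygous regions that remained
unphased (SNV runs outside any block), and scaffolds with very low SNV
density (inbred homozygous stretches — or hemizygous X scaffolds if the
sample is male).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .placement import PileupCounts

DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_ALT_FRACTION = 0.2
DEFAULT_DENSITY_THRESHOLD = 0.1  # SNVs per kb
UNPHASED_MIN_SNVS = 5
UNPHASED_MIN_SPAN = 10_000


@dataclass
class VariantCall:
    scaffold: str
    pos: int  # 0-based
    ref: str
    alt: str
    dp4: tuple[int, int, int, int]  # ref_fwd, ref_rev, alt_fwd, alt_rev

    @property
    def baf(self) -> float:
        return compute_baf(self)


def compute_baf(v: VariantCall) -> float:
    """Alternate-allele read fraction from the DP4 counts."""
    rf, rr, af, ar = v.dp4
    total = rf + rr + af + ar
    if total <= 0:
        raise ValueError("zero total DP4 depth")
    return (af + ar) / total


def call_snvs(
    pileup: PileupCounts,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_alt_fraction: float = DEFAULT_MIN_ALT_FRACTION,
) -> list[VariantCall]:
    """Threshold SNV caller over DP4 pileup counts.

    A site is emitted when total DP4 depth reaches ``min_depth`` and the
    alternate fraction reaches ``min_alt_fraction``.  Indel evidence is not
    represented in the pileup and is therefore ignored; the defaults keep
    false calls rare at 30x with percent-scale sequencing error.
    """
    if min_depth <= 0 or min_alt_fraction <= 0:
        raise ValueError("thresholds must be positive")
    out = []
    t = pileup.sites
    total = t["ref_fwd"] + t["ref_rev"] + t["alt_fwd"] + t["alt_rev"]
    altn = t["alt_fwd"] + t["alt_rev"]
    keep = (total >= min_depth) & (t["alt"] != "") & (altn / total.clip(lower=1) >= min_alt_fraction)
    for row in t[keep].itertuples(index=False):
        out.append(
            VariantCall(
                row.scaffold,
                int(row.pos),
                row.ref,
                row.alt,
                (int(row.ref_fwd), int(row.ref_rev), int(row.alt_fwd), int(row.alt_rev)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# phase-block concordance


@dataclass
class PhaseReport:
    per_scaffold: pd.DataFrame
    unphased_het_intervals: list[tuple[str, int, int, int]]  # scaffold, start, end, n_snvs


def phase_concordance(
    variants: list[VariantCall],
    phase_blocks: list[tuple[str, int, int]],
    scaffold_lengths: dict[str, int],
    density_threshold: float = DEFAULT_DENSITY_THRESHOLD,
    min_run_snvs: int = UNPHASED_MIN_SNVS,
    min_run_span: int = UNPHASED_MIN_SPAN,
) -> PhaseReport:
    """Profile SNV density and phased fraction per scaffold.

    Reports, per scaffold: SNV count, density per kb, phased bp, fraction of
    SNVs inside phase blocks, and a low-heterozygosity flag when density
    falls below ``density_threshold``.  Maximal runs of at least
    ``min_run_snvs`` consecutive outside-block SNVs spanning at least
    ``min_run_span`` bp are reported as heterozygous-but-unphased intervals.
    """
    blocks_by_scf: dict[str, list[tuple[int, int]]] = {}
    for scf, s, e in phase_blocks:
        if scf not in scaffold_lengths:
            raise ValueError(f"phase block on unknown scaffold {scf!r}")
        blocks_by_scf.setdefault(scf, []).append((s, e))
    for ivs in blocks_by_scf.values():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("phase blocks must be non-overlapping")

    vars_by_scf: dict[str, list[int]] = {}
    for v in variants:
        vars_by_scf.setdefault(v.scaffold, []).append(v.pos)

    rows = []
    runs: list[tuple[str, int, int, int]] = []
    for name, L in scaffold_lengths.items():
        pos = np.sort(np.array(vars_by_scf.get(name, []), dtype=np.int64))
        ivs = blocks_by_scf.get(name, [])
        phased_bp = int(sum(e - s for s, e in ivs))
        if pos.size and ivs:
            starts = np.array([s for s, _ in ivs])
            ends = np.array([e for _, e in ivs])
            j = np.searchsorted(starts, pos, side="right") - 1
            inside = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
        else:
            inside = np.zeros(pos.size, dtype=bool)
        density = pos.size / (L / 1000.0)
        rows.append(
            (
                name,
                int(pos.size),
                density,
                phased_bp,
                float(inside.mean()) if pos.size else 0.0,
                bool(density < density_threshold),
            )
        )
        # maximal runs of consecutive outside-block SNVs
        i = 0
        while i < pos.size:
            if inside[i]:
                i += 1
                continue
            j = i
            while j + 1 < pos.size and not inside[j + 1]:
                j += 1
            n = j - i + 1
            span = int(pos[j] - pos[i] + 1)
            if n >= min_run_snvs and span >= min_run_span:
                runs.append((name, int(pos[i]), int(pos[j]) + 1, n))
            i = j + 1

    per_scaffold = pd.DataFrame(
        rows,
        columns=[
            "scaffold",
            "n_snvs",
            "snv_density_per_kb",
            "phased_bp",
            "fraction_phased",
            "low_heterozygosity",
        ],
    )
    return PhaseReport(per_scaffold, runs)


# ---------------------------------------------------------------------------
# VCF I/O (DP4 as INFO, SNVs only)


def write_vcf(variants: list[VariantCall], scaffold_lengths: dict[str, int], path) -> None:
    """Write SNV calls as VCF with DP4 in INFO."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=DP4,Number=4,Type=Integer,Description="Strand-resolved ref fwd, ref rev, alt fwd, alt rev depths">')
    for name, L in scaffold_lengths.items():
        header.contigs.add(name, length=L)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (v.scaffold, v.pos)):
            rec = out.new_record(
                contig=v.scaffold,
                start=v.pos,
                stop=v.pos + 1,
                alleles=(v.ref, v.alt),
            )
            rec.info["DP4"] = v.dp4
            out.write(rec)


def read_vcf(path) -> list[VariantCall]:
    """Read SNV calls (with DP4 INFO) back from VCF."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if len(rec.ref) != 1 or any(len(a) != 1 for a in rec.alts or ()):
                continue
            dp4 = tuple(int(x) for x in rec.info["DP4"])
            out.append(VariantCall(rec.contig, rec.start, rec.ref, rec.alts[0], dp4))
    return out
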