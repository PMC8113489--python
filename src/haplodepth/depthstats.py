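"""Duplication-artifact diagnostics on conserved marker (BUSCO) genes.

The central idea: if genes flagged "duplicated" by a BUSCO run on some other
assembly are *haplotype-induced duplication artifacts*, reads mapped to a
properly collapsed assembly show no depth difference between duplicated and
single-copy gene classes; if the genes are genuinely duplicated but were
erroneously collapsed, their mapped depth doubles.  The two hypotheses are
separated with a one-sided two-sample Kolmogorov–Smirnov test on per-gene
mean depth, with the duplicated class as the putatively greater sample, and
an X-vs-autosome comparison in a male sample serves as the positive control
for detecting two-fold copy-number shifts.

The one-sided statistic is D+ = sup_x [F_lesser(x) − F_greater(x)] and the
asymptotic p-value exp(−2·D+²·n1·n2/(n1+n2)), the form R's ``ks.test`` uses
for one-sided two-sample alternatives; a seeded permutation p-value is
available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .placement import DepthTrack

_STATUS_MAP = {
    "Complete": "single_copy",
    "Duplicated": "duplicated",
    "Fragmented": "fragmented",
    "Missing": "missing",
}


@dataclass
class MarkerGene:
    """A conserved gene with copy-number status and 0-based half-open placement(s)."""

    gene_id: str
    status: str  # single_copy | duplicated | fragmented | missing
    placements: list[tuple[str, int, int]] = field(default_factory=list)
    linkage: str = "unknown"  # autosome | X | unknown

    @property
    def scaffold(self):
        return self.placements[0][0] if self.placements else None

    @property
    def interval(self):
        return (self.placements[0][1], self.placements[0][2]) if self.placements else None


@dataclass
class KSResult:
    """One-sided two-sample Kolmogorov–Smirnov result."""

    d_plus: float
    p_value: float
    n1: int
    n2: int
    alternative: str = "greater sample stochastically larger"

    def to_dict(self) -> dict:
        return {
            "D_plus": self.d_plus,
            "p_value": self.p_value,
            "n1": self.n1,
            "n2": self.n2,
            "alternative": self.alternative,
        }


# ---------------------------------------------------------------------------
# BUSCO table


def parse_busco_table(path, linkage: dict[str, str] | None = None) -> list[MarkerGene]:
    """Parse a BUSCO "full table" TSV into marker genes.

    Rows with the same id (Duplicated) are merged into one gene carrying all
    placements.  1-based inclusive table coordinates become 0-based half-open.
    """
    genes: dict[str, MarkerGene] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise ValueError(f"malformed BUSCO row: {line!r}")
            gene_id, status = f[0], f[1]
            if status not in _STATUS_MAP:
                raise ValueError(f"unknown BUSCO status {status!r}")
            g = genes.get(gene_id)
            if g is None:
                g = genes[gene_id] = MarkerGene(gene_id, _STATUS_MAP[status])
            if status == "Duplicated":
                g.status = "duplicated"
            if status in ("Complete", "Duplicated", "Fragmented") and len(f) >= 5:
                scf, start, end = f[2], int(f[3]), int(f[4])
                g.placements.append((scf, start - 1, end))
                if linkage:
                    g.linkage = linkage.get(scf, "unknown")
    return list(genes.values())


def write_busco_table(genes: list[MarkerGene], path) -> None:
    """Emit marker genes in BUSCO full-table layout (1-based inclusive)."""
    rev = {v: k for k, v in _STATUS_MAP.items()}
    with open(path, "w") as fh:
        fh.write("# Busco id\tStatus\tSequence\tGene Start\tGene End\tScore\tLength\n")
        for g in genes:
            if not g.placements:
                fh.write(f"{g.gene_id}\t{rev[g.status]}\n")
                continue
            for scf, s, e in g.placements:
                fh.write(
                    f"{g.gene_id}\t{rev[g.status]}\t{scf}\t{s + 1}\t{e}\t0.0\t{e - s}\n"
                )


def marker_genes_from_truth(duplication_truth: pd.DataFrame,
                            linkage: dict[str, str] | None = None) -> list[MarkerGene]:
    """Marker genes from a simulator duplication-truth table.

    Any non-``single`` label becomes status ``duplicated`` — mirroring how a
    BUSCO run on the haplotype-inflated assembly would classify those genes.
    """
    genes = []
    for i, row in enumerate(duplication_truth.itertuples(index=False)):
        status = "single_copy" if row.label == "single" else "duplicated"
        genes.append(
            MarkerGene(
                f"busco{i:05d}",
                status,
                [(row.scaffold, int(row.start), int(row.end))],
                linkage.get(row.scaffold, "unknown") if linkage else "unknown",
            )
        )
    return genes


# ---------------------------------------------------------------------------
# per-gene depth


def mean_depth_per_gene(track: DepthTrack, genes: list[MarkerGene]) -> pd.DataFrame:
    """Mean depth across the complete genomic range of each gene.

    Every base of the interval counts, including zero-depth bases.  Genes with
    several placements use the first placement present in the assembly under
    test; genes with no such placement are skipped.
    """
    rows = []
    for g in genes:
        placement = next(
            ((scf, s, e) for scf, s, e in g.placements if scf in track.depths), None
        )
        if placement is None:
            continue
        scf, s, e = placement
        if e <= s:
            raise ValueError(f"zero-length interval for {g.gene_id}")
        if not 0 <= s < e <= track.depths[scf].size:
            raise ValueError(f"gene {g.gene_id} outside scaffold {scf}")
        rows.append((g.gene_id, g.status, g.linkage, scf, s, e,
                     float(track.depths[scf][s:e].mean())))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "status", "linkage", "scaffold", "start", "end", "mean_depth"],
    )


# ---------------------------------------------------------------------------
# one-sided KS


def ks_one_sided(greater_sample, lesser_sample) -> KSResult:
    """One-sided KS test that ``greater_sample`` is stochastically larger.

    D+ is the supremum of ECDF_lesser − ECDF_greater over the pooled sample
    points; the p-value is the asymptotic exp(−2·D+²·n1·n2/(n1+n2)), clamped
    to (0, 1].
    """
    g = np.sort(np.asarray(greater_sample, dtype=float))
    l = np.sort(np.asarray(lesser_sample, dtype=float))
    n1, n2 = g.size, l.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([g, l])
    ecdf_g = np.searchsorted(g, pooled, side="right") / n1
    ecdf_l = np.searchsorted(l, pooled, side="right") / n2
    d_plus = float(max(np.max(ecdf_l - ecdf_g), 0.0))
    p = math.exp(-2.0 * d_plus * d_plus * n1 * n2 / (n1 + n2))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return KSResult(d_plus, p, n1, n2)


def ks_permutation_pvalue(
    greater_sample, lesser_sample, n_permutations: int = 1000, seed: int = 0
) -> float:
    """Permutation alternative to the asymptotic one-sided p-value."""
    g = np.asarray(greater_sample, dtype=float)
    l = np.asarray(lesser_sample, dtype=float)
    obs = ks_one_sided(g, l).d_plus
    pooled = np.concatenate([g, l])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if ks_one_sided(perm[: g.size], perm[g.size :]).d_plus >= obs:
            hits += 1
    return (1 + hits) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# the duplication-artifact test and its positive control


def duplication_artifact_test(
    track: DepthTrack,
    genes: list[MarkerGene],
    alpha: float = 0.05,
    bin_width: float | None = None,
) -> dict:
    """Compare mapped depth of duplicated vs single-copy marker genes.

    Returns a report with per-class depth samples, medians, histogram bin
    counts and the one-sided KS result (duplicated as the putatively greater
    sample).  If either class is empty the report carries an ``untestable``
    flag and no p-value.
    """
    table = mean_depth_per_gene(track, genes)
    single = table.loc[table["status"] == "single_copy", "mean_depth"].to_numpy()
    dup = table.loc[table["status"] == "duplicated", "mean_depth"].to_numpy()

    report: dict = {
        "n_single": int(single.size),
        "n_duplicated": int(dup.size),
        "alpha": alpha,
        "filters": {"min_mapq": track.min_mapq, "masked": track.masked},
        "per_gene": table,
    }
    if single.size == 0 or dup.size == 0:
        report["untestable"] = True
        return report
    report["untestable"] = False
    report["median_single"] = float(np.median(single))
    report["median_duplicated"] = float(np.median(dup))
    report["median_ratio"] = (
        float(np.median(dup) / np.median(single)) if np.median(single) > 0 else float("nan")
    )
    ks = ks_one_sided(dup, single)
    report["ks"] = ks
    report["reject"] = bool(ks.p_value < alpha)

    if bin_width is None:
        bin_width = max(report["median_single"] / 10.0, 1e-9)
    top = max(single.max(), dup.max())
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    report["histogram"] = {
        "bin_edges": edges.tolist(),
        "single": np.histogram(single, bins=edges)[0].tolist(),
        "duplicated": np.histogram(dup, bins=edges)[0].tolist(),
    }
    return report


def x_autosome_control(
    track: DepthTrack, genes: list[MarkerGene], sex: str
) -> KSResult:
    """Positive control: autosomal vs X-linked marker-gene depth.

    The alternative is autosomal depth greater — true in a male (hemizygous
    X at half depth), false in a female.
    """
    labelled = [g for g in genes if g.linkage in ("autosome", "X")]
    if len(labelled) < len(genes):
        missing = len(genes) - len(labelled)
        raise ValueError(f"{missing} genes lack linkage labels")
    table = mean_depth_per_gene(track, labelled)
    aut = table.loc[table["linkage"] == "autosome", "mean_depth"].to_numpy()
    x = table.loc[table["linkage"] == "X", "mean_depth"].to_numpy()
    if aut.size == 0 or x.size == 0:
        raise ValueError("both autosomal and X-linked genes are required")
    return ks_one_sided(aut, x)
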