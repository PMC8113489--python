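"""End-to-end scenario runners on the bundled simulator.

Each function builds a genome, renders assemblies, simulates sexed reads,
places them with the exact-seed placer, and runs one diagnostic — the same
path a user would follow on real data, with every stochastic step derived
from a single scenario seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .baf import call_snvs, compute_baf
from .config import SimulationConfig
from .depthstats import (
    duplication_artifact_test,
    marker_genes_from_truth,
    x_autosome_control,
)
from .placement import depth_track, pileup_counts, place_reads
from .sexscan import classify_scaffolds, scaffold_ratio
from .simulate import (
    apply_true_duplication,
    make_marker_loci,
    render_assemblies,
    simulate_genome,
    simulate_reads,
)

# fixed offsets decorrelate the per-stage random streams within a scenario
_LOCI_SEED, _DUP_SEED, _PLACE_SEED = 13, 31, 29


def _collapsed_pipeline(config: SimulationConfig, genome, sex: str, min_mapq: int,
                        marker_loci, mask=None):
    collapsed, artifact = render_assemblies(genome, marker_loci, config)
    reads = simulate_reads(genome, sex, config)
    aln = place_reads(
        reads, collapsed, seed=config.seed + _PLACE_SEED, error_rate=config.error_rate
    )
    track = depth_track(aln, min_mapq=min_mapq, mask=mask)
    return collapsed, artifact, reads, aln, track


def artifact_null_scenario(
    config: SimulationConfig | None = None,
    n_genes: int = 100,
    gene_length: int = 2000,
    seed: int = 0,
    min_mapq: int = 1,
) -> dict:
    """Haplotype-artifact scenario: labelled duplications, collapsed mapping.

    A fraction of marker genes is labelled "duplicated" because the artifact
    rendering carries both haplotypes of those loci — but reads are mapped to
    the properly collapsed rendering, so no depth difference is expected and
    the one-sided KS test should not reject.
    """
    if config is None:
        config = SimulationConfig(n_x_scaffolds=0, error_rate=0.0)
    config = replace(config, seed=seed)
    genome = simulate_genome(config)
    loci = make_marker_loci(genome, n_genes, gene_length, seed=config.seed + _LOCI_SEED)
    collapsed, artifact, reads, aln, track = _collapsed_pipeline(
        config, genome, "female", min_mapq, loci
    )
    genes = marker_genes_from_truth(collapsed.duplication_truth, genome.sex_linkage)
    report = duplication_artifact_test(track, genes)
    # companion report on all mapped reads (no MAPQ filter), as the test is
    # usually shown for both filter settings side by side
    track_all = depth_track(aln, min_mapq=0)
    report_all = duplication_artifact_test(track_all, genes)
    return {
        "config": config,
        "genome": genome,
        "collapsed": collapsed,
        "artifact": artifact,
        "reads": reads,
        "alignments": aln,
        "track": track,
        "genes": genes,
        "report": report,
        "report_all_reads": report_all,
    }


def true_duplication_scenario(
    config: SimulationConfig | None = None,
    n_genes: int = 100,
    dup_fraction: float = 0.3,
    gene_length: int = 2000,
    seed: int = 0,
    min_mapq: int = 1,
) -> dict:
    """Genuine tandem duplications erroneously collapsed in the assembly.

    The duplicated gene class should show ~2x the single-copy depth and the
    one-sided KS test should reject.
    """
    if config is None:
        config = SimulationConfig(n_x_scaffolds=0, error_rate=0.0, artifact_fraction=0.0)
    config = replace(config, seed=seed, artifact_fraction=0.0)
    genome = simulate_genome(config)
    loci = make_marker_loci(genome, n_genes, gene_length, seed=config.seed + _LOCI_SEED)
    rng = np.random.default_rng(config.seed + _DUP_SEED)
    n_dup = int(round(dup_fraction * len(loci)))
    chosen = rng.choice(len(loci), size=n_dup, replace=False)
    genome = apply_true_duplication(genome, [loci[i] for i in sorted(chosen)])
    collapsed, artifact, reads, aln, track = _collapsed_pipeline(
        config, genome, "female", min_mapq, loci
    )
    genes = marker_genes_from_truth(collapsed.duplication_truth, genome.sex_linkage)
    report = duplication_artifact_test(track, genes)
    return {
        "config": config,
        "genome": genome,
        "collapsed": collapsed,
        "track": track,
        "genes": genes,
        "report": report,
    }


def x_autosome_scenario(
    sex: str,
    config: SimulationConfig | None = None,
    n_autosomal_genes: int = 40,
    n_x_genes: int = 20,
    gene_length: int = 2000,
    seed: int = 0,
    min_mapq: int = 1,
) -> dict:
    """Positive control: autosome-vs-X marker depth in a sexed sample."""
    if config is None:
        config = SimulationConfig(error_rate=0.0, artifact_fraction=0.0)
    config = replace(config, seed=seed, artifact_fraction=0.0)
    genome = simulate_genome(config)
    autosomes = [n for n in genome.scaffolds if genome.sex_linkage[n] == "autosome"]
    x_scf = [n for n in genome.scaffolds if genome.sex_linkage[n] == "X"]
    loci = make_marker_loci(
        genome, n_autosomal_genes, gene_length, seed=config.seed + _LOCI_SEED,
        scaffolds=autosomes,
    ) + make_marker_loci(
        genome, n_x_genes, gene_length, seed=config.seed + _LOCI_SEED + 1,
        scaffolds=x_scf,
    )
    collapsed, artifact, reads, aln, track = _collapsed_pipeline(
        config, genome, sex, min_mapq, sorted(loci)
    )
    genes = marker_genes_from_truth(collapsed.duplication_truth, genome.sex_linkage)
    ks = x_autosome_control(track, genes, sex)
    return {"config": config, "genome": genome, "track": track, "genes": genes, "ks": ks}


def sex_scan_scenario(
    config: SimulationConfig | None = None,
    window: int | None = None,
    seed: int = 0,
    min_mapq: int = 1,
) -> dict:
    """Male + female read sets on one assembly, windowed depth-ratio calls."""
    if config is None:
        config = SimulationConfig(error_rate=0.0, artifact_fraction=0.0)
    config = replace(config, seed=seed, artifact_fraction=0.0)
    if window is None:
        window = max(config.scaffold_length // 10, 1)
    genome = simulate_genome(config)
    collapsed, _ = render_assemblies(genome, [], config)
    tracks = {}
    for sex in ("male", "female"):
        reads = simulate_reads(genome, sex, config)
        aln = place_reads(
            reads, collapsed, seed=config.seed + _PLACE_SEED,
            error_rate=config.error_rate,
        )
        tracks[sex] = depth_track(aln, min_mapq=min_mapq)
    ratios = classify_scaffolds(scaffold_ratio(tracks["male"], tracks["female"], window))
    return {
        "config": config,
        "genome": genome,
        "tracks": tracks,
        "ratios": ratios,
    }


def baf_scenario(
    config: SimulationConfig | None = None,
    seed: int = 0,
    min_mapq: int = 1,
    min_depth: int = 10,
    min_alt_fraction: float = 0.2,
) -> dict:
    """Female diploid sample: SNV calls, BAF at truth heterozygous sites."""
    if config is None:
        config = SimulationConfig(n_x_scaffolds=0, error_rate=0.0, artifact_fraction=0.0)
    config = replace(config, seed=seed, artifact_fraction=0.0)
    genome = simulate_genome(config)
    collapsed, _ = render_assemblies(genome, [], config)
    reads = simulate_reads(genome, "female", config)
    aln = place_reads(
        reads, collapsed, seed=config.seed + _PLACE_SEED, error_rate=config.error_rate
    )
    pileup = pileup_counts(aln, collapsed.sequences, min_mapq=min_mapq)
    calls = call_snvs(pileup, min_depth=min_depth, min_alt_fraction=min_alt_fraction)

    truth = genome.truth_variants
    truth_snvs = truth[truth["type"] == "SNV"]
    truth_keys = set(zip(truth_snvs["scaffold"], truth_snvs["pos"]))
    at_truth = [v for v in calls if (v.scaffold, v.pos) in truth_keys]
    mean_baf = float(np.mean([compute_baf(v) for v in at_truth])) if at_truth else float("nan")
    return {
        "config": config,
        "genome": genome,
        "pileup": pileup,
        "calls": calls,
        "calls_at_truth_het": at_truth,
        "n_truth_snvs": int(len(truth_snvs)),
        "recall": len(at_truth) / max(len(truth_snvs), 1),
        "false_calls": len(calls) - len(at_truth),
        "mean_baf": mean_baf,
    }
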