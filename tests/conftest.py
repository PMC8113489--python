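import numpy as np
import pytest

from haplodepth import SimulationConfig
from haplodepth.simulate import diverge_haplotypes, simulate_genome


@pytest.fixture(scope="session")
def small_config():
    """Two 30-kb autosomes, error-free reads: fast end-to-end fixture."""
    return SimulationConfig(
        n_autosomes=2,
        n_x_scaffolds=0,
        scaffold_length=30_000,
        indel_rate=0.0,
        error_rate=0.0,
        homozygous_block_fraction=0.0,
        artifact_fraction=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


def brute_force_depth(placements, lengths, read_length):
    """Interval-stabbing oracle: count reads covering each base."""
    out = {n: np.zeros(L, dtype=int) for n, L in lengths.items()}
    for scf, pos in placements:
        for b in range(pos, min(pos + read_length, lengths[scf])):
            out[scf][b] += 1
    return out


def brute_force_dplus(greater, lesser):
    """ECDF-sup oracle for the one-sided KS statistic."""
    pts = sorted(set(list(greater) + list(lesser)))
    best = 0.0
    for x in pts:
        fg = sum(1 for v in greater if v <= x) / len(greater)
        fl = sum(1 for v in lesser if v <= x) / len(lesser)
        best = max(best, fl - fg)
    return best
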