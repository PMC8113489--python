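"""Simulation configuration for the bundled diploid genome simulator."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class SimulationConfig:
    """Parameters of a simulated diploid individual and its sequencing run.

    The defaults describe the study conditions the analysis is designed for:
    a beetle-like genome at ~32% GC, heterozygosity below 0.4% dominated by
    SNVs with a minority of short indels, long homozygous stretches from
    inbreeding, 150-bp paired-end reads at 30x collapsed-assembly depth.

    ``coverage`` is the expected mapped depth on the *collapsed* assembly in
    regions present in two copies; each haplotype copy is therefore sampled
    at ``coverage / 2``, which makes a hemizygous X scaffold in a male run at
    half the autosomal depth.
    """

    n_autosomes: int = 5
    n_x_scaffolds: int = 2
    scaffold_length: int = 1_000_000
    gc_content: float = 0.3221
    snv_rate: float = 0.004
    indel_rate: float = 0.0004
    max_indel: int = 10  # indel lengths drawn uniformly from 1..max_indel
    homozygous_block_fraction: float = 0.3
    phased_fraction: float = 0.8  # fraction of each heterozygous interval marked phased
    artifact_fraction: float = 0.3
    true_dup_fraction: float = 0.0
    coverage: float = 30.0
    read_length: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "snv_rate": self.snv_rate,
            "indel_rate": self.indel_rate,
            "homozygous_block_fraction": self.homozygous_block_fraction,
            "phased_fraction": self.phased_fraction,
            "artifact_fraction": self.artifact_fraction,
            "true_dup_fraction": self.true_dup_fraction,
            "error_rate": self.error_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError(f"gc_content must lie in (0, 1), got {self.gc_content}")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length < 31:
            raise ValueError("read_length must be >= 31")
        if self.insert_mean < self.read_length:
            raise ValueError("insert_mean must be >= read_length")
        if self.artifact_fraction + self.true_dup_fraction > 1.0:
            raise ValueError("artifact_fraction + true_dup_fraction must be <= 1")
        if self.n_autosomes < 0 or self.n_x_scaffolds < 0:
            raise ValueError("scaffold counts must be non-negative")
        if self.scaffold_length <= 0:
            raise ValueError("scaffold_length must be positive")
        if self.max_indel < 1:
            raise ValueError("max_indel must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
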