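"""Simulation configuration with field-naming validation errors."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from ..errors import ConfigurationError

_RATE_FIELDS = (
    "phenocopy_rate",
    "known_fraction",
    "on_array_fraction",
    "synonymous_fraction",
    "genotype_error_rate",
    "missing_rate",
    "disease_allele_freq",
)


@dataclass
class SimConfig:
    """Parameters for pedigree, gene-drop, variant, phenotype simulators.

    ``seed`` is mandatory for every stochastic operation; identical
    config + seed gives identical output.
    """

    seed: int = 0

    # pedigree
    n_founders: int = 20
    n_generations: int = 4
    generation_sizes: list[int] | int = 60
    linebreeding_founder: str | None = None  # default: first male founder
    linebreeding_weight: float = 5.0

    # marker map / gene drop
    n_chromosomes: int = 1
    chromosome_length_bp: int = 100_000_000
    markers_per_chromosome: int = 2_000
    cm_per_mb: float = 1.0  # uniform genetic map; no published map exists
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    disease_allele_freq: float = 0.13
    causal_chrom_index: int = 0
    causal_fraction_along: float = 0.5  # relative position of the causal locus

    # disease / cases
    n_cases: int = 46
    n_phenocopies: int = 5
    min_aa_attempts: int = 8  # whole-drop redraws to reach the required AA count

    # genotype error layer
    genotype_error_rate: float = 0.001  # symmetric per-allele miscall
    missing_rate: float = 0.01

    # variant-table background category counts (first-failing step each)
    n_outside_interval: int = 50
    n_fail_genotype: int = 30
    n_known: int = 10
    n_on_array: int = 5
    n_synonymous: int = 4
    known_fraction: float = 0.0   # reserved for rate-based generation
    on_array_fraction: float = 0.0
    synonymous_fraction: float = 0.0
    phenocopy_rate: float = 0.0

    # phenotypes
    trait_mean: float = 63.0
    trait_sd: float = 9.4
    effect_ag: float = 1.6
    effect_aa: float = 0.0
    heritability: float = 0.3
    nuisance_effects: bool = False  # optional additive herd-like layer, off by default
    n_nuisance_groups: int = 10
    nuisance_sd: float = 0.0

    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed: must be an integer")
        if self.n_founders < 2:
            raise ConfigurationError("n_founders: must be >= 2")
        if self.n_generations < 1:
            raise ConfigurationError("n_generations: must be >= 1")
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}: rate {v} outside [0, 1]")
        if not 0.0 <= self.heritability < 1.0:
            raise ConfigurationError("heritability: must be in [0, 1)")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("allele_freq_range: must satisfy 0 < lo <= hi < 1")
        if self.markers_per_chromosome < 2:
            raise ConfigurationError("markers_per_chromosome: must be >= 2")
        if self.n_phenocopies > self.n_cases:
            raise ConfigurationError("n_phenocopies: cannot exceed n_cases")
        if self.trait_sd <= 0:
            raise ConfigurationError("trait_sd: must be positive")
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes: must be >= 1")
        if not 0.0 < self.causal_fraction_along < 1.0:
            raise ConfigurationError("causal_fraction_along: must be in (0, 1)")

    def sizes(self) -> list[int]:
        """Per-generation offspring counts for generations 1..n_generations-1."""
        n_off = self.n_generations - 1
        if isinstance(self.generation_sizes, int):
            return [self.generation_sizes] * n_off
        sizes = list(self.generation_sizes)
        if len(sizes) != n_off:
            raise ConfigurationError(
                f"generation_sizes: expected {n_off} entries, got {len(sizes)}"
            )
        return sizes


@dataclass(frozen=True)
class GroupSpec:
    """Target mean/SD (measurement units) and size for one morphometry group."""

    name: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ConfigurationError(f"group {self.name}: mean must be positive")
        if self.sd <= 0:
            raise ConfigurationError(f"group {self.name}: sd must be positive")
        if self.n < 1:
            raise ConfigurationError(f"group {self.name}: n must be >= 1")
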