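"""Simulation configuration for a ZW-system cohort.

The generator emulates the situation in a bird with highly differentiated sex
chromosomes: a short terminal pseudoautosomal region (PAR) on the Z in which
females undergo one obligate crossover per meiosis (concentrated in a hotspot
near the PAR boundary), no female recombination elsewhere on the Z, male
recombination chromosome-wide, and female hemizygosity for the differentiated
part of the Z.  Defaults are chosen to match a collared-flycatcher-like study
design at reduced genome size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

ROLE_AUTOSOME = "autosome"
ROLE_PAR = "PAR"
ROLE_Z_DIFF = "Z_diff"
ROLES = (ROLE_AUTOSOME, ROLE_PAR, ROLE_Z_DIFF)


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class Scaffold:
    name: str
    length: int
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(f"scaffold role must be one of {ROLES}, got {self.role!r}")
        if self.length <= 0:
            raise ConfigError(f"scaffold {self.name}: length must be positive")


@dataclass(frozen=True)
class Hotspot:
    """Interval of elevated female crossover intensity, in Z-chromosome bp.

    ``fraction`` is the probability that the obligate female crossover falls
    inside the interval; the remainder is uniform over the rest of the PAR.
    """

    start: int
    end: int
    fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ConfigError("hotspot fraction must lie in [0, 1]")
        if self.end <= self.start or self.start < 0:
            raise ConfigError("hotspot interval must be non-empty and non-negative")


@dataclass(frozen=True)
class ExpressionPlan:
    """Tissue panel and per-role sex effects for the expression matrix.

    ``sex_effect`` maps a scaffold role to the multiplicative male:female
    expression ratio applied to genes on scaffolds of that role.  Defaults
    reproduce the avian pattern of incomplete dosage compensation: Z-linked
    genes male-biased (~1.4), PAR and autosomal genes balanced.
    """

    tissues: tuple[str, ...] = (
        "brain",
        "kidney",
        "liver",
        "lung",
        "muscle",
        "skin",
        "embryo",
        "testis",
        "ovary",
    )
    gonads: tuple[str, ...] = ("testis", "ovary")
    replicates_per_sex: int = 5
    mean_log2_expression: float = 5.0
    sd_log2_expression: float = 1.5
    noise_sd_log2: float = 0.25
    sex_effect: dict[str, float] = field(
        default_factory=lambda: {
            ROLE_AUTOSOME: 1.02,
            ROLE_PAR: 0.95,
            ROLE_Z_DIFF: 1.40,
        }
    )


def _default_genome_plan() -> tuple[Scaffold, ...]:
    # Three PAR scaffolds with the size structure of the flycatcher PAR
    # (436.0 + 182.2 + 2.3 kb) followed by a differentiated-Z scaffold, plus
    # two autosomal scaffolds for depth normalization; Z_diff and autosomes
    # are scaled down from whole-chromosome size to keep cohorts fast.
    return (
        Scaffold("auto_1", 2_000_000, ROLE_AUTOSOME),
        Scaffold("auto_2", 2_000_000, ROLE_AUTOSOME),
        Scaffold("par_1", 436_000, ROLE_PAR),
        Scaffold("par_2", 182_200, ROLE_PAR),
        Scaffold("par_3", 2_300, ROLE_PAR),
        Scaffold("zdiff_1", 3_000_000, ROLE_Z_DIFF),
    )


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the cohort generator.

    Rates and targets default to the study conditions this generator
    emulates: per-site noncoding diversity ~0.0034 in the PAR vs 0.0032 on
    the differentiated Z, fixed-difference density between sister species
    0.0001 vs 0.0011, LD decay parameter alpha 0.2/bp vs 0.005776/bp, sequencing
    depth 5x per individual with 10 males + 10 females per pool, and an
    obligate single female crossover of which ~80% fall in a ~150-kb hotspot
    adjacent to the PAR boundary.
    """

    seed: int = 0
    n_families: int = 10
    offspring_per_family: int = 8
    n_generations: int = 4
    genome_plan: tuple[Scaffold, ...] = field(default_factory=_default_genome_plan)
    hotspot: Hotspot | None = None  # None -> terminal 150 kb of PAR, fraction 0.8
    male_co_rate: float = 3.0  # cM/Mb, chromosome-wide Poisson crossovers
    marker_spacing: int = 50_000  # bp between array markers
    depth_mean: float = 5.0  # reads per base per (diploid) individual
    n_males: int = 10  # individuals per sequencing pool
    n_females: int = 10
    depth_model: str = "poisson"  # or "negative_binomial"
    depth_dispersion: float = 0.0  # NB shape: var = mu + dispersion * mu^2
    pi_target: dict[str, float] = field(
        default_factory=lambda: {ROLE_PAR: 0.0034, ROLE_Z_DIFF: 0.0032, ROLE_AUTOSOME: 0.0037}
    )
    df_target: dict[str, float] = field(
        default_factory=lambda: {ROLE_PAR: 0.0001, ROLE_Z_DIFF: 0.0011, ROLE_AUTOSOME: 0.0005}
    )
    alpha_ld: dict[str, float] = field(
        default_factory=lambda: {ROLE_PAR: 0.2, ROLE_Z_DIFF: 0.005776, ROLE_AUTOSOME: 0.005776}
    )
    n_haplotype_individuals: int = 10  # per species, per sex pool in the panel
    gc_target: dict[str, float] = field(
        default_factory=lambda: {ROLE_PAR: 0.492, ROLE_Z_DIFF: 0.399, ROLE_AUTOSOME: 0.410}
    )
    repeat_target: dict[str, float] = field(
        default_factory=lambda: {ROLE_PAR: 0.064, ROLE_Z_DIFF: 0.116, ROLE_AUTOSOME: 0.121}
    )
    genes_per_mb: dict[str, float] = field(
        default_factory=lambda: {ROLE_PAR: 34.9, ROLE_Z_DIFF: 10.0, ROLE_AUTOSOME: 20.0}
    )
    expression_plan: ExpressionPlan = field(default_factory=ExpressionPlan)

    # ---- derived geometry -------------------------------------------------

    def scaffolds(self, role: str | None = None) -> tuple[Scaffold, ...]:
        if role is None:
            return tuple(self.genome_plan)
        return tuple(s for s in self.genome_plan if s.role == role)

    @property
    def par_length(self) -> int:
        return sum(s.length for s in self.scaffolds(ROLE_PAR))

    @property
    def z_length(self) -> int:
        """Total Z length: PAR scaffolds followed by differentiated scaffolds."""
        return self.par_length + sum(s.length for s in self.scaffolds(ROLE_Z_DIFF))

    def z_scaffold_order(self) -> tuple[Scaffold, ...]:
        """Z scaffolds in chromosome order: PAR first (terminal PAR), then Z_diff."""
        return self.scaffolds(ROLE_PAR) + self.scaffolds(ROLE_Z_DIFF)

    def z_offsets(self) -> dict[str, int]:
        """Start offset (0-based) of each Z scaffold on the Z chromosome axis."""
        offsets: dict[str, int] = {}
        at = 0
        for s in self.z_scaffold_order():
            offsets[s.name] = at
            at += s.length
        return offsets

    def effective_hotspot(self) -> Hotspot:
        if self.hotspot is not None:
            return self.hotspot
        start = max(0, self.par_length - 150_000)
        return Hotspot(start, self.par_length, 0.8)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.offspring_per_family < 1:
            raise ConfigError("n_families and offspring_per_family must be >= 1")
        if self.n_generations < 2:
            raise ConfigError("a pedigree needs at least two generations")
        if self.scaffolds(ROLE_Z_DIFF) and not self.scaffolds(ROLE_PAR):
            raise ConfigError("a differentiated Z requires a PAR scaffold (terminal PAR model)")
        if self.par_length > self.z_length:
            raise ConfigError("PAR cannot exceed the Z chromosome")
        if self.male_co_rate < 0 or self.depth_mean <= 0 or self.marker_spacing <= 0:
            raise ConfigError("rates must be non-negative and depth/spacing positive")
        if self.depth_model not in ("poisson", "negative_binomial"):
            raise ConfigError(f"unknown depth model {self.depth_model!r}")
        if self.scaffolds(ROLE_PAR):
            hs = self.effective_hotspot()
            if hs.end > self.par_length:
                raise ConfigError("hotspot interval must lie inside the PAR")
        for name, by_role in (
            ("pi_target", self.pi_target),
            ("df_target", self.df_target),
            ("alpha_ld", self.alpha_ld),
        ):
            for role, value in by_role.items():
                if value < 0:
                    raise ConfigError(f"{name}[{role}] must be >= 0")
        if any(v > 1 for v in self.df_target.values()):
            raise ConfigError("df_target implies more than one difference per site")
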