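"""Domain types shared across the pipeline.

The pipeline studies two things in buckwheat (*Fagopyrum esculentum*), an
obligately outcrossing, heterostylous self-incompatible crop:

* the partition of the seed rutin phenotype of an F1 cross into a maternal
  and a pollen-parent (xenia) component, and
* the expression of pollen-parent alleles in maturing F1 seeds, measured
  from per-position nucleotide counts of a self-type cross and an outcross
  to a homozygous reference line.

Records are plain dataclasses; tabular operations convert them to pandas
frames at module boundaries.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

BASES = ("A", "C", "G", "T")

COMPATIBILITY_VALUES = ("SI", "SC")
FLOWER_TYPES = ("pin", "thrum", "long_homostyle", "mixed")
CROSS_TYPES = ("self_cross", "outcross")
ENZYME_FAMILIES = (
    "PAL", "C4H", "4CL", "CHS", "CHI", "F3H", "F3pH", "F3p5pH", "FLS", "GTR",
)

#: SNP classes at a variant position.  Pattern II sites are the
#: ratio-informative ones: the maternal line carries only non-reference
#: allele(s), so reference reads in the outcross are attributable to the
#: pollen parent.  Pattern I sites have a maternal ref/alt heterozygote
#: (reference reads are confounded).  Anything else is uninformative.
PATTERN_I = "I"
PATTERN_II = "II"
PATTERN_UNINFORMATIVE = "uninformative"
PATTERNS = (PATTERN_I, PATTERN_II, PATTERN_UNINFORMATIVE)

#: Rendered placeholder for absent values in report tables.
MISSING = "-"


class RutinseqError(Exception):
    """Base class for package errors."""


class TableFormatError(RutinseqError):
    """A tabular input violated the expected schema; names the offending row."""

    def __init__(self, message: str, row: int | None = None, path=None):
        self.row = row
        self.path = path
        loc = ""
        if path is not None:
            loc += f"{path}: "
        if row is not None:
            loc += f"row {row}: "
        super().__init__(loc + message)


class UndefinedEffectError(RutinseqError):
    """Maternal effect is undefined (equal parental means)."""


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (0.375 -> 0.38, -0.375 -> -0.38).

    Report tables use this convention; Python's builtin ``round`` is
    banker's rounding and would disagree on exact halves.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LineSpec:
    """A parental line: identity, breeding system and rutin distribution.

    ``rutin_mean``/``rutin_sd`` are per-seed rutin content parameters in
    mg/g.  SI lines are heterozygous (outcrossers) with broad SDs; SC lines
    are effectively homozygous with narrow SDs.
    """

    name: str
    compatibility: str  # "SI" | "SC"
    flower_type: str    # pin | thrum | long_homostyle | mixed
    rutin_mean: float
    rutin_sd: float

    def __post_init__(self):
        if not self.name:
            raise ValueError("line name must be non-empty")
        if self.compatibility not in COMPATIBILITY_VALUES:
            raise ValueError(f"compatibility must be one of {COMPATIBILITY_VALUES}")
        if self.flower_type not in FLOWER_TYPES:
            raise ValueError(f"flower_type must be one of {FLOWER_TYPES}")
        if self.rutin_mean < 0 or self.rutin_sd < 0:
            raise ValueError("rutin_mean and rutin_sd must be >= 0")


@dataclass(frozen=True)
class SeedRutinRecord:
    """Rutin content (mg/g) of one seed of one plant of one line or cross."""

    line: str
    plant_index: int
    seed_index: int
    rutin: float

    def __post_init__(self):
        if self.plant_index < 1 or self.seed_index < 1:
            raise ValueError("plant_index and seed_index are 1-based")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.line, self.plant_index, self.seed_index)


@dataclass(frozen=True)
class CrossSpec:
    """A cross: maternal line x pollen line, grown in a named plot.

    Crosses sharing a ``plot_group`` were grown and pollinated together, so
    their significance tests share one pooled error variance.
    """

    cross_id: str
    maternal: str
    pollen: str
    plot_group: str

    def __post_init__(self):
        if self.maternal == self.pollen:
            raise ValueError(f"cross {self.cross_id}: maternal == pollen")


@dataclass(frozen=True)
class LocusInfo:
    """A cDNA locus of the flavonoid pathway reference transcriptome."""

    locus_id: str
    enzyme_family: str
    length_bp: int
    cds_start: int | None = None  # 1-based, None when unknown

    def __post_init__(self):
        if self.enzyme_family not in ENZYME_FAMILIES:
            raise ValueError(f"unknown enzyme family {self.enzyme_family!r}")
        if self.length_bp <= 0:
            raise ValueError("length_bp must be > 0")
        if self.cds_start is not None and not 1 <= self.cds_start <= self.length_bp:
            raise ValueError("cds_start outside [1, length_bp]")


@dataclass(frozen=True)
class PileupColumn:
    """Per-position nucleotide counts for one sample at one cDNA position.

    ``sample_id`` names the maternal plant (replicate); the same sample_id
    appears once with ``cross_type='self_cross'`` and once with
    ``cross_type='outcross'``, which is how the two members of a comparison
    pair are matched.  Positions are 1-based on the transcript.
    """

    sample_id: str
    cross_type: str
    locus_id: str
    pos: int
    ref_base: str
    counts: Mapping[str, int]

    def __post_init__(self):
        if self.cross_type not in CROSS_TYPES:
            raise ValueError(f"cross_type must be one of {CROSS_TYPES}")
        if self.pos < 1:
            raise ValueError("pos is 1-based")
        if self.ref_base not in BASES:
            raise ValueError(f"ref_base must be one of {BASES}")
        if any(self.counts.get(b, 0) < 0 for b in BASES):
            raise ValueError("counts must be >= 0")

    @property
    def depth(self) -> int:
        return sum(self.counts.get(b, 0) for b in BASES)


@dataclass
class ExpressionRecord:
    """RSEM-style expression estimate for one locus in one sample.

    ``tpm`` is filled by :func:`rutinseq.ase.compute_tpm`.
    """

    sample_id: str
    locus_id: str
    est_count: float
    effective_length: float
    tpm: float | None = None

    def __post_init__(self):
        if self.est_count < 0:
            raise ValueError("est_count must be >= 0")
        if self.effective_length <= 0:
            raise ValueError("effective_length must be > 0")


@dataclass(frozen=True)
class VariantCall:
    """A classified SNP between the self-type cross and the outcross."""

    sample_id: str
    locus_id: str
    pos: int
    ref_base: str
    alleles_self: frozenset[str]
    alleles_out: frozenset[str]
    pattern: str
    pollen_ratio: float | None = None  # percent, pattern II only

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if (self.pattern == PATTERN_II) != (self.pollen_ratio is not None):
            raise ValueError("pollen_ratio present iff pattern II")
        if self.pollen_ratio is not None and not 0 <= self.pollen_ratio <= 100:
            raise ValueError("pollen_ratio is a percentage in [0, 100]")


@dataclass
class LocusAseSummary:
    """Per-locus, per-replicate allele-specific expression summary.

    ``mean_ratio`` is the arithmetic mean of pattern-II per-SNP
    pollen-allele ratios (percent); ``se_ratio`` its standard error, absent
    (None, rendered "-") when fewer than two pattern-II SNPs exist.
    """

    sample_id: str
    locus_id: str
    enzyme_family: str | None
    total_positions: int
    n_pattern_i: int
    n_pattern_ii: int
    mean_ratio: float | None
    se_ratio: float | None
    expressed: bool = True
    tpm: float | None = None

    def __post_init__(self):
        if (self.n_pattern_ii >= 1) != (self.mean_ratio is not None):
            raise ValueError("mean_ratio present iff n_pattern_ii >= 1")
        if (self.n_pattern_ii >= 2) != (self.se_ratio is not None):
            raise ValueError("se_ratio present iff n_pattern_ii >= 2")
        if self.mean_ratio is not None and not 0 <= self.mean_ratio <= 100:
            raise ValueError("mean_ratio is a percentage in [0, 100]")


@dataclass
class EffectResult:
    """Mid-parent value and maternal/pollen effect partition for one cross.

    ``m`` solves F1 = m*Pm + (1-m)*Pp for the group means and is reported
    unclamped (values outside [0, 1] are flagged, not truncated).
    ``stars_*`` follow the convention ***<0.001, **<0.01, *<0.05, otherwise
    the p-value itself printed at 2 dp.
    """

    cross_id: str
    pm_mean: float
    pp_mean: float
    f1_mean: float
    f1_sd: float
    mp: float
    m: float
    pollen_effect: float
    p_pm_vs_f1: float | None = None
    p_pp_vs_f1: float | None = None
    stars_pm: str | None = None
    stars_pp: str | None = None

    @property
    def outside_unit_interval(self) -> bool:
        return not 0.0 <= self.m <= 1.0


@dataclass(frozen=True)
class TruthSite:
    """Generator ground truth for one simulated variant site."""

    locus_id: str
    pos: int
    ref_base: str
    maternal_genotype: tuple[str, str]
    self_pollen_genotype: tuple[str, str]
    expected_pattern: str
    true_pi: float


@dataclass
class AseSimTruth:
    """Ground truth of a simulated allele-expression experiment."""

    sites: list[TruthSite]
    true_pi: float

    def by_position(self) -> dict[tuple[str, int], TruthSite]:
        return {(s.locus_id, s.pos): s for s in self.sites}


@dataclass
class PathwaySummary:
    """Per-enzyme-family locus counts for the rutin biosynthesis pathway.

    The glycosyltransferase (GTR) family is tallied but excluded from the
    expressed / pollen-allele totals (its single expressed locus appears in
    one plant only); the detected-in-reference total includes it.
    """

    per_family: dict[str, tuple[int, int, int]]  # family -> (detected, expressed, pollen)
    total_detected: int
    total_expressed: int
    total_pollen: int
    percent_expressed: float
    excluded_families: tuple[str, ...] = ("GTR",)


@dataclass
class RatioStats:
    """Summary of pollen-allele ratio averages across loci and replicates."""

    n_values: int
    min_ratio: float
    max_ratio: float
    band_lo: float
    band_hi: float
    band_count: int
    band_percent: float


@dataclass
class RunConfig:
    """Pipeline constants.

    Defaults encode the study conventions: trim 6 bases at each transcript
    end (unreliable base calls), call a locus expressed when TPM is strictly
    above 1.0, report at 2 decimals, band pollen-allele ratios over the
    inclusive [20, 40]% interval, and classify line rutin means as
    low (<0.1), medium (0.1-0.5) or high (>0.5 mg/g).
    """

    rng_seed: int = 0
    trim_bases: int = 6
    tpm_threshold: float = 1.0
    min_allele_count: int = 3
    min_allele_fraction: float = 0.10
    rounding_decimals: int = 2
    band_lo: float = 20.0
    band_hi: float = 40.0
    group_low: float = 0.1
    group_high: float = 0.5
    lsd_scope: str = "plot"  # "plot" | "cross"
    total_positions_mode: str = "post_trim"  # "post_trim" | "full_length"

    def __post_init__(self):
        if not 0 <= self.min_allele_fraction <= 1:
            raise ValueError("min_allele_fraction in [0, 1]")
        if self.trim_bases < 0:
            raise ValueError("trim_bases >= 0")
        if self.band_lo > self.band_hi:
            raise ValueError("band_lo <= band_hi required")
        if self.lsd_scope not in ("plot", "cross"):
            raise ValueError("lsd_scope must be 'plot' or 'cross'")
        if self.total_positions_mode not in ("post_trim", "full_length"):
            raise ValueError("total_positions_mode must be 'post_trim' or 'full_length'")

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))
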