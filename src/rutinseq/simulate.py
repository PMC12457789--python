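"""Synthetic data with known ground truth.

Two generators mirror the two halves of the study design:

* :func:`simulate_rutin` draws per-seed rutin measurements for parental
  lines (5 plants x 15 seeds each by default) and for F1 crosses whose mean
  follows the mixture F1 = m*Pm + (1-m)*Pp for a known maternal effect m.

* :func:`simulate_ase` draws per-position nucleotide-count pileups for the
  paired cross design: a self-incompatible, highly heterozygous maternal
  plant crossed once within its own line (self-type cross) and once to a
  homozygous line that is also the mapping reference (outcross).  Each read
  comes from the pollen allele with probability pi (the true
  pollen-expression fraction) and from one of the two maternal alleles
  otherwise; sequencing error flips a read base uniformly to another base
  with probability eps.  The returned truth lists every variant site with
  its genotypes and expected SNP pattern, enabling recovery tests.

All randomness flows through a single ``numpy`` Generator; identical seeds
give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import (
    BASES,
    PATTERN_I,
    PATTERN_II,
    PATTERN_UNINFORMATIVE,
    AseSimTruth,
    CrossSpec,
    LineSpec,
    LocusInfo,
    PileupColumn,
    SeedRutinRecord,
    TruthSite,
)

logger = logging.getLogger("rutinseq")

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class RutinSimSpec:
    """Design of a rutin-measurement simulation.

    Defaults reproduce the field design: five plants per row and fifteen
    seeds measured per plant (75 seeds per line or cross).  ``truncation``
    controls negative Normal draws: ``clip_resample`` redraws until the
    value is non-negative (a truncated Normal); ``none`` keeps them.
    ``plant_sd`` adds an optional plant-level random intercept (default 0:
    all seeds of a line i.i.d.).  ``f1_sd`` overrides the F1 seed SD; by
    default it is the mean of the two parental SDs.
    """

    lines: list[LineSpec]
    n_plants: int = 5
    n_seeds_per_plant: int = 15
    truncation: str = "clip_resample"
    plant_sd: float = 0.0
    f1_sd: float | None = None

    def __post_init__(self):
        if self.n_plants < 1 or self.n_seeds_per_plant < 1:
            raise ValueError("n_plants and n_seeds_per_plant must be >= 1")
        if self.truncation not in ("clip_resample", "none"):
            raise ValueError("truncation must be 'clip_resample' or 'none'")


@dataclass
class AseSimSpec:
    """Design of an allele-expression simulation.

    ``maternal_het_rate`` / ``maternal_hom_alt_rate`` / ``multiallelic_rate``
    are the per-position probabilities that the maternal plant is
    heterozygous ref/alt, homozygous for one non-reference allele, or
    heterozygous for two different non-reference alleles.  ``true_pollen_fraction``
    (pi) is the fraction of transcripts from the pollen allele,
    ``mean_depth`` the Poisson read depth per position and ``base_error``
    the per-read uniform miscall probability.

    An optional three-compartment mode mixes embryo, endosperm and testa
    contributions (endosperm maternal:paternal dosage 2:1, testa fully
    maternal); it is off by default, in which case pi is used directly as
    the aggregate mixing fraction.
    """

    loci: list[LocusInfo]
    sequences: dict[str, str]
    maternal_het_rate: float = 0.02
    maternal_hom_alt_rate: float = 0.01
    multiallelic_rate: float = 0.0
    true_pollen_fraction: float = 0.3
    mean_depth: float = 200.0
    base_error: float = 0.0
    rng_seed: int = 0
    sample_id: str = "plant-A"
    tissue_weights: tuple[float, float, float] | None = None  # embryo, endosperm, testa

    def __post_init__(self):
        for name in ("maternal_het_rate", "maternal_hom_alt_rate",
                     "multiallelic_rate", "true_pollen_fraction", "base_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.maternal_het_rate + self.maternal_hom_alt_rate + self.multiallelic_rate > 1:
            raise ValueError("genotype rates must sum to <= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not self.loci:
            raise ValueError("empty locus list")
        missing = [l.locus_id for l in self.loci if l.locus_id not in self.sequences]
        if missing:
            raise ValueError(f"sequences missing for loci {missing}")

    @property
    def effective_pi(self) -> float:
        """Aggregate paternal transcript fraction.

        With tissue weights (w_emb, w_end, w_testa), the embryo is diploid
        1:1, the endosperm triploid 2:1 maternal:paternal, and the testa
        fully maternal, each scaled by pi as the per-tissue paternal
        activity relative to the biparental expectation.
        """
        if self.tissue_weights is None:
            return self.true_pollen_fraction
        w = np.asarray(self.tissue_weights, dtype=float)
        if w.min() < 0 or w.sum() <= 0:
            raise ValueError("tissue weights must be non-negative, not all zero")
        w = w / w.sum()
        paternal_dose = np.array([0.5, 1.0 / 3.0, 0.0])
        # rescale so that pi = 0.5 reproduces a fully biparental embryo signal
        return float(2 * self.true_pollen_fraction * (w * paternal_dose).sum())


# ---------------------------------------------------------------------------
# rutin measurements


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float,
                    size: int, truncation: str) -> np.ndarray:
    values = rng.normal(mean, sd, size=size)
    if truncation == "clip_resample" and sd > 0:
        bad = values < 0
        while bad.any():
            values[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            bad = values < 0
        bias = values.mean() - mean
        logger.debug("truncation bias for mean=%.3g sd=%.3g: %.4g", mean, sd, bias)
    return values


def simulate_rutin(
    spec: RutinSimSpec,
    m_truth: dict[str, float] | None = None,
    crosses: list[CrossSpec] | None = None,
    seed: int | None = None,
) -> list[SeedRutinRecord]:
    """Draw per-seed rutin records for parental lines and (optionally) F1s.

    Parameters
    ----------
    spec
        Line distributions and sampling design.
    m_truth
        True maternal effect per cross_id; the F1 seed mean is
        ``m*Pm_mean + (1-m)*Pp_mean``.  Values outside [-0.5, 1.5] are
        rejected as implausible.
    crosses
        Crosses to simulate; both parents must appear in ``spec.lines``.
    seed
        RNG seed; the same seed reproduces the records exactly.
    """
    rng = np.random.default_rng(seed)
    by_name = {l.name: l for l in spec.lines}
    records: list[SeedRutinRecord] = []

    def emit(label: str, mean: float, sd: float):
        for plant in range(1, spec.n_plants + 1):
            shift = rng.normal(0.0, spec.plant_sd) if spec.plant_sd > 0 else 0.0
            values = _draw_truncated(rng, mean + shift, sd,
                                     spec.n_seeds_per_plant, spec.truncation)
            for s, v in enumerate(values, start=1):
                records.append(SeedRutinRecord(label, plant, s, float(v)))

    for line in spec.lines:
        emit(line.name, line.rutin_mean, line.rutin_sd)

    for cross in crosses or []:
        if cross.maternal not in by_name or cross.pollen not in by_name:
            raise ValueError(f"cross {cross.cross_id}: unknown parent line")
        if m_truth is None or cross.cross_id not in m_truth:
            raise ValueError(f"cross {cross.cross_id}: no true maternal effect given")
        m = m_truth[cross.cross_id]
        if not -0.5 <= m <= 1.5:
            raise ValueError(f"cross {cross.cross_id}: maternal effect {m} outside [-0.5, 1.5]")
        pm, pp = by_name[cross.maternal], by_name[cross.pollen]
        f1_mean = m * pm.rutin_mean + (1 - m) * pp.rutin_mean
        f1_sd = spec.f1_sd if spec.f1_sd is not None else 0.5 * (pm.rutin_sd + pp.rutin_sd)
        emit(cross.cross_id, f1_mean, f1_sd)

    logger.info("simulated %d seed rutin records (%d lines, %d crosses)",
                len(records), len(spec.lines), len(crosses or []))
    return records


# ---------------------------------------------------------------------------
# allele-expression pileups


def _pick_alt(rng: np.random.Generator, ref: str, exclude: set[str] = frozenset()) -> str:
    choices = [b for b in BASES if b != ref and b not in exclude]
    return choices[rng.integers(len(choices))]


def _expected_pattern(maternal: tuple[str, str], pollen_self: tuple[str, str],
                      ref: str, pi: float) -> str:
    """Pattern the classifier should assign, from the true allele pools.

    The self-cross sample can show the maternal alleles plus (when pi > 0)
    the self-pollen alleles; the outcross shows the maternal alleles plus
    (when pi > 0) the reference pollen allele.
    """
    self_pool = set(maternal) | (set(pollen_self) if pi > 0 else set())
    out_pool = set(maternal) | ({ref} if pi > 0 else set())
    if ref in self_pool:
        return PATTERN_I
    if ref in out_pool:
        return PATTERN_II
    return PATTERN_UNINFORMATIVE


def simulate_ase(spec: AseSimSpec, read_log: bool = False):
    """Simulate paired self-cross / outcross pileups with ground truth.

    Returns ``(pileups, truth)``, or ``(pileups, truth, log)`` when
    ``read_log`` is requested: ``log`` is then a list of per-read tuples
    ``(cross_type, locus_id, pos, origin, true_base, observed_base)``
    from which the pileup counts can be re-tallied independently.

    Per position the read depth is Poisson(mean_depth) in each sample; a
    read carries the pollen allele with probability pi (self-cross: one of
    the self-pollen plant's two alleles; outcross: the reference base) and
    otherwise one of the two maternal alleles, each with probability 1/2.
    A miscall replaces the base by one of the other three uniformly with
    probability base_error.
    """
    rng = np.random.default_rng(spec.rng_seed)
    pi = spec.effective_pi
    eps = spec.base_error

    pileups: list[PileupColumn] = []
    sites: list[TruthSite] = []
    log: list[tuple] = []

    for locus in spec.loci:
        seq = spec.sequences[locus.locus_id]
        length = min(locus.length_bp, len(seq))
        refs = np.array(list(seq[:length]))

        # genotype category per position: 0 ref/ref, 1 het, 2 hom-alt, 3 alt1/alt2
        u = rng.random(length)
        het = u < spec.maternal_het_rate
        hom = (~het) & (u < spec.maternal_het_rate + spec.maternal_hom_alt_rate)
        multi = (~het) & (~hom) & (
            u < spec.maternal_het_rate + spec.maternal_hom_alt_rate + spec.multiallelic_rate
        )

        maternal: list[tuple[str, str]] = []
        pollen_self: list[tuple[str, str]] = []
        for p in range(length):
            ref = refs[p]
            if ref not in _BASE_INDEX:  # N or masked base: treat as invariant
                maternal.append((ref, ref))
                pollen_self.append((ref, ref))
                continue
            if het[p]:
                alt = _pick_alt(rng, ref)
                maternal.append((ref, alt))
                # population frequency 0.5 for the segregating allele
                pollen_self.append((
                    ref if rng.random() < 0.5 else alt,
                    ref if rng.random() < 0.5 else alt,
                ))
            elif hom[p]:
                alt = _pick_alt(rng, ref)
                maternal.append((alt, alt))
                # the line is fixed for the alternative allele here
                pollen_self.append((alt, alt))
            elif multi[p]:
                alt1 = _pick_alt(rng, ref)
                alt2 = _pick_alt(rng, ref, exclude={alt1})
                maternal.append((alt1, alt2))
                pollen_self.append((
                    alt1 if rng.random() < 0.5 else alt2,
                    alt1 if rng.random() < 0.5 else alt2,
                ))
            else:
                maternal.append((ref, ref))
                pollen_self.append((ref, ref))

        for cross_type in ("self_cross", "outcross"):
            depths = rng.poisson(spec.mean_depth, size=length)
            for p in range(length):
                ref = refs[p]
                n = int(depths[p])
                counts = dict.fromkeys(BASES, 0)
                if ref not in _BASE_INDEX:
                    if n > 0:
                        # unresolvable reference base: emit no reads
                        n = 0
                elif n > 0:
                    m1, m2 = maternal[p]
                    if cross_type == "outcross":
                        p1 = p2 = ref
                    else:
                        p1, p2 = pollen_self[p]
                    probs = np.zeros(4)
                    for allele, w in ((m1, (1 - pi) / 2), (m2, (1 - pi) / 2),
                                      (p1, pi / 2), (p2, pi / 2)):
                        probs[_BASE_INDEX[allele]] += w
                    if eps > 0:
                        probs = probs * (1 - eps) + eps * (1 - probs) / 3
                    if read_log:
                        origins = rng.random(n) < pi
                        for from_pollen in origins:
                            if from_pollen:
                                true_base = p1 if rng.random() < 0.5 else p2
                                origin = "pollen"
                            else:
                                true_base = m1 if rng.random() < 0.5 else m2
                                origin = "maternal"
                            observed = true_base
                            if eps > 0 and rng.random() < eps:
                                observed = _pick_alt(rng, true_base)
                            counts[observed] += 1
                            log.append((cross_type, locus.locus_id, p + 1,
                                        origin, true_base, observed))
                    else:
                        drawn = rng.multinomial(n, probs)
                        for b, c in zip(BASES, drawn):
                            counts[b] = int(c)
                pileups.append(PileupColumn(
                    sample_id=spec.sample_id,
                    cross_type=cross_type,
                    locus_id=locus.locus_id,
                    pos=p + 1,
                    ref_base=ref if ref in _BASE_INDEX else "A",
                    counts=counts,
                ))

        for p in range(length):
            ref = refs[p]
            if ref not in _BASE_INDEX:
                continue
            non_ref = set(maternal[p]) | set(pollen_self[p]) != {ref}
            if non_ref:
                sites.append(TruthSite(
                    locus_id=locus.locus_id,
                    pos=p + 1,
                    ref_base=ref,
                    maternal_genotype=maternal[p],
                    self_pollen_genotype=pollen_self[p],
                    expected_pattern=_expected_pattern(maternal[p], pollen_self[p], ref, pi),
                    true_pi=pi,
                ))

    truth = AseSimTruth(sites=sites, true_pi=pi)
    logger.info("simulated %d pileup columns over %d loci (%d variant sites)",
                len(pileups), len(spec.loci), len(sites))
    if read_log:
        return pileups, truth, log
    return pileups, truth


def expression_from_pileups(pileups: list[PileupColumn],
                            loci: list[LocusInfo]):
    """Derive RSEM-style expression records from simulated pileups.

    The estimated count for a (sample, locus) is the total number of
    simulated reads over its positions and the effective length is the
    locus length; adequate for exercising TPM computation downstream.
    """
    from .types import ExpressionRecord

    lengths = {l.locus_id: l.length_bp for l in loci}
    totals: dict[tuple[str, str], int] = {}
    for col in pileups:
        key = (col.sample_id, col.locus_id)
        totals[key] = totals.get(key, 0) + col.depth
    return [
        ExpressionRecord(sample_id=s, locus_id=l, est_count=float(c),
                         effective_length=float(lengths.get(l, 1)))
        for (s, l), c in sorted(totals.items())
    ]


def random_sequences(locus_lengths: dict[str, int], seed: int = 0) -> dict[str, str]:
    """Uniform-random ACGT sequences for the given loci (test scaffolding)."""
    rng = np.random.default_rng(seed)
    return {
        name: "".join(rng.choice(list(BASES), size=n))
        for name, n in locus_lengths.items()
    }
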