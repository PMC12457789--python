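"""Pollen-parent allele expression from paired self-cross/outcross pileups.

The design: a heterozygous (self-incompatible) maternal plant is crossed
once within its own line (self-type cross) and once to a homozygous line
whose cDNA is also the mapping reference (outcross).  Any base present in
the self-cross sample can come from the maternal side; in the outcross,
reference bases at positions where the maternal plant carries only
non-reference alleles must come from the pollen parent.  That observation
drives the SNP taxonomy:

* **pattern II** (ratio-informative): the reference base is absent from the
  self-cross allele set and present in the outcross — the pollen-allele
  ratio is the reference-read fraction at that position;
* **pattern I**: the reference base is present in the self-cross sample
  (maternal ref/alt heterozygote) — the pollen contribution is confounded;
* anything else is uninformative.

Positions within the first and last ``trim_bases`` (default 6) of each
locus are discarded (unreliable base calls at transcript ends), and loci
are analysed only when expressed (TPM strictly above the threshold).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .pathway import ratio_stats as _ratio_stats
from .pathway import tabulate_pathway
from .types import (
    BASES,
    MISSING,
    PATTERN_I,
    PATTERN_II,
    PATTERN_UNINFORMATIVE,
    ExpressionRecord,
    LocusAseSummary,
    LocusInfo,
    PileupColumn,
    RunConfig,
    VariantCall,
    round_half_away,
)

logger = logging.getLogger("rutinseq")

__all__ = [
    "trim_ends", "compute_tpm", "expression_filter", "present_alleles",
    "detect_variants", "classify_pattern", "pollen_allele_ratio",
    "summarize_locus", "detect_pollen_allele", "annotate_amino_acid_change",
    "AlleleExpressionModel", "AlleleExpressionResults",
]


def trim_ends(columns: Sequence[PileupColumn], locus_length: int,
              trim_bases: int = 6) -> list[PileupColumn]:
    """Drop positions within ``trim_bases`` of either transcript end.

    Retains positions p with ``trim_bases < p <= locus_length - trim_bases``.
    A locus shorter than ``2*trim_bases + 1`` retains nothing (warned).
    """
    lo, hi = trim_bases, locus_length - trim_bases
    if hi <= lo:
        logger.warning("locus length %d <= 2*%d: no positions retained",
                       locus_length, trim_bases)
        return []
    return [c for c in columns if lo < c.pos <= hi]


def retained_length(locus_length: int, trim_bases: int = 6) -> int:
    return max(0, locus_length - 2 * trim_bases)


def compute_tpm(records: Sequence[ExpressionRecord]) -> list[ExpressionRecord]:
    """Fill TPM for one sample: tpm_i = 1e6 * (c_i/l_i) / sum_j (c_j/l_j).

    All-zero counts give all-zero TPM.  Records must belong to one sample.
    """
    samples = {r.sample_id for r in records}
    if len(samples) > 1:
        raise ValueError(f"compute_tpm expects one sample, got {sorted(samples)}")
    rates = np.array([r.est_count / r.effective_length for r in records])
    total = rates.sum()
    for r, rate in zip(records, rates):
        r.tpm = float(1e6 * rate / total) if total > 0 else 0.0
    return list(records)


def expression_filter(records: Iterable[ExpressionRecord],
                      tpm_threshold: float = 1.0) -> dict[tuple[str, str], bool]:
    """Expressed flag per (sample, locus): strictly TPM > threshold."""
    flags = {}
    for r in records:
        if r.tpm is None:
            raise ValueError(f"TPM not computed for {r.sample_id}/{r.locus_id}")
        flags[(r.sample_id, r.locus_id)] = r.tpm > tpm_threshold
    return flags


def present_alleles(column: PileupColumn, min_allele_count: int,
                    min_allele_fraction: float) -> frozenset[str]:
    """Bases considered really present in a pileup column.

    A base is present iff its count is at least ``min_allele_count`` and
    its fraction of the column depth at least ``min_allele_fraction``; the
    thresholds exist to suppress sequencing-error-level noise.
    """
    depth = column.depth
    if depth == 0:
        return frozenset()
    return frozenset(
        b for b in BASES
        if column.counts.get(b, 0) >= min_allele_count
        and column.counts.get(b, 0) / depth >= min_allele_fraction
    )


def classify_pattern(alleles_self: frozenset[str], alleles_out: frozenset[str],
                     ref: str) -> str:
    """Assign a variant position to pattern I, II or uninformative.

    See the module docstring; the rule is pluggable via
    :class:`AlleleExpressionModel`'s ``classifier`` argument.
    """
    if ref in alleles_self:
        return PATTERN_I
    if ref in alleles_out:
        return PATTERN_II
    return PATTERN_UNINFORMATIVE


def pollen_allele_ratio(out_column: PileupColumn, ref: str,
                        alleles_out: frozenset[str] | None = None) -> float:
    """Percent of outcross reads carrying the (pollen-parent) reference base.

    The denominator is the read count over the *present* alleles at the
    position (all four bases when no allele set is given).
    """
    alleles = alleles_out if alleles_out else frozenset(BASES)
    total = sum(out_column.counts.get(b, 0) for b in alleles)
    if total == 0:
        raise ValueError(f"zero usable depth at {out_column.locus_id}:{out_column.pos}")
    return 100.0 * out_column.counts.get(ref, 0) / total


def detect_variants(
    self_columns: Sequence[PileupColumn],
    out_columns: Sequence[PileupColumn],
    min_allele_count: int = 3,
    min_allele_fraction: float = 0.10,
    classifier=classify_pattern,
) -> list[VariantCall]:
    """Call and classify variant positions for one locus of one replicate.

    Positions are matched between the self-cross and outcross samples;
    a position is a variant when any present allele in either sample
    differs from the reference.  Positions with zero depth in both samples
    are skipped.  Trimming must already have been applied.
    """
    self_by_pos = {c.pos: c for c in self_columns}
    out_by_pos = {c.pos: c for c in out_columns}
    calls: list[VariantCall] = []
    for pos in sorted(set(self_by_pos) | set(out_by_pos)):
        sc, oc = self_by_pos.get(pos), out_by_pos.get(pos)
        ref = (oc or sc).ref_base
        if sc is not None and oc is not None and sc.ref_base != oc.ref_base:
            raise ValueError(f"reference base mismatch at {sc.locus_id}:{pos}")
        a_self = (present_alleles(sc, min_allele_count, min_allele_fraction)
                  if sc is not None else frozenset())
        a_out = (present_alleles(oc, min_allele_count, min_allele_fraction)
                 if oc is not None else frozenset())
        if not a_self and not a_out:
            logger.debug("position %s:%d has no usable depth; skipped",
                         (oc or sc).locus_id, pos)
            continue
        if (a_self | a_out) <= {ref}:
            continue  # all present alleles match the reference
        pattern = classifier(a_self, a_out, ref)
        ratio = None
        if pattern == PATTERN_II:
            ratio = pollen_allele_ratio(oc, ref, a_out)
        sample = (oc or sc).sample_id
        calls.append(VariantCall(
            sample_id=sample, locus_id=(oc or sc).locus_id, pos=pos,
            ref_base=ref, alleles_self=a_self, alleles_out=a_out,
            pattern=pattern, pollen_ratio=ratio,
        ))
    return calls


def summarize_locus(
    calls: Sequence[VariantCall],
    sample_id: str,
    locus: LocusInfo,
    total_positions: int,
    tpm: float | None = None,
    expressed: bool = True,
) -> LocusAseSummary:
    """Per-locus summary: SNP counts by pattern, mean +/- SE of the ratios.

    ``mean_ratio`` is the arithmetic mean of pattern-II per-SNP ratios;
    ``se_ratio`` the sample SD (n-1) over sqrt(n), defined only when at
    least two pattern-II SNPs exist (rendered "-" otherwise).
    """
    ratios = [c.pollen_ratio for c in calls if c.pattern == PATTERN_II]
    n_i = sum(1 for c in calls if c.pattern == PATTERN_I)
    n_ii = len(ratios)
    mean = float(np.mean(ratios)) if n_ii >= 1 else None
    se = float(np.std(ratios, ddof=1) / math.sqrt(n_ii)) if n_ii >= 2 else None
    return LocusAseSummary(
        sample_id=sample_id, locus_id=locus.locus_id,
        enzyme_family=locus.enzyme_family, total_positions=total_positions,
        n_pattern_i=n_i, n_pattern_ii=n_ii,
        mean_ratio=mean, se_ratio=se, expressed=expressed, tpm=tpm,
    )


def detect_pollen_allele(summaries: Iterable[LocusAseSummary]) -> dict[str, bool]:
    """Pollen-parent allele detected per locus.

    Detected iff any replicate observed at least one SNP of either pattern;
    pattern-I-only loci count as detected (the pollen allele is seen even
    though its ratio cannot be computed).
    """
    detected: dict[str, bool] = {}
    for s in summaries:
        hit = (s.n_pattern_i + s.n_pattern_ii) >= 1
        detected[s.locus_id] = detected.get(s.locus_id, False) or hit
    return detected


def annotate_amino_acid_change(sequence: str, cds_start: int, pos: int,
                               ref_base: str, alt_base: str) -> str:
    """Effect of a substitution on the encoded protein.

    Translates the affected codon (standard genetic code) before and after
    the substitution.  Positions upstream of ``cds_start`` or in an
    incomplete terminal codon are ``noncoding``.
    """
    if not 1 <= pos <= len(sequence):
        raise ValueError(f"pos {pos} outside sequence of length {len(sequence)}")
    if pos < cds_start:
        return "noncoding"
    offset = pos - cds_start
    codon_start = cds_start + 3 * (offset // 3)  # 1-based
    codon = sequence[codon_start - 1:codon_start + 2]
    if len(codon) < 3:
        logger.warning("incomplete terminal codon at %d; treated as noncoding",
                       codon_start)
        return "noncoding"
    i = pos - codon_start
    if codon[i] != ref_base:
        logger.warning("reference base %s does not match sequence %s at %d",
                       ref_base, codon[i], pos)
    mutated = codon[:i] + alt_base + codon[i + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


# ---------------------------------------------------------------------------
# model / results


class AlleleExpressionModel:
    """Pollen-allele expression estimated from paired cross pileups.

    Parameters
    ----------
    pileups
        Per-position counts; each ``sample_id`` (maternal plant replicate)
        must appear with both ``cross_type`` values, which is how the
        self-cross and outcross members of a pair are matched.
    loci
        Locus metadata (enzyme family, length, optional CDS frame).
    expression
        Optional expression estimates; when given, TPM is computed per
        sample and a locus is analysed only if expressed (TPM strictly
        above ``config.tpm_threshold``) in every sample of the pair.
        Without expression data all loci are analysed.
    config
        Thresholds (trimming, allele presence, TPM).
    classifier
        Pattern-assignment strategy; defaults to :func:`classify_pattern`.
    """

    def __init__(self, pileups, loci, expression=None, config=None,
                 classifier=classify_pattern):
        self.pileups = list(pileups)
        self.loci = list(loci)
        self.expression = list(expression) if expression else None
        self.config = config or RunConfig()
        self.classifier = classifier

    @classmethod
    def from_files(cls, pileup_path, loci_path=None, expression_path=None,
                   fasta_path=None, config=None):
        from . import io
        pileups = io.read_pileup_table(pileup_path)
        if loci_path:
            loci = io.read_loci_table(loci_path)
        elif fasta_path:
            loci = io.loci_from_fasta(io.read_fasta(fasta_path))
        else:
            raise ValueError("either loci_path or fasta_path is required")
        expression = (io.read_expression_table(expression_path)
                      if expression_path else None)
        return cls(pileups, loci, expression, config)

    def _tpm_flags(self):
        """(sample, locus) -> (tpm, expressed); None when no expression data."""
        if self.expression is None:
            return None
        by_sample: dict[str, list[ExpressionRecord]] = {}
        for r in self.expression:
            by_sample.setdefault(r.sample_id, []).append(r)
        for records in by_sample.values():
            compute_tpm(records)
        flags = expression_filter(
            [r for rs in by_sample.values() for r in rs],
            self.config.tpm_threshold,
        )
        tpms = {(r.sample_id, r.locus_id): r.tpm
                for rs in by_sample.values() for r in rs}
        return tpms, flags

    def fit(self) -> "AlleleExpressionResults":
        cfg = self.config
        lengths = {l.locus_id: l.length_bp for l in self.loci}
        by_locus = {l.locus_id: l for l in self.loci}
        tpm_info = self._tpm_flags()

        grouped: dict[tuple[str, str, str], list[PileupColumn]] = {}
        for col in self.pileups:
            if col.locus_id not in lengths:
                raise ValueError(f"pileup references unknown locus {col.locus_id!r}")
            grouped.setdefault((col.sample_id, col.locus_id, col.cross_type),
                               []).append(col)

        replicates = sorted({k[0] for k in grouped})
        calls: list[VariantCall] = []
        summaries: list[LocusAseSummary] = []
        for sample in replicates:
            exp_samples = self._expression_samples_for(sample)
            for locus_id in sorted({k[1] for k in grouped if k[0] == sample}):
                locus = by_locus[locus_id]
                tpm, expressed = None, True
                if tpm_info is not None:
                    tpms, flags = tpm_info
                    keys = [(s, locus_id) for s in exp_samples] or [(sample, locus_id)]
                    known = [k for k in keys if k in flags]
                    expressed = bool(known) and all(flags[k] for k in known)
                    tpm = float(np.mean([tpms[k] for k in known])) if known else None
                total = (retained_length(locus.length_bp, cfg.trim_bases)
                         if cfg.total_positions_mode == "post_trim"
                         else locus.length_bp)
                if not expressed:
                    summaries.append(LocusAseSummary(
                        sample_id=sample, locus_id=locus_id,
                        enzyme_family=locus.enzyme_family, total_positions=total,
                        n_pattern_i=0, n_pattern_ii=0, mean_ratio=None,
                        se_ratio=None, expressed=False, tpm=tpm,
                    ))
                    continue
                self_cols = trim_ends(
                    grouped.get((sample, locus_id, "self_cross"), []),
                    locus.length_bp, cfg.trim_bases)
                out_cols = trim_ends(
                    grouped.get((sample, locus_id, "outcross"), []),
                    locus.length_bp, cfg.trim_bases)
                locus_calls = detect_variants(
                    self_cols, out_cols, cfg.min_allele_count,
                    cfg.min_allele_fraction, self.classifier)
                calls.extend(locus_calls)
                summaries.append(summarize_locus(
                    locus_calls, sample, locus, total, tpm, expressed))
        logger.info("classified %d variant positions over %d locus summaries "
                    "(thresholds: count>=%d, fraction>=%.2f, trim=%d, TPM>%g)",
                    len(calls), len(summaries), cfg.min_allele_count,
                    cfg.min_allele_fraction, cfg.trim_bases, cfg.tpm_threshold)
        return AlleleExpressionResults(self, calls, summaries)

    def _expression_samples_for(self, sample: str) -> list[str]:
        if self.expression is None:
            return []
        exact = sorted({r.sample_id for r in self.expression
                        if r.sample_id == sample})
        if exact:
            return exact
        # allow expression sample ids suffixed by cross type (sample.self_cross)
        return sorted({r.sample_id for r in self.expression
                       if r.sample_id.startswith(sample)})


class AlleleExpressionResults:
    """Fitted ASE analysis: variant calls and per-locus summaries."""

    def __init__(self, model: AlleleExpressionModel,
                 variants: list[VariantCall],
                 locus_summaries: list[LocusAseSummary]):
        self.model = model
        self.variants = variants
        self.locus_summaries = locus_summaries

    # -- accessors ---------------------------------------------------------

    def variants_frame(self) -> pd.DataFrame:
        rows = [{
            "sample_id": v.sample_id, "locus_id": v.locus_id, "pos": v.pos,
            "ref_base": v.ref_base,
            "alleles_self": "".join(sorted(v.alleles_self)) or MISSING,
            "alleles_out": "".join(sorted(v.alleles_out)) or MISSING,
            "pattern": v.pattern,
            "pollen_ratio": v.pollen_ratio if v.pollen_ratio is not None else None,
        } for v in self.variants]
        return pd.DataFrame(rows, columns=[
            "sample_id", "locus_id", "pos", "ref_base", "alleles_self",
            "alleles_out", "pattern", "pollen_ratio"])

    def summary_frame(self) -> pd.DataFrame:
        rows = [{
            "sample_id": s.sample_id, "locus_id": s.locus_id,
            "enzyme_family": s.enzyme_family,
            "total_positions": s.total_positions,
            "n_pattern_I": s.n_pattern_i, "n_pattern_II": s.n_pattern_ii,
            "mean_ratio": s.mean_ratio, "se_ratio": s.se_ratio,
            "expressed": s.expressed, "tpm": s.tpm,
        } for s in self.locus_summaries]
        return pd.DataFrame(rows, columns=[
            "sample_id", "locus_id", "enzyme_family", "total_positions",
            "n_pattern_I", "n_pattern_II", "mean_ratio", "se_ratio",
            "expressed", "tpm"])

    def pollen_detected(self) -> dict[str, bool]:
        return detect_pollen_allele(
            s for s in self.locus_summaries if s.expressed)

    def pathway(self, excluded=("GTR",)):
        return tabulate_pathway(self.model.loci, self.locus_summaries, excluded)

    def ratio_stats(self, band_lo=None, band_hi=None):
        cfg = self.model.config
        return _ratio_stats(
            self.locus_summaries,
            cfg.band_lo if band_lo is None else band_lo,
            cfg.band_hi if band_hi is None else band_hi,
        )

    def pooled_ratio(self, locus_id: str, sample_id: str | None = None) -> float:
        """Depth-weighted pollen-allele ratio over a locus' pattern-II SNPs.

        Pools reference and total present-allele read counts across the
        pattern-II positions of the locus (optionally one replicate) in the
        outcross sample; this is the estimator whose sampling error shrinks
        as binomial in the total read count.
        """
        out_cols = {
            (c.sample_id, c.locus_id, c.pos): c
            for c in self.model.pileups if c.cross_type == "outcross"
        }
        ref_reads = total_reads = 0
        for v in self.variants:
            if v.locus_id != locus_id or v.pattern != PATTERN_II:
                continue
            if sample_id is not None and v.sample_id != sample_id:
                continue
            col = out_cols[(v.sample_id, v.locus_id, v.pos)]
            alleles = v.alleles_out or frozenset(BASES)
            total_reads += sum(col.counts.get(b, 0) for b in alleles)
            ref_reads += col.counts.get(v.ref_base, 0)
        if total_reads == 0:
            raise ValueError(f"no pattern-II reads for locus {locus_id}")
        return 100.0 * ref_reads / total_reads

    def write(self, out_dir) -> None:
        """Write variants.tsv and ase_summary.tsv (absent values as '-')."""
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nd = self.model.config.rounding_decimals
        vf = self.variants_frame()
        vf["pollen_ratio"] = vf["pollen_ratio"].map(
            lambda v: MISSING if pd.isna(v) else f"{round_half_away(v, nd):.{nd}f}")
        vf.to_csv(out / "variants.tsv", sep="\t", index=False)
        sf = self.summary_frame()
        for col in ("mean_ratio", "se_ratio", "tpm"):
            sf[col] = sf[col].map(
                lambda v: MISSING if v is None or pd.isna(v)
                else f"{round_half_away(v, nd):.{nd}f}")
        sf.to_csv(out / "ase_summary.tsv", sep="\t", index=False)

    def summary(self) -> str:
        """Report-style per-locus table (one block per replicate)."""
        nd = self.model.config.rounding_decimals
        lines = ["Pollen-parent allele expression by locus",
                 "=" * 78,
                 f"{'replicate':<12}{'locus':<22}{'family':<8}{'sites':>6}"
                 f"{'pat I':>6}{'pat II':>7}{'ratio%':>9}{'SE':>7}"]
        for s in self.locus_summaries:
            if not s.expressed:
                continue
            mean = MISSING if s.mean_ratio is None else f"{round_half_away(s.mean_ratio, 1):.1f}"
            se = MISSING if s.se_ratio is None else f"{round_half_away(s.se_ratio, nd):.{nd}f}"
            lines.append(
                f"{s.sample_id:<12}{s.locus_id:<22}{s.enzyme_family or MISSING:<8}"
                f"{s.total_positions:>6}{s.n_pattern_i:>6}{s.n_pattern_ii:>7}"
                f"{mean:>9}{se:>7}")
        lines.append("=" * 78)
        return "\n".join(lines)
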