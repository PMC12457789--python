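"""Pathway-level aggregation and report rendering.

Rolls per-locus results up to the ten enzyme families of the rutin
biosynthesis pathway (PAL, C4H, 4CL, CHS, CHI, F3H, F3'H, F3'5'H, FLS,
GTR), classifies line rutin means into low/medium/high groups, and
summarises the distribution of pollen-allele ratio averages across loci
and replicates.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import (
    ENZYME_FAMILIES,
    MISSING,
    LocusAseSummary,
    LocusInfo,
    PathwaySummary,
    RatioStats,
    RunConfig,
    round_half_away,
)

logger = logging.getLogger("rutinseq")

__all__ = [
    "classify_rutin_group", "tabulate_pathway", "pathway_from_counts",
    "ratio_stats", "render_report",
]


def classify_rutin_group(mean_rutin: float, low: float = 0.1,
                         high: float = 0.5) -> str:
    """Classify a line's mean rutin content (mg/g) into low/medium/high.

    Boundaries belong to "medium": low is strictly below ``low`` and high
    strictly above ``high``.
    """
    if mean_rutin < 0:
        raise ValueError(f"negative mean rutin {mean_rutin}")
    if mean_rutin < low:
        return "low"
    if mean_rutin > high:
        return "high"
    return "medium"


def _assemble(per_family: Mapping[str, tuple[int, int, int]],
              excluded: tuple[str, ...]) -> PathwaySummary:
    for fam, (d, e, p) in per_family.items():
        if fam not in ENZYME_FAMILIES:
            raise ValueError(f"unknown enzyme family {fam!r}")
        if not (p <= e <= d):
            raise ValueError(
                f"{fam}: need pollen ({p}) <= expressed ({e}) <= detected ({d})"
            )
    # the detected-in-reference total spans the whole pathway, while the
    # expressed / pollen totals exclude the flagged families (GTR's single
    # expressed locus appears in one plant only)
    total_detected = sum(d for d, _, _ in per_family.values())
    total_expressed = sum(e for f, (_, e, _) in per_family.items() if f not in excluded)
    total_pollen = sum(p for f, (_, _, p) in per_family.items() if f not in excluded)
    percent = 100.0 * total_expressed / total_detected if total_detected else 0.0
    return PathwaySummary(
        per_family=dict(per_family),
        total_detected=total_detected,
        total_expressed=total_expressed,
        total_pollen=total_pollen,
        percent_expressed=percent,
        excluded_families=excluded,
    )


def pathway_from_counts(counts: Mapping[str, tuple[int, int, int]],
                        excluded: tuple[str, ...] = ("GTR",)) -> PathwaySummary:
    """Build a pathway summary from per-family (detected, expressed, pollen) counts."""
    return _assemble(counts, excluded)


def tabulate_pathway(
    loci: Sequence[LocusInfo],
    summaries: Sequence[LocusAseSummary],
    excluded: tuple[str, ...] = ("GTR",),
) -> PathwaySummary:
    """Aggregate per-locus summaries into per-family counts.

    A locus counts as detected (it is in the reference set), as expressed
    when any replicate flags it expressed, and as pollen-allele-detected
    when any replicate observed at least one pattern-I or pattern-II SNP.
    """
    by_locus: dict[str, list[LocusAseSummary]] = {}
    for s in summaries:
        by_locus.setdefault(s.locus_id, []).append(s)

    counts: dict[str, list[int]] = {f: [0, 0, 0] for f in ENZYME_FAMILIES}
    for locus in loci:
        fam = locus.enzyme_family
        counts[fam][0] += 1
        reps = by_locus.get(locus.locus_id, [])
        expressed = any(s.expressed for s in reps)
        pollen = any(s.expressed and (s.n_pattern_i + s.n_pattern_ii) >= 1
                     for s in reps)
        if expressed:
            counts[fam][1] += 1
        if pollen:
            counts[fam][2] += 1
    per_family = {f: tuple(c) for f, c in counts.items() if c[0] > 0}
    return _assemble(per_family, excluded)


def ratio_stats(
    summaries: Iterable[LocusAseSummary] | Iterable[float],
    band_lo: float = 20.0,
    band_hi: float = 40.0,
) -> RatioStats:
    """Min / max / band statistics of pollen-allele ratio averages.

    Pools every available per-(locus, replicate) mean ratio; the band
    count uses the inclusive interval [band_lo, band_hi] percent.
    Accepts either summaries or raw percentage values.
    """
    values: list[float] = []
    for item in summaries:
        if isinstance(item, LocusAseSummary):
            if item.mean_ratio is not None:
                values.append(item.mean_ratio)
        else:
            values.append(float(item))
    if not values:
        raise ValueError("no pollen-allele ratios available")
    in_band = [v for v in values if band_lo <= v <= band_hi]
    return RatioStats(
        n_values=len(values),
        min_ratio=min(values),
        max_ratio=max(values),
        band_lo=band_lo,
        band_hi=band_hi,
        band_count=len(in_band),
        band_percent=100.0 * len(in_band) / len(values),
    )


def pathway_frame(summary: PathwaySummary) -> pd.DataFrame:
    rows = []
    for fam, (d, e, p) in summary.per_family.items():
        flag = fam in summary.excluded_families
        rows.append({
            "enzyme_family": fam, "detected_in_reference": d,
            "expressed": f"({e})" if flag else e,
            "pollen_allele_detected": f"({p})" if flag else p,
        })
    rows.append({
        "enzyme_family": "total", "detected_in_reference": summary.total_detected,
        "expressed": summary.total_expressed,
        "pollen_allele_detected": summary.total_pollen,
    })
    return pd.DataFrame(rows)


def render_report(
    effects_results=None,
    pathway_summary: PathwaySummary | None = None,
    stats: RatioStats | None = None,
    config: RunConfig | None = None,
    out_dir=".",
) -> Path:
    """Write the report tables (TSV) and a markdown overview.

    Emits ``effects.tsv`` (per-cross effect partition, rounded per config,
    absent values as "-"), ``pathway.tsv`` (per-family counts with the
    excluded-family values in parentheses) and ``report.md``.  Sections
    without data say so explicitly.  Returns the report path.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nd = config.rounding_decimals
    md = ["# Pipeline report", ""]

    if effects_results is not None and effects_results.effects:
        df = effects_results.to_frame(rounded=True)
        for col in ("mp", "f1_mean", "f1_sd", "maternal_effect", "pollen_effect"):
            df[col] = df[col].map(lambda v: f"{v:.{nd}f}")
        df.to_csv(out / "effects.tsv", sep="\t", index=False)
        md += ["## Parental effects", "", effects_results.summary(), ""]
    else:
        md += ["## Parental effects", "", "no data", ""]

    if pathway_summary is not None:
        pf = pathway_frame(pathway_summary)
        pf.to_csv(out / "pathway.tsv", sep="\t", index=False)
        md += [
            "## Pathway aggregation", "",
            f"loci detected in reference: {pathway_summary.total_detected}",
            f"expressed (excl. {'/'.join(pathway_summary.excluded_families)}): "
            f"{pathway_summary.total_expressed} "
            f"({round_half_away(pathway_summary.percent_expressed, 0):.0f}%)",
            f"pollen-parent alleles detected: {pathway_summary.total_pollen}", "",
        ]
    else:
        md += ["## Pathway aggregation", "", "no data", ""]

    if stats is not None:
        md += [
            "## Pollen-allele ratio distribution", "",
            f"n = {stats.n_values} locus x replicate averages",
            f"range: {round_half_away(stats.min_ratio, 1)}% - "
            f"{round_half_away(stats.max_ratio, 1)}%",
            f"within [{stats.band_lo:g}, {stats.band_hi:g}]%: "
            f"{stats.band_count}/{stats.n_values} "
            f"({round_half_away(stats.band_percent, 0):.0f}%)", "",
        ]
    else:
        md += ["## Pollen-allele ratio distribution", "", "no data", ""]

    report_path = out / "report.md"
    report_path.write_text("\n".join(md))
    logger.info("report written to %s", report_path)
    return report_path
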