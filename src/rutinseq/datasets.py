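"""Published summary data of the buckwheat xenia / allele-expression study.

These are the printed group-level statistics of the source experiment:
per-line seed rutin means and SDs for the seven parental lines, the F1
seed means and effect partitions of the ten field crosses, the per-family
locus counts of the rutin biosynthesis pathway, and the per-locus SNP
summaries of the two glasshouse replicates (maternal plants A and B,
each crossed to the homozygous reference line).

They serve as worked-example inputs and as desk-scale checks: the effect
partition, pathway totals and ratio statistics recompute directly from
these numbers.
"""

from __future__ import annotations

from .types import CrossSpec, LineSpec, LocusInfo

#: Parental lines: breeding system, flower morphology and per-seed rutin
#: distribution (mg/g).  HR8 is the self-incompatible high-rutin line
#: (broad SD from heterozygosity); PL4 and LoR are self-compatible
#: low-rutin lines with narrow SDs; the remaining four are SI cultivars
#: with medium rutin content.
LINES: list[LineSpec] = [
    LineSpec("HR8", "SI", "mixed", 0.60, 0.41),
    LineSpec("PL4", "SC", "long_homostyle", 0.06, 0.03),
    LineSpec("LoR", "SC", "long_homostyle", 0.01, 0.02),
    LineSpec("KTM", "SI", "mixed", 0.18, 0.09),
    LineSpec("KTW", "SI", "mixed", 0.21, 0.13),
    LineSpec("RRN", "SI", "mixed", 0.15, 0.12),
    LineSpec("KTY", "SI", "mixed", 0.17, 0.14),
]

#: Field crosses; letters name the shared plot (a1/a2 were grown together).
CROSSES: list[CrossSpec] = [
    CrossSpec("a1", "HR8", "KTM", "a"),
    CrossSpec("b1", "HR8", "KTW", "b"),
    CrossSpec("c1", "HR8", "RRN", "c"),
    CrossSpec("d1", "HR8", "KTY", "d"),
    CrossSpec("e", "HR8", "PL4", "e"),
    CrossSpec("f", "HR8", "LoR", "f"),
    CrossSpec("a2", "KTM", "HR8", "a"),
    CrossSpec("b2", "KTW", "HR8", "b"),
    CrossSpec("c2", "RRN", "HR8", "c"),
    CrossSpec("d2", "KTY", "HR8", "d"),
]

#: Printed F1 results per cross: mean rutin (mg/g), SD, significance codes
#: for the Pm-vs-F1 and Pp-vs-F1 comparisons, and the published maternal /
#: pollen effect values.
F1_RESULTS: dict[str, dict] = {
    "a1": dict(f1_mean=0.38, f1_sd=0.26, sig_pm="***", sig_pp="***", m=0.49, pollen=0.51),
    "b1": dict(f1_mean=0.36, f1_sd=0.36, sig_pm="***", sig_pp="**", m=0.40, pollen=0.60),
    "c1": dict(f1_mean=0.40, f1_sd=0.26, sig_pm="***", sig_pp="***", m=0.56, pollen=0.44),
    "d1": dict(f1_mean=0.31, f1_sd=0.26, sig_pm="***", sig_pp="**", m=0.32, pollen=0.68),
    "e": dict(f1_mean=0.44, f1_sd=0.28, sig_pm="**", sig_pp="***", m=0.71, pollen=0.29),
    "f": dict(f1_mean=0.45, f1_sd=0.27, sig_pm="**", sig_pp="***", m=0.74, pollen=0.26),
    "a2": dict(f1_mean=0.32, f1_sd=0.28, sig_pm="**", sig_pp="***", m=0.65, pollen=0.35),
    "b2": dict(f1_mean=0.22, f1_sd=0.19, sig_pm="0.87", sig_pp="***", m=0.98, pollen=0.02),
    "c2": dict(f1_mean=0.21, f1_sd=0.16, sig_pm="0.16", sig_pp="***", m=0.86, pollen=0.14),
    "d2": dict(f1_mean=0.28, f1_sd=0.20, sig_pm="*", sig_pp="***", m=0.75, pollen=0.25),
}

#: Published per-cross effect values grouped by the maternal parent's rutin
#: group (high-rutin maternal block, then medium-rutin maternal block);
#: their means are the published block averages 0.54/0.46 and 0.81/0.19.
HIGH_MATERNAL_CROSSES = ["a1", "b1", "c1", "d1", "e", "f"]
MEDIUM_MATERNAL_CROSSES = ["a2", "b2", "c2", "d2"]

#: Rutin pathway gene families: (detected in reference, expressed during
#: seed formation, pollen-parent allele detected).  GTR's single expressed
#: locus appeared in only one plant; the family is excluded from the
#: expressed/pollen totals while its 12 reference loci do count toward the
#: detected total (62).
PATHWAY_COUNTS: dict[str, tuple[int, int, int]] = {
    "PAL": (4, 4, 3),
    "C4H": (6, 2, 1),
    "4CL": (2, 2, 1),
    "CHS": (13, 5, 3),
    "CHI": (3, 1, 1),
    "F3H": (2, 2, 1),
    "F3pH": (2, 2, 1),
    "F3p5pH": (16, 3, 3),
    "FLS": (2, 1, 0),
    "GTR": (12, 1, 1),
}

#: Per-locus SNP summaries for the two replicates.  Each entry:
#: (family, locus, total positions, then per replicate (A, B):
#:  pattern-I count, pattern-II count, mean ratio %, SE % — None = absent).
ASE_LOCUS_TABLE: list[tuple] = [
    ("PAL", "Chr3.g195460.1", 2173, (22, 3, 30.3, 1.94), (15, 10, 16.9, 4.02)),
    ("PAL", "Chr4.g269240.1", 2110, (20, 18, 22.5, 9.80), (43, 5, 14.6, 5.60)),
    ("PAL", "Chr8.g155630.1", 2113, (4, 12, 44.4, 6.63), (8, 7, 47.1, 6.55)),
    ("C4H", "sc0109.1.g001280.1", 1516, (39, 5, 20.7, 2.05), (22, 7, 26.7, 5.11)),
    ("4CL", "Chr4.g271010.1", 1642, (13, 1, 38.5, None), (35, 2, 18.0, 2.00)),
    ("CHS", "Chr4.g217000.1", 1183, (3, 7, 68.0, 3.15), (3, 7, 66.1, 5.61)),
    ("CHS", "Chr7.g094080.1", 1180, (5, 0, None, None), (4, 1, 74.2, None)),
    ("CHS", "Chr7.g094660.1", 1180, (5, 0, None, None), (4, 1, 9.6, None)),
    ("CHI", "Chr3.g000530.1", 772, (11, 0, None, None), (10, 0, None, None)),
    ("F3H", "Chr5.g258370.1", 1105, (10, 3, 21.4, 0.91), (13, 3, 20.0, 2.52)),
    ("F3pH", "Chr8.g248260.1", 1588, (9, 16, 54.9, 8.55), (8, 16, 53.9, 7.66)),
    ("F3p5pH", "Chr4.g265140.1", 1834, (13, 1, 36.4, None), (15, 0, None, None)),
    ("F3p5pH", "Chr4.g265180.1", 1876, (31, 1, 11.8, None), (18, 0, None, None)),
    ("F3p5pH", "Chr4.g265190.1", 1576, (5, 0, None, None), (5, 0, None, None)),
]


def line_specs() -> dict[str, LineSpec]:
    return {l.name: l for l in LINES}


def published_effects(cross_ids: list[str], which: str = "pollen") -> list[float]:
    """Published effect values for the given crosses (for block averages)."""
    key = "pollen" if which == "pollen" else "m"
    return [F1_RESULTS[c][key] for c in cross_ids]


def ase_mean_ratios() -> list[float]:
    """All published per-(locus, replicate) mean pollen-allele ratios (n=20)."""
    values = []
    for _, _, _, rep_a, rep_b in ASE_LOCUS_TABLE:
        for rep in (rep_a, rep_b):
            if rep[2] is not None:
                values.append(rep[2])
    return values


def ase_loci() -> list[LocusInfo]:
    return [LocusInfo(locus_id=loc, enzyme_family=fam, length_bp=total + 12)
            for fam, loc, total, _, _ in ASE_LOCUS_TABLE]
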