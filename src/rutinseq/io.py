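"""Readers and writers for the pipeline's plain-text formats.

All tables are UTF-8 TSV with fixed headers and "." decimal separators;
absent values are written as ``-`` and parsed to ``None``, never to 0.
Positions are 1-based on the cDNA/transcript.  Every reader/writer pair is
a bijection on valid data; parsers reject invalid rows with a
:class:`~rutinseq.types.TableFormatError` naming the offending row (1-based
data row, excluding the header).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    BASES,
    MISSING,
    CrossSpec,
    ExpressionRecord,
    LineSpec,
    LocusInfo,
    PileupColumn,
    RunConfig,
    SeedRutinRecord,
    TableFormatError,
    TruthSite,
)

logger = logging.getLogger("rutinseq")

RUTIN_COLUMNS = ["line", "plant", "seed", "rutin_mg_per_g"]
LINE_COLUMNS = ["name", "compatibility", "flower_type", "rutin_mean", "rutin_sd"]
CROSS_COLUMNS = ["cross_id", "maternal", "pollen", "plot_group"]
LOCUS_COLUMNS = ["locus_id", "enzyme_family", "length_bp", "cds_start"]
PILEUP_COLUMNS = [
    "sample_id", "cross_type", "locus_id", "pos", "ref_base",
    "count_A", "count_C", "count_G", "count_T",
]
EXPRESSION_COLUMNS = ["sample_id", "locus_id", "est_count", "effective_length"]
TRUTH_COLUMNS = [
    "locus_id", "pos", "ref_base", "maternal_genotype",
    "self_pollen_genotype", "expected_pattern", "true_pi",
]


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing column(s) {missing}", path=path)
    return df


def _num(value: str, column: str, row: int, path, kind=float):
    if value == MISSING or value == "":
        return None
    try:
        return kind(value)
    except ValueError as exc:
        raise TableFormatError(
            f"column {column!r}: cannot parse {value!r}", row=row, path=path
        ) from exc


# ---------------------------------------------------------------------------
# per-seed rutin measurements


def read_rutin_table(path) -> list[SeedRutinRecord]:
    """Read per-seed rutin measurements (line, plant, seed, rutin_mg_per_g)."""
    df = _read_tsv(path, RUTIN_COLUMNS)
    records: list[SeedRutinRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rutin = _num(row.rutin_mg_per_g, "rutin_mg_per_g", i, path)
        if rutin is None:
            raise TableFormatError("rutin_mg_per_g is required", row=i, path=path)
        if rutin < 0:
            raise TableFormatError(f"negative rutin {rutin}", row=i, path=path)
        try:
            rec = SeedRutinRecord(
                line=row.line,
                plant_index=_num(row.plant, "plant", i, path, int),
                seed_index=_num(row.seed, "seed", i, path, int),
                rutin=rutin,
            )
        except (TypeError, ValueError) as exc:
            raise TableFormatError(str(exc), row=i, path=path) from exc
        if rec.key in seen:
            raise TableFormatError(f"duplicate key {rec.key}", row=i, path=path)
        seen.add(rec.key)
        records.append(rec)
    logger.info("read %d seed rutin records from %s", len(records), path)
    return records


def write_rutin_table(records: Iterable[SeedRutinRecord], path) -> None:
    df = pd.DataFrame(
        [(r.line, r.plant_index, r.seed_index, repr(float(r.rutin))) for r in records],
        columns=RUTIN_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# line and cross metadata


def read_lines_table(path) -> list[LineSpec]:
    df = _read_tsv(path, LINE_COLUMNS)
    specs, names = [], set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            spec = LineSpec(
                name=row.name,
                compatibility=row.compatibility,
                flower_type=row.flower_type,
                rutin_mean=_num(row.rutin_mean, "rutin_mean", i, path),
                rutin_sd=_num(row.rutin_sd, "rutin_sd", i, path),
            )
        except (TypeError, ValueError) as exc:
            raise TableFormatError(str(exc), row=i, path=path) from exc
        if spec.name in names:
            raise TableFormatError(f"duplicate line {spec.name!r}", row=i, path=path)
        names.add(spec.name)
        specs.append(spec)
    return specs


def write_lines_table(specs: Iterable[LineSpec], path) -> None:
    df = pd.DataFrame(
        [(s.name, s.compatibility, s.flower_type, repr(float(s.rutin_mean)),
          repr(float(s.rutin_sd))) for s in specs],
        columns=LINE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_crosses_table(path) -> list[CrossSpec]:
    df = _read_tsv(path, CROSS_COLUMNS)
    crosses, ids = [], set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            cross = CrossSpec(row.cross_id, row.maternal, row.pollen, row.plot_group)
        except ValueError as exc:
            raise TableFormatError(str(exc), row=i, path=path) from exc
        if cross.cross_id in ids:
            raise TableFormatError(f"duplicate cross {cross.cross_id!r}", row=i, path=path)
        ids.add(cross.cross_id)
        crosses.append(cross)
    return crosses


def write_crosses_table(crosses: Iterable[CrossSpec], path) -> None:
    df = pd.DataFrame(
        [(c.cross_id, c.maternal, c.pollen, c.plot_group) for c in crosses],
        columns=CROSS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_loci_table(path) -> list[LocusInfo]:
    df = _read_tsv(path, LOCUS_COLUMNS)
    loci, ids = [], set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            info = LocusInfo(
                locus_id=row.locus_id,
                enzyme_family=row.enzyme_family,
                length_bp=_num(row.length_bp, "length_bp", i, path, int),
                cds_start=_num(row.cds_start, "cds_start", i, path, int),
            )
        except (TypeError, ValueError) as exc:
            raise TableFormatError(str(exc), row=i, path=path) from exc
        if info.locus_id in ids:
            raise TableFormatError(f"duplicate locus {info.locus_id!r}", row=i, path=path)
        ids.add(info.locus_id)
        loci.append(info)
    return loci


def write_loci_table(loci: Iterable[LocusInfo], path) -> None:
    df = pd.DataFrame(
        [(l.locus_id, l.enzyme_family, l.length_bp,
          MISSING if l.cds_start is None else l.cds_start) for l in loci],
        columns=LOCUS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pileups and expression


def read_pileup_table(path) -> list[PileupColumn]:
    """Read per-position nucleotide counts; validates bases and counts."""
    df = _read_tsv(path, PILEUP_COLUMNS)
    columns = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        counts = {}
        for base in BASES:
            n = _num(getattr(row, f"count_{base}"), f"count_{base}", i, path, int)
            if n is None or n < 0:
                raise TableFormatError(f"count_{base} must be >= 0", row=i, path=path)
            counts[base] = n
        try:
            col = PileupColumn(
                sample_id=row.sample_id,
                cross_type=row.cross_type,
                locus_id=row.locus_id,
                pos=_num(row.pos, "pos", i, path, int),
                ref_base=row.ref_base,
                counts=counts,
            )
        except (TypeError, ValueError) as exc:
            raise TableFormatError(str(exc), row=i, path=path) from exc
        columns.append(col)
    logger.info("read %d pileup columns from %s", len(columns), path)
    return columns


def write_pileup_table(columns: Iterable[PileupColumn], path) -> None:
    df = pd.DataFrame(
        [(c.sample_id, c.cross_type, c.locus_id, c.pos, c.ref_base,
          c.counts.get("A", 0), c.counts.get("C", 0),
          c.counts.get("G", 0), c.counts.get("T", 0)) for c in columns],
        columns=PILEUP_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_expression_table(path) -> list[ExpressionRecord]:
    df = _read_tsv(path, EXPRESSION_COLUMNS)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(ExpressionRecord(
                sample_id=row.sample_id,
                locus_id=row.locus_id,
                est_count=_num(row.est_count, "est_count", i, path),
                effective_length=_num(row.effective_length, "effective_length", i, path),
            ))
        except (TypeError, ValueError) as exc:
            raise TableFormatError(str(exc), row=i, path=path) from exc
    return records


def write_expression_table(records: Iterable[ExpressionRecord], path) -> None:
    df = pd.DataFrame(
        [(r.sample_id, r.locus_id, repr(float(r.est_count)),
          repr(float(r.effective_length))) for r in records],
        columns=EXPRESSION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# simulation truth


def read_truth_table(path) -> list[TruthSite]:
    df = _read_tsv(path, TRUTH_COLUMNS)
    sites = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        sites.append(TruthSite(
            locus_id=row.locus_id,
            pos=_num(row.pos, "pos", i, path, int),
            ref_base=row.ref_base,
            maternal_genotype=tuple(row.maternal_genotype.split("/")),
            self_pollen_genotype=tuple(row.self_pollen_genotype.split("/")),
            expected_pattern=row.expected_pattern,
            true_pi=_num(row.true_pi, "true_pi", i, path),
        ))
    return sites


def write_truth_table(sites: Iterable[TruthSite], path) -> None:
    df = pd.DataFrame(
        [(s.locus_id, s.pos, s.ref_base, "/".join(s.maternal_genotype),
          "/".join(s.self_pollen_genotype), s.expected_pattern,
          repr(float(s.true_pi))) for s in sites],
        columns=TRUTH_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA and config


def read_fasta(path) -> dict[str, str]:
    """Read a multi-record FASTA into {locus_id: uppercase sequence}.

    Duplicate identifiers raise; non-ACGTN characters are kept with a
    warning (they never match a pileup base, so they are effectively
    masked downstream).
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise TableFormatError(f"duplicate FASTA identifier {record.id!r}", path=path)
        seq = str(record.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            logger.warning("%s: sequence %s contains non-ACGTN characters %s",
                           path, record.id, sorted(bad))
        sequences[record.id] = seq
    return sequences


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_config(path) -> RunConfig:
    """Load a YAML configuration mirroring :class:`RunConfig` fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def write_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def loci_from_fasta(sequences: dict[str, str],
                    families: dict[str, str] | None = None) -> list[LocusInfo]:
    """Build LocusInfo from sequences when no metadata table is given."""
    families = families or {}
    return [
        LocusInfo(locus_id=name, enzyme_family=families.get(name, "PAL"),
                  length_bp=len(seq))
        for name, seq in sequences.items()
    ]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
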