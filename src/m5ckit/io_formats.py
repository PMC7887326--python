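"""Readers and writers for every on-disk format the pipeline touches.

All readers validate strictly and reject malformed input with errors that
carry line numbers; nothing is silently repaired.  Internal coordinates are
0-based half-open; GTF's 1-based closed coordinates are converted here and
nowhere else.
"""
from __future__ import annotations

import re
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .datatypes import (
    DIFF_COLUMNS,
    DIFF_DIRECTIONS,
    FASTA_ALPHABET,
    PILEUP_COLUMNS,
    SITE_COLUMNS,
    GenomeSequence,
    GenomicInterval,
    TranscriptModel,
)

_ILLEGAL_BASE = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Malformed input file."""


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------
def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a FASTA file into a mapping chrom_id -> GenomeSequence.

    Sequences are uppercased; only A/C/G/T/N are accepted.  Duplicate
    headers and illegal characters raise ``FormatError``.
    """
    path = Path(path)
    records: "OrderedDict[str, list[str]]" = OrderedDict()
    current: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if header in records:
                    raise FormatError(f"{path}:{lineno}: duplicate header {header!r}")
                records[header] = []
                current = header
            else:
                if current is None:
                    raise FormatError(f"{path}:{lineno}: sequence before first header")
                records[current].append(line.upper())
    genome: dict[str, GenomeSequence] = {}
    for chrom, chunks in records.items():
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: record {chrom!r} has empty sequence")
        m = _ILLEGAL_BASE.search(seq)
        if m:
            raise FormatError(
                f"{path}: record {chrom!r}: illegal character {m.group()!r} "
                f"at offset {m.start()}"
            )
        genome[chrom] = GenomeSequence(chrom, seq)
    return genome


def write_fasta(genome: Mapping[str, GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, rec in genome.items():
            fh.write(f">{chrom}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# BED
# --------------------------------------------------------------------------
def read_bed(
    path: str | Path,
    dialect: str = "BED6",
    genome: Mapping[str, GenomeSequence] | None = None,
) -> list[GenomicInterval]:
    """Read BED6 or BED12 intervals (half-open, as on disk).

    BED12 block structure is validated (block spans fit the interval) and
    each block is returned as its own interval named ``<name>/block<i>``
    in addition to nothing else: the caller receives one interval per
    record for BED6 and one per block for BED12's exonic footprint plus
    the enclosing record interval first.
    """
    if dialect not in ("BED6", "BED12"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    ncols = 6 if dialect == "BED6" else 12
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncols:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {ncols} tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise FormatError(
                    f"{path}:{lineno}: invalid coordinates start={start} end={end}"
                )
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            if genome is not None and chrom not in genome:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            record = GenomicInterval(chrom, start, end, strand, name)
            out.append(record)
            if dialect == "BED12":
                try:
                    n_blocks = int(fields[9])
                    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                    offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: malformed block columns") from exc
                if len(sizes) != n_blocks or len(offsets) != n_blocks:
                    raise FormatError(
                        f"{path}:{lineno}: blockCount disagrees with block lists"
                    )
                for i, (sz, off) in enumerate(zip(sizes, offsets)):
                    bs, be = start + off, start + off + sz
                    if be > end or sz < 1:
                        raise FormatError(f"{path}:{lineno}: block {i} outside record")
                    out.append(GenomicInterval(chrom, bs, be, strand, f"{name}/block{i}"))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


# --------------------------------------------------------------------------
# TSV site tables (pileup / sites / diff)
# --------------------------------------------------------------------------
_TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "pileup": PILEUP_COLUMNS,
    "sites": SITE_COLUMNS,
    "diff": DIFF_COLUMNS,
}

_INT_COLUMNS = {"pos", "c_count", "t_count", "coverage", "replicate"}
_LEVEL_COLUMNS = {"level", "level_a", "level_b"}


def _validate_table(df: pd.DataFrame, kind: str, path: str) -> None:
    required = _TABLE_SCHEMAS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        return
    if (df["pos"] < 0).any():
        raise FormatError(f"{path}: negative position")
    if "strand" in df.columns:
        bad = set(df["strand"].unique()) - {"+", "-", "."}
        if bad:
            raise FormatError(f"{path}: unknown strand symbol(s) {sorted(bad)}")
    for col in ("c_count", "t_count"):
        if col in df.columns and (df[col] < 0).any():
            raise FormatError(f"{path}: negative count in column {col!r}")
    if "coverage" in df.columns and (df["coverage"] < 1).any():
        raise FormatError(f"{path}: coverage must be >= 1")
    for col in _LEVEL_COLUMNS & set(df.columns):
        v = df[col]
        if ((v < 0) | (v > 1)).any():
            raise FormatError(f"{path}: column {col!r} must lie in [0, 1]")
    if "pvalue" in df.columns:
        v = df["pvalue"]
        if ((v <= 0) | (v > 1)).any():
            raise FormatError(f"{path}: pvalue must lie in (0, 1]")
    if "direction" in df.columns:
        bad = set(df["direction"].unique()) - set(DIFF_DIRECTIONS)
        if bad:
            raise FormatError(f"{path}: unknown direction value(s) {sorted(bad)}")


def read_site_table(path: str | Path, kind: str = "sites") -> pd.DataFrame:
    """Read one of the pipeline's TSV tables (``pileup``/``sites``/``diff``).

    Required columns per kind are validated along with value ranges; extra
    columns are preserved, so write -> read is the identity.
    """
    if kind not in _TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    _validate_table(df, kind, str(path))
    for col in _INT_COLUMNS & set(df.columns):
        df[col] = df[col].astype(int)
    return df


def write_site_table(df: pd.DataFrame, path: str | Path, kind: str = "sites") -> None:
    _validate_table(df, kind, str(path))
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Minimal GTF
# --------------------------------------------------------------------------
_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_minimal(path: str | Path) -> list[TranscriptModel]:
    """Parse exon/CDS features grouped by transcript_id into gene models.

    GTF is 1-based closed; output models are 0-based half-open.  A
    transcript with CDS bases outside its exon union, or with overlapping
    exons, is rejected.
    """
    path = Path(path)
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise FormatError(f"{path}:{lineno}: invalid GTF coordinates")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: strand must be + or -")
            attr = dict(_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            gid = attr.get("gene_id", tid)
            if not tid:
                raise FormatError(f"{path}:{lineno}: missing transcript_id attribute")
            iv = (start1 - 1, end1)  # to 0-based half-open
            if tid not in meta:
                meta[tid] = (gid, chrom, strand)
                order.append(tid)
            elif meta[tid] != (gid, chrom, strand):
                raise FormatError(
                    f"{path}:{lineno}: inconsistent gene/chrom/strand for {tid!r}"
                )
            (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)

    models: list[TranscriptModel] = []
    for tid in order:
        gid, chrom, strand = meta[tid]
        ex = sorted(exons.get(tid, []))
        if not ex:
            raise FormatError(f"{path}: transcript {tid!r} has CDS but no exons")
        for (s1, e1), (s2, _e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise FormatError(f"{path}: transcript {tid!r} has overlapping exons")
        cds_start = cds_end = None
        if tid in cds:
            spans = sorted(cds[tid])
            cds_start, cds_end = spans[0][0], spans[-1][1]
            covered = 0
            for cs, ce in spans:
                for s, e in ex:
                    covered += max(0, min(ce, e) - max(cs, s))
            cds_total = sum(e - s for s, e in spans)
            if covered != cds_total:
                raise FormatError(
                    f"{path}: transcript {tid!r}: CDS outside exon union"
                )
        try:
            models.append(
                TranscriptModel(tid, gid, chrom, strand, tuple(ex), cds_start, cds_end)
            )
        except ValueError as exc:
            raise FormatError(f"{path}: transcript {tid!r}: {exc}") from exc
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write minimal exon/CDS GTF (1-based closed on disk)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tm5ckit\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.is_coding:
                for s, e in m.exons:
                    cs, ce = max(s, m.cds_start), min(e, m.cds_end)
                    if cs < ce:
                        fh.write(
                            f"{m.chrom}\tm5ckit\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t.\t{attrs}\n"
                        )
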