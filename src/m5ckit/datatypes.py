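"""Core value types and table schemas shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package (BED
convention). GTF input (1-based closed) is converted at the I/O boundary.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property

VALID_STRANDS = {"+", "-", "."}
FASTA_ALPHABET = set("ACGTN")
_ILLEGAL_BASE = re.compile(r"[^ACGTN]")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A single reference chromosome/contig."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.chrom_id:
            raise ValueError("chrom_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence for {self.chrom_id!r} is empty")
        m = _ILLEGAL_BASE.search(self.sequence)
        if m:
            raise ValueError(
                f"illegal character {m.group()!r} in {self.chrom_id!r} "
                f"at offset {m.start()}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class TranscriptModel:
    """A gene model: ordered exons plus optional CDS bounds.

    ``exons`` are sorted, non-overlapping (start, end) pairs in genomic
    coordinates.  ``cds_start``/``cds_end`` delimit the genomic CDS span
    (half-open); both ``None`` for a non-coding model.  Spliced-transcript
    coordinates run 5'→3' on the transcript, so on the − strand offset 0
    is the highest genomic exonic position.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.transcript_id}: bad exon ({s},{e})")
            if s < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted at ({s},{e})"
                )
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: partial CDS bounds")
        if self.cds_start is not None:
            if not (self.start <= self.cds_start < self.cds_end <= self.end):
                raise ValueError(f"{self.transcript_id}: CDS outside exon span")
            if self._plus_offset(self.cds_start) is None or self._plus_offset(
                self.cds_end - 1
            ) is None:
                raise ValueError(f"{self.transcript_id}: CDS bounds not exonic")

    # -- basic geometry ----------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @cached_property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    # -- coordinate projection --------------------------------------------
    def _plus_offset(self, pos: int) -> int | None:
        """Offset of a genomic position in plus-orientation spliced coords."""
        acc = 0
        for s, e in self.exons:
            if pos < s:
                return None
            if pos < e:
                return acc + (pos - s)
            acc += e - s
        return None

    def genomic_to_spliced(self, pos: int) -> int | None:
        """Spliced 5'→3' transcript offset of a genomic position, or None."""
        off = self._plus_offset(pos)
        if off is None:
            return None
        return off if self.strand == "+" else self.spliced_length - 1 - off

    def spliced_to_genomic(self, offset: int) -> int:
        if not (0 <= offset < self.spliced_length):
            raise ValueError(f"spliced offset {offset} out of range")
        plus = offset if self.strand == "+" else self.spliced_length - 1 - offset
        acc = 0
        for s, e in self.exons:
            if plus < acc + (e - s):
                return s + (plus - acc)
            acc += e - s
        raise AssertionError("unreachable")

    # -- region lengths in transcript coordinates --------------------------
    @cached_property
    def _cds_plus_bounds(self) -> tuple[int, int] | None:
        if not self.is_coding:
            return None
        s = self._plus_offset(self.cds_start)
        e = self._plus_offset(self.cds_end - 1) + 1
        return s, e

    @property
    def cds_len(self) -> int:
        b = self._cds_plus_bounds
        return 0 if b is None else b[1] - b[0]

    @property
    def utr5_len(self) -> int:
        b = self._cds_plus_bounds
        if b is None:
            return 0
        return b[0] if self.strand == "+" else self.spliced_length - b[1]

    @property
    def utr3_len(self) -> int:
        b = self._cds_plus_bounds
        if b is None:
            return 0
        return self.spliced_length - b[1] if self.strand == "+" else b[0]


# -- table schemas ---------------------------------------------------------
PILEUP_COLUMNS = ("chrom", "pos", "strand", "replicate", "condition", "c_count", "t_count")
SITE_COLUMNS = ("chrom", "pos", "strand", "gene", "level", "coverage", "pvalue")
DIFF_COLUMNS = ("chrom", "pos", "strand", "gene", "level_a", "level_b", "pvalue", "direction")
DIFF_DIRECTIONS = ("hyper", "hypo", "ns")

SITE_KEY = ["chrom", "pos", "strand"]
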