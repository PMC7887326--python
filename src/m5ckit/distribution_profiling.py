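"""Distribution analytics for called m5C sites.

Covers the five-region annotation (5'UTR / start codon / CDS / stop codon /
3'UTR), metagene projection onto a virtual transcript, 21-nt sequence
windows and their CG/CHG/CHH context, the position-frequency matrix behind
sequence logos, sites-per-gene histograms with a two-proportion test, and
per-chromosome site density.
"""
from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenomeSequence, TranscriptModel, reverse_complement
from .differential_methylation import fisher_exact_two_sided

logger = logging.getLogger(__name__)

REGION_LABELS = (
    "five_prime_utr",
    "start_codon",
    "cds",
    "stop_codon",
    "three_prime_utr",
    "noncoding",
    "intergenic",
)

#: Bin edges of the sites-per-gene histogram; the last bin is open (">8").
SITES_PER_GENE_BINS = tuple(str(i) for i in range(1, 9)) + (">8",)


def representative_transcripts(
    transcriptome: Iterable[TranscriptModel],
) -> dict[str, TranscriptModel]:
    """One deterministic representative per gene: the longest coding model
    (ties broken by transcript_id), falling back to the longest model."""
    best: dict[str, TranscriptModel] = {}
    for m in transcriptome:
        cur = best.get(m.gene_id)
        if cur is None:
            best[m.gene_id] = m
            continue
        key = (m.is_coding, m.spliced_length, m.transcript_id)
        cur_key = (cur.is_coding, cur.spliced_length, cur.transcript_id)
        if key > cur_key:
            best[m.gene_id] = m
    return best


def annotate_region(pos: int, strand: str, transcript: TranscriptModel) -> str:
    """Map a site to one of the five mRNA regions (or noncoding/intergenic).

    The start/stop codon regions are exactly the three CDS-terminal
    nucleotides and take precedence over CDS.
    """
    if strand != transcript.strand or transcript.genomic_to_spliced(pos) is None:
        return "intergenic"
    if not transcript.is_coding:
        return "noncoding"
    off = transcript.genomic_to_spliced(pos)
    u5, cds = transcript.utr5_len, transcript.cds_len
    if u5 <= off < u5 + 3:
        return "start_codon"
    if u5 + cds - 3 <= off < u5 + cds:
        return "stop_codon"
    if off < u5:
        return "five_prime_utr"
    if off < u5 + cds:
        return "cds"
    return "three_prime_utr"


def region_length_medians(
    transcriptome: Iterable[TranscriptModel],
) -> tuple[float, float, float]:
    """Median 5'UTR / CDS / 3'UTR lengths over coding transcripts."""
    u5, cds, u3 = [], [], []
    for m in transcriptome:
        if m.is_coding:
            u5.append(m.utr5_len)
            cds.append(m.cds_len)
            u3.append(m.utr3_len)
    if not cds:
        raise ValueError("no coding transcripts")
    return float(np.median(u5)), float(np.median(cds)), float(np.median(u3))


def metagene_coordinate(
    pos: int,
    transcript: TranscriptModel,
    scaling: str = "per_transcript",
    region_medians: tuple[float, float, float] | None = None,
) -> float | None:
    """Project a site onto the virtual transcript axis [0, 3).

    ``per_transcript``: fractional position within its region plus the
    region offset (5'UTR -> [0,1), CDS -> [1,2), 3'UTR -> [2,3)).
    ``median_rescaled``: region widths are proportional to the
    transcriptome's median region lengths (normalised to total 3), the
    MetaPlotR convention; requires ``region_medians``.
    Returns None (with a log entry) for sites in zero-length regions or
    outside the transcript.
    """
    if scaling not in ("per_transcript", "median_rescaled"):
        raise ValueError(f"unknown scaling {scaling!r}")
    if not transcript.is_coding:
        return None
    off = transcript.genomic_to_spliced(pos)
    if off is None:
        return None
    u5, cds, u3 = transcript.utr5_len, transcript.cds_len, transcript.utr3_len
    if off < u5:
        region, frac = 0, off / u5 if u5 else None
    elif off < u5 + cds:
        region, frac = 1, (off - u5) / cds if cds else None
    else:
        region, frac = 2, (off - u5 - cds) / u3 if u3 else None
    if frac is None:
        logger.info(
            "site at %s:%d skipped: zero-length region on %s",
            transcript.chrom, pos, transcript.transcript_id,
        )
        return None
    if scaling == "per_transcript":
        return float(region + frac)
    if region_medians is None:
        raise ValueError("median_rescaled scaling requires region_medians")
    widths = np.asarray(region_medians, dtype=float)
    if widths.sum() <= 0:
        raise ValueError("degenerate region medians")
    widths = widths * 3.0 / widths.sum()
    edges = np.concatenate([[0.0], np.cumsum(widths)])
    return float(edges[region] + frac * widths[region])


def extract_window(
    genome: Mapping[str, GenomeSequence], chrom: str, pos: int, strand: str,
    flank: int = 10,
) -> str:
    """Sequence window of 2*flank+1 nt centred on the site, on its strand.

    Positions beyond the chromosome ends are padded with N.  The centre
    base must read C on the site's strand.
    """
    seq = genome[chrom].sequence
    if not (0 <= pos < len(seq)):
        raise ValueError(f"position {pos} outside {chrom}")
    lo, hi = pos - flank, pos + flank + 1
    window = (
        "N" * max(0, -lo)
        + seq[max(0, lo) : min(len(seq), hi)]
        + "N" * max(0, hi - len(seq))
    )
    if strand == "-":
        window = reverse_complement(window)
    if window[flank] != "C":
        raise ValueError(
            f"{chrom}:{pos}({strand}): centre base is {window[flank]!r}, not C "
            "(coordinate or strand bug)"
        )
    return window


def classify_context(window: str) -> str | None:
    """CG / CHG / CHH context from the two bases 3' of the cytosine.

    Returns None (logged) when an N falls in the decisive span.
    """
    flank = len(window) // 2
    if window[flank] != "C":
        raise ValueError("window centre is not C")
    nxt, nxt2 = window[flank + 1], window[flank + 2] if flank + 2 < len(window) else "N"
    if nxt == "N":
        logger.info("context undetermined: N immediately 3' of the site")
        return None
    if nxt == "G":
        return "CG"
    if nxt2 == "N":
        logger.info("context undetermined: N two bases 3' of the site")
        return None
    return "CHG" if nxt2 == "G" else "CHH"


def position_frequency_matrix(windows: Sequence[str]) -> pd.DataFrame:
    """Column-stochastic base-frequency matrix of aligned windows.

    Rows A/C/G/U (T counted as U), one column per window position; each
    column sums to 1 over non-N counts.
    """
    if not windows:
        raise ValueError("need at least one window")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("windows have mixed lengths")
    counts = np.zeros((4, width))
    row = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
    for w in windows:
        for j, base in enumerate(w.upper()):
            if base in row:
                counts[row[base], j] += 1
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("a column contains only N")
    freqs = counts / totals
    return pd.DataFrame(freqs, index=["A", "C", "G", "U"])


def sites_per_gene_distribution(sites: pd.DataFrame) -> pd.DataFrame:
    """Histogram of m5C sites per methylated gene over bins 1..8 and '>8'.

    Returns a DataFrame (bin, count, proportion); proportions sum to 1 over
    methylated genes.
    """
    labelled = sites[sites["gene"] != ""] if len(sites) else sites
    per_gene = labelled.groupby("gene").size() if len(labelled) else pd.Series(dtype=int)
    counter = Counter(
        str(n) if n <= 8 else ">8" for n in per_gene
    )
    total = sum(counter.values())
    rows = [
        (b, counter.get(b, 0), counter.get(b, 0) / total if total else 0.0)
        for b in SITES_PER_GENE_BINS
    ]
    return pd.DataFrame(rows, columns=["bin", "count", "proportion"])


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided test of p1 == p2 from counts k1/n1 vs k2/n2.

    Chi-square on the 2x2 table without continuity correction; falls back
    to the Fisher exact test when any expected cell is 5 or less (the
    usual small-sample validity rule, boundary included).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n in both groups")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if (table.sum(axis=0) == 0).any():
        return 1.0  # degenerate margin: proportions are trivially equal
    expected = stats.contingency.expected_freq(table)
    if (expected <= 5).any():
        return fisher_exact_two_sided(k1, n1 - k1, k2, n2 - k2)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def chromosome_density(
    sites: pd.DataFrame, chrom_lengths: Mapping[str, int], bin_size: int
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Binned site counts per chromosome plus per-chromosome totals.

    Every chromosome in ``chrom_lengths`` gets ceil(len / bin_size) bins
    (trailing partial bin included); bins sum to that chromosome's total.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    bins: dict[str, np.ndarray] = {}
    totals: dict[str, int] = {}
    for chrom, length in chrom_lengths.items():
        n_bins = -(-length // bin_size)
        sub = sites[sites["chrom"] == chrom] if len(sites) else sites
        pos = sub["pos"].to_numpy() if len(sub) else np.array([], dtype=int)
        if len(pos) and (pos >= length).any():
            bad = int(pos[pos >= length][0])
            raise ValueError(f"site at {chrom}:{bad} beyond stated length {length}")
        bins[chrom] = np.bincount(pos // bin_size, minlength=n_bins).astype(int)
        totals[chrom] = int(len(pos))
    unknown = set(sites["chrom"].unique()) - set(chrom_lengths) if len(sites) else set()
    if unknown:
        raise ValueError(f"sites on unknown chromosome(s): {sorted(unknown)}")
    return bins, totals


def region_counts(
    sites: pd.DataFrame,
    transcriptome: Iterable[TranscriptModel],
) -> pd.DataFrame:
    """Count sites per region label using one representative model per gene."""
    reps = representative_transcripts(transcriptome)
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for m in reps.values():
        by_chrom.setdefault(m.chrom, []).append(m)
    counter = Counter()
    for r in sites.itertuples():
        label = "intergenic"
        for m in by_chrom.get(r.chrom, []):
            lab = annotate_region(r.pos, r.strand, m)
            if lab != "intergenic":
                label = lab
                break
        counter[label] += 1
    return pd.DataFrame(
        [(lab, counter.get(lab, 0)) for lab in REGION_LABELS],
        columns=["region", "count"],
    )
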