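"""Synthetic genomes, transcriptomes, bisulfite pileups, expression and RBP tracks.

The generator realises the same statistical structure the analysis assumes:
methylation lives on transcript-sense cytosines; a bisulfite pileup at a
cytosine with true level pi draws its unconverted count from
Binomial(n, pi + (1 - pi) * non_conversion_rate), so incomplete conversion
is the only error mode; coverage varies per site and replicate following a
negative-binomial law.  Everything is deterministic under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import GenomeSequence, GenomicInterval, TranscriptModel

CONDITION_A = "control"
CONDITION_B = "treated"

# per-operation stream tags so stages draw independent, reproducible streams
_STREAM_GENOME = 1
_STREAM_TRANSCRIPTOME = 2
_STREAM_METHYLATION = 3
_STREAM_PILEUP = 4
_STREAM_EXPRESSION = 5
_STREAM_RBP = 6


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int
    n_chroms: int = 3
    chrom_len: int = 60_000
    gc_content: float = 0.5
    n_genes: int = 40
    utr5_range: tuple[int, int] = (60, 240)
    cds_codons_range: tuple[int, int] = (60, 240)  # CDS length = 3 * codons
    utr3_range: tuple[int, int] = (60, 300)
    max_exons: int = 3
    intron_range: tuple[int, int] = (60, 200)
    intergenic_range: tuple[int, int] = (150, 600)
    n_methylated_sites: int = 300
    site_levels: tuple[float, ...] = (0.2, 0.35, 0.5, 0.65, 0.8)
    fraction_differential: float = 0.3
    differential_effect: float = 0.4
    hyper_fraction: float = 0.5
    coverage_mean: float = 50.0
    coverage_dispersion: float = 10.0  # NB size; var = m + m^2 / size
    non_conversion_rate: float = 0.005
    n_replicates: int = 3
    expression_baseline: float = 200.0
    expression_log_sd: float = 0.5
    expression_dispersion: float = 0.1  # NB alpha; var = m + alpha m^2
    fraction_de: float = 0.3
    de_log2fc_range: tuple[float, float] = (1.0, 2.5)
    n_rbps: int = 6
    sites_per_rbp: int = 40
    rbp_site_width: int = 30
    rbp_enrichment: float = 0.3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("gc_content", "fraction_differential", "hyper_fraction",
                     "non_conversion_rate", "fraction_de", "rbp_enrichment"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be > 0")
        if not (0.0 < self.differential_effect <= 0.9):
            raise ValueError("differential_effect must lie in (0, 0.9]")


@dataclass
class TruthTable:
    """Ground truth: per-site methylation levels and per-gene expression."""

    sites: pd.DataFrame  # chrom,pos,strand,gene,true_level_condA,true_level_condB,is_differential,direction
    genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "true_log2fc", "is_de"]
        )
    )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


# --------------------------------------------------------------------------
def generate_genome(config: SimulationConfig) -> dict[str, GenomeSequence]:
    """Random genome with the configured GC content."""
    if config.n_chroms == 0:
        return {}
    if config.chrom_len < 1000:
        raise ValueError("chrom_len < 1000 is too short to host transcripts")
    rng = _rng(config, _STREAM_GENOME)
    g = config.gc_content
    probs = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
    bases = np.array(list("ACGT"))
    genome: dict[str, GenomeSequence] = {}
    for i in range(config.n_chroms):
        seq = "".join(rng.choice(bases, size=config.chrom_len, p=probs))
        name = f"chr{i + 1}"
        genome[name] = GenomeSequence(name, seq)
    return genome


def generate_transcriptome(
    genome: Mapping[str, GenomeSequence], config: SimulationConfig
) -> list[TranscriptModel]:
    """Non-overlapping single-isoform gene models laid out along the genome."""
    if not genome:
        raise ValueError("genome is empty")
    rng = _rng(config, _STREAM_TRANSCRIPTOME)
    chroms = list(genome)
    cursors = {c: rng.integers(*config.intergenic_range) for c in chroms}
    models: list[TranscriptModel] = []
    chrom_cycle = 0
    attempts = 0
    while len(models) < config.n_genes:
        if attempts > config.n_genes * len(chroms) * 4:
            raise ValueError(
                f"genome too small for {config.n_genes} genes; "
                "reduce n_genes or enlarge chrom_len"
            )
        attempts += 1
        chrom = chroms[chrom_cycle % len(chroms)]
        chrom_cycle += 1
        utr5 = int(rng.integers(*config.utr5_range))
        cds = 3 * int(rng.integers(*config.cds_codons_range))
        utr3 = int(rng.integers(*config.utr3_range))
        spliced = utr5 + cds + utr3
        n_exons = int(rng.integers(1, config.max_exons + 1))
        # split the spliced length into exon chunks of >= 30 nt
        while True:
            if n_exons == 1:
                exon_lens = [spliced]
                break
            cuts = np.sort(rng.integers(30, spliced - 30, size=n_exons - 1))
            lens = np.diff(np.concatenate([[0], cuts, [spliced]]))
            if (lens >= 30).all():
                exon_lens = [int(x) for x in lens]
                break
        introns = [int(rng.integers(*config.intron_range)) for _ in range(n_exons - 1)]
        span = sum(exon_lens) + sum(introns)
        start = cursors[chrom]
        if start + span > len(genome[chrom]):
            continue  # this chromosome is full; try the next
        exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if i < n_exons - 1:
                pos += introns[i]
        strand = "+" if rng.random() < 0.5 else "-"
        idx = len(models) + 1
        model = TranscriptModel(
            transcript_id=f"tx{idx:04d}",
            gene_id=f"gene{idx:04d}",
            chrom=chrom,
            strand=strand,
            exons=tuple(exons),
            cds_start=None,
            cds_end=None,
        )
        # plus-oriented spliced CDS interval: 5'UTR sits at the low-coordinate
        # end for + models and at the high-coordinate end for - models
        lead = utr5 if strand == "+" else utr3
        cds_start = model.spliced_to_genomic(
            lead if strand == "+" else spliced - lead - 1
        )
        cds_end_inner = model.spliced_to_genomic(
            lead + cds - 1 if strand == "+" else spliced - (lead + cds)
        )
        cs, ce = sorted((cds_start, cds_end_inner))
        model = replace(model, cds_start=cs, cds_end=ce + 1)
        models.append(model)
        cursors[chrom] = start + span + int(rng.integers(*config.intergenic_range))
    return models


# --------------------------------------------------------------------------
def _sense_cytosines(
    model: TranscriptModel, genome: Mapping[str, GenomeSequence]
) -> np.ndarray:
    """Genomic positions of transcript-sense cytosines (exonic)."""
    seq = genome[model.chrom].sequence
    want = "C" if model.strand == "+" else "G"
    pos = []
    for s, e in model.exons:
        for p in range(s, e):
            if seq[p] == want:
                pos.append(p)
    return np.asarray(pos, dtype=int)


def plant_methylation(
    transcriptome: list[TranscriptModel],
    genome: Mapping[str, GenomeSequence],
    config: SimulationConfig,
) -> TruthTable:
    """Choose methylated cytosines and assign true levels per condition.

    A ``fraction_differential`` of the planted sites differ between the two
    conditions by exactly ``differential_effect`` (hyper and hypo directions
    mixed per ``hyper_fraction``); the rest share one level drawn from
    ``site_levels``.
    """
    rng = _rng(config, _STREAM_METHYLATION)
    rows = []
    for m in transcriptome:
        for p in _sense_cytosines(m, genome):
            rows.append((m.chrom, int(p), m.strand, m.gene_id))
    if len(rows) < config.n_methylated_sites:
        raise ValueError(
            f"only {len(rows)} transcript-sense cytosines available for "
            f"{config.n_methylated_sites} requested sites"
        )
    pick = rng.choice(len(rows), size=config.n_methylated_sites, replace=False)
    pick.sort()
    chosen = [rows[i] for i in pick]
    n = len(chosen)
    is_diff = rng.random(n) < config.fraction_differential
    hyper = rng.random(n) < config.hyper_fraction
    eff = config.differential_effect
    level_a = np.empty(n)
    level_b = np.empty(n)
    base = rng.choice(np.asarray(config.site_levels), size=n)
    level_a[:] = base
    level_b[:] = base
    # differential sites: draw the low-condition level so the shifted one
    # stays inside [0, 0.95]
    for i in np.flatnonzero(is_diff):
        if hyper[i]:
            a = rng.uniform(0.1, min(0.95 - eff, 0.5))
            level_a[i], level_b[i] = a, a + eff
        else:
            b = rng.uniform(0.1, min(0.95 - eff, 0.5))
            level_a[i], level_b[i] = b + eff, b
    direction = np.where(
        ~is_diff, "none", np.where(hyper, "hyper", "hypo")
    )
    sites = pd.DataFrame(
        {
            "chrom": [c for c, _, _, _ in chosen],
            "pos": [p for _, p, _, _ in chosen],
            "strand": [s for _, _, s, _ in chosen],
            "gene": [g for _, _, _, g in chosen],
            "true_level_condA": level_a,
            "true_level_condB": level_b,
            "is_differential": is_diff,
            "direction": direction,
        }
    )
    return TruthTable(sites=sites)


# --------------------------------------------------------------------------
def simulate_pileups(
    truth: TruthTable,
    transcriptome: list[TranscriptModel],
    genome: Mapping[str, GenomeSequence],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Bisulfite pileup counts for every transcript-sense cytosine.

    Planted sites use their true level; all remaining sense cytosines are
    unmethylated background (level 0) whose only C signal is the
    non-conversion error.  Returns the long pileup table
    (chrom, pos, strand, replicate, condition, c_count, t_count).
    """
    ncr = config.non_conversion_rate
    if ncr >= 0.5:
        raise ValueError("non_conversion_rate >= 0.5 makes the error model nonsensical")
    rng = _rng(config, _STREAM_PILEUP)
    truth_key = {
        (r.chrom, r.pos, r.strand): (r.true_level_condA, r.true_level_condB)
        for r in truth.sites.itertuples()
    }
    keys: list[tuple[str, int, str]] = []
    seen = set()
    for m in transcriptome:
        for p in _sense_cytosines(m, genome):
            k = (m.chrom, int(p), m.strand)
            if k not in seen:
                seen.add(k)
                keys.append(k)
    # planted sites not on the transcript list (shouldn't happen) still covered
    for k in truth_key:
        if k not in seen:
            seen.add(k)
            keys.append(k)
    n_pos = len(keys)
    pi = {
        CONDITION_A: np.array([truth_key.get(k, (0.0, 0.0))[0] for k in keys]),
        CONDITION_B: np.array([truth_key.get(k, (0.0, 0.0))[1] for k in keys]),
    }
    r = config.coverage_dispersion
    p_nb = r / (r + config.coverage_mean)
    frames = []
    for cond in (CONDITION_A, CONDITION_B):
        p_c = pi[cond] + (1.0 - pi[cond]) * ncr
        for rep in range(1, config.n_replicates + 1):
            cov = rng.negative_binomial(r, p_nb, size=n_pos)
            c = rng.binomial(cov, p_c)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": [k[0] for k in keys],
                        "pos": [k[1] for k in keys],
                        "strand": [k[2] for k in keys],
                        "replicate": rep,
                        "condition": cond,
                        "c_count": c,
                        "t_count": cov - c,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
def simulate_expression(
    transcriptome: list[TranscriptModel], config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene negative-binomial counts for 2 conditions x n replicates.

    Returns ``(counts, gene_truth)``: counts has columns ``gene_id`` plus
    ``<condition>_<rep>``; gene_truth has (gene_id, true_log2fc, is_de) with
    planted |log2FC| >= log2(1.5) for DE genes.
    """
    if config.expression_baseline <= 0:
        raise ValueError("expression_baseline must be > 0")
    if config.expression_dispersion <= 0:
        raise ValueError("expression_dispersion must be > 0")
    if config.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = _rng(config, _STREAM_EXPRESSION)
    genes = [m.gene_id for m in transcriptome]
    n = len(genes)
    base = rng.lognormal(np.log(config.expression_baseline), config.expression_log_sd, n)
    is_de = rng.random(n) < config.fraction_de
    mag = rng.uniform(*config.de_log2fc_range, size=n)
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    lfc = np.where(is_de, sign * mag, 0.0)
    assert (np.abs(lfc[is_de]) >= np.log2(1.5)).all() if is_de.any() else True
    mean_a, mean_b = base, base * np.exp2(lfc)
    alpha = config.expression_dispersion
    size = 1.0 / alpha
    data: dict[str, object] = {"gene_id": genes}
    for cond, mu in ((CONDITION_A, mean_a), (CONDITION_B, mean_b)):
        for rep in range(1, config.n_replicates + 1):
            p_nb = size / (size + mu)
            data[f"{cond}_{rep}"] = rng.negative_binomial(size, p_nb)
    counts = pd.DataFrame(data)
    gene_truth = pd.DataFrame(
        {"gene_id": genes, "true_log2fc": lfc, "is_de": is_de}
    )
    return counts, gene_truth


# --------------------------------------------------------------------------
def generate_rbp_tracks(
    transcriptome: list[TranscriptModel],
    truth: TruthTable,
    config: SimulationConfig,
    genome: Mapping[str, GenomeSequence] | None = None,
) -> dict[str, list[GenomicInterval]]:
    """Synthetic RBP binding-site interval tracks inside transcript spans.

    A ``rbp_enrichment`` fraction of each track's intervals is placed to
    cover a planted methylation site; the rest land uniformly within random
    transcript spans.
    """
    if config.n_rbps < 1:
        raise ValueError("need at least one RBP")
    if config.rbp_site_width < 1:
        raise ValueError("rbp_site_width must be >= 1")
    rng = _rng(config, _STREAM_RBP)
    w = config.rbp_site_width
    chrom_len = {m.chrom: (len(genome[m.chrom]) if genome else None) for m in transcriptome}
    tracks: dict[str, list[GenomicInterval]] = {}
    truth_rows = truth.sites
    for r_i in range(1, config.n_rbps + 1):
        name = f"RBP{r_i:02d}"
        ivs: list[GenomicInterval] = []
        n_enriched = int(round(config.rbp_enrichment * config.sites_per_rbp))
        for j in range(config.sites_per_rbp):
            if j < n_enriched and len(truth_rows):
                row = truth_rows.iloc[int(rng.integers(len(truth_rows)))]
                lo = max(0, int(row.pos) - w + 1)
                hi = int(row.pos)
                limit = chrom_len.get(row.chrom)
                if limit is not None:
                    hi = min(hi, limit - w)
                start = int(rng.integers(lo, max(lo, hi) + 1))
                ivs.append(
                    GenomicInterval(row.chrom, start, start + w, ".", f"{name}_{j}")
                )
            else:
                m = transcriptome[int(rng.integers(len(transcriptome)))]
                span_hi = max(m.start, m.end - w)
                start = int(rng.integers(m.start, span_hi + 1))
                ivs.append(
                    GenomicInterval(m.chrom, start, start + w, m.strand, f"{name}_{j}")
                )
        tracks[name] = ivs
    return tracks
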