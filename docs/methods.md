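# Methods

## Data model and conventions

All coordinates are 0-based half-open (BED convention) everywhere inside
the package; GTF input (1-based closed) is converted at the I/O boundary
and nowhere else. Site identity is the triple (chrom, pos, strand).
Spliced transcript coordinates run 5′→3′, so on the − strand offset 0 is
the highest genomic exonic position and the 5′UTR is the high-coordinate
side. Tables are plain TSV with fixed headers (pileup: chrom, pos, strand,
replicate, condition, c_count, t_count; sites: chrom, pos, strand, gene,
level, coverage, pvalue; diff: those plus level_a/level_b/direction and the
pooled counts); readers validate ranges and reject malformed rows with
line-bearing errors rather than repairing them.

## Site calling

The observation at a cytosine is (c, t): unconverted and converted read
counts. The methylation level estimator is the plain ratio c/(c+t) with no
correction for the non-conversion rate; the error null is instead handled
by a one-sided binomial test, p = P(X ≥ c | n = c+t, p₀ = non-conversion
rate). A site is credible in a condition iff every replicate passes level
≥ min_level (default 0.1), coverage ≥ min_coverage (default 10) and p ≤ α
(default 0.05); all thresholds are inclusive. Reported level and coverage
pool replicates by summing counts (coverage-weighted, consistent with the
downstream Fisher pooling), so the pooled level always lies between the
replicate extremes. The per-replicate α is applied to raw p-values by
default; an optional mode replaces them with Benjamini–Hochberg adjusted
values across the candidate cytosines of each replicate. α and the test
itself are implementation choices — the level/coverage/all-replicates
filters are the interface contract, the binomial null is the natural
conjugate of the generator's error model. p-values are clamped to
[1e-300, 1] so extreme sites never underflow to an invalid 0.

## Differential methylation

Candidates are the union of sites credible in either condition with pooled
counts available in both. Each is tested with a two-sided Fisher exact
test on [[c_ctrl, t_ctrl], [c_treat, t_treat]]. The two-sided rule is the
point-probability method: sum the hypergeometric probabilities of all
tables at the observed margins that are no more probable than the observed
table. The implementation enumerates the hypergeometric support in exact
integer arithmetic (a multiplicative recurrence on the integer weights
C(n1, x)·C(n2, k−x), which divides exactly), so tie decisions are
bit-stable and independent of floating-point epsilons; agreement with an
independent enumeration oracle and with a reference implementation is part
of the test suite. Direction is assigned by the sign of
level_treat − level_ctrl when p ≤ 0.01 (default) and |Δlevel| clears an
optional floor; otherwise the record is `ns`. Transcript-level summaries
count a gene hyper (hypo) if it has at least one hyper (hypo) site and
none of the opposite direction; genes with both are reported as `mixed`
rather than silently assigned — the treatment of conflicting multi-site
transcripts is genuinely open, and an explicit category keeps the two
totals interpretable.

## Distribution analytics

Region annotation projects a site into spliced coordinates of one
deterministic representative transcript per gene (the longest coding
model; ties broken by id). The start and stop codon regions are exactly
the three CDS-terminal nucleotides and take precedence over CDS; with the
generator's minimum CDS of 6 nt they never overlap. Metagene projection
maps a site to [0, 3): region index (0 = 5′UTR, 1 = CDS, 2 = 3′UTR) plus
the fractional position within the region; the `median_rescaled` mode
instead makes region widths proportional to the transcriptome's median
region lengths (normalised to total 3) before placing the fraction, the
convention used by metagene plotting tools. Context classes are read from
the two bases 3′ of the cytosine on its own strand: next base G → CG, else
next-next G → CHG, else CHH (H = A, C or U); windows are 21 nt, padded
with N at chromosome ends, and any N in the decisive span excludes the
site with a log entry. The position-frequency matrix normalises each
column over non-N counts (T reported as U). The two-proportion test is a
chi-square without continuity correction, falling back to the Fisher exact
test when any expected cell is ≤ 5; the inclusive boundary is deliberate
so that borderline small-sample tables get the exact test.

## RBP overlap

A site hits an interval iff start ≤ pos < end on the same chromosome;
strand is ignored by default because public RBP binding-site exports mix
stranded and unstranded records (unstranded intervals match either strand
even in `same` mode). Two normalisations are kept side by side because
they answer different questions: `fraction_known_rbps` =
binding sites containing ≥ 1 site / binding sites, and `m5c_per_rbp` =
sites inside the track / total sites. The pooled record uses the merged
(union) track, so self-concatenation of a track changes nothing. The
between-condition difference is (treat − ctrl)/treat, undefined (reported
missing) when the treatment value is 0.

## Expression integration

Fold change is linear with a 0.5 pseudocount on the means,
FC = (mean_treat + 0.5)/(mean_ctrl + 0.5); up requires FC > 1.5, down
FC < 1/1.5 (symmetric reciprocal reading of "|FC| > 1.5"), both at
p < 0.01 with strict inequalities. The built-in DE test is a deliberately
simple two-sample t-test on log2 counts-per-million — a placeholder that
any external DE table (gene_id, log2fc, pvalue) bypasses. The 0.01
threshold is the default; 0.05 is equally valid for the methylated-DEG
join and is exposed as a parameter rather than asserted as canonical. The
four-quadrant table admits only genes significant on both axes, excludes
mixed-methylation genes with a log entry, and its counts partition that
join exactly (asserted in tests). The methylation–expression relationship
is summarised by Pearson correlation between per-gene mean Δlevel and
log2FC.

## Synthetic-data generator

The generator emulates exactly the structure the analysis assumes, which
is what makes ground-truth recovery tests meaningful:

- **Genome**: i.i.d. bases at a configurable GC content (default 0.5),
  default 3 chromosomes × 60 kb.
- **Transcriptome**: default 40 non-overlapping single-isoform genes on
  both strands, 1–3 exons, 5′UTR 60–240 nt, CDS 180–720 nt (multiple of
  3), 3′UTR 60–300 nt, introns 60–200 nt.
- **Methylation truth**: default 300 sites planted only on transcript-sense
  cytosines; non-differential sites share one level drawn from
  {0.2, 0.35, 0.5, 0.65, 0.8}; a fraction (default 0.3) differ between
  conditions by exactly the configured effect (default 0.4), hyper and
  hypo in equal proportion, with the lower level drawn from U(0.1, 0.5).
- **Pileups**: every transcript-sense cytosine appears in every replicate
  of both conditions; coverage ~ NB(mean 50, size 10) per site per
  replicate, and c ~ Binomial(n, π + (1−π)·ncr) with non-conversion rate
  ncr = 0.005. Incomplete conversion is the only error mode; sequencing
  miscalls are folded into it, keeping the caller's null exact.
- **Expression**: per-gene NB counts (baseline mean 200, lognormal spread,
  dispersion 0.1); a DE fraction (default 0.3) gets |log2FC| ∈ [1, 2.5].
- **RBP tracks**: default 6 tracks × 40 intervals of 30 nt inside
  transcript spans; an enrichment fraction (default 0.3) is placed to
  cover a planted site.

Determinism: every operation draws from `default_rng([seed, stage_tag])`,
so stages are independent and runs are byte-reproducible across platforms.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: alignment and mapping artifacts, C→T SNPs
masquerading as non-conversion, RNA structure-dependent conversion
resistance, coverage correlation along transcripts, isoform ambiguity
(one isoform per gene by construction), overlapping genes, and
condition-dependent library composition. The recovery numbers certify the
estimator and tests against the stated stochastic model, not against
protocol-specific biases.

## Problem sizes and tolerances

The calibration checks run at ~2,200 planted sites on a 4 × 120 kb genome
with 150 genes: level recovery at coverage ~100× (observed MAE ≈ 0.021
against a < 0.03 bound — the binomial standard error of a pooled 300×
estimate is ≈ 0.029 at level 0.5), differential sensitivity at Δ = 0.4 and
coverage ~50× (≥ 0.90 required; the pooled Fisher test is essentially
saturated there), and null specificity (≤ 0.02 false differential calls at
p ≤ 0.01; Fisher is conservative on discrete tables so the observed rate
sits near 0.01). The Fisher implementation is checked exhaustively against
enumeration for every 2×2 table with total ≤ 40 (135,750 tables), interval
overlap against a quadratic all-pairs oracle at 1,000 × 1,000, and context
classification against a pattern oracle on all 16 neighbour pairs plus
10,000 random windows. These sizes keep the whole suite under a minute on
one CPU while leaving the statistical bounds comfortably non-trivial.

## Known limitations

- The site-level test assumes a known, position-independent non-conversion
  rate; real protocols show transcript-specific conversion resistance.
- Pooling replicates by summation ignores between-replicate
  overdispersion; a beta-binomial model would be the natural extension.
- The built-in DE test is underpowered relative to purpose-built
  negative-binomial DE methods and exists to close the loop on synthetic
  data; external DE tables are first-class input.
- Multi-isoform genes are reduced to one representative transcript for
  region annotation and metagene projection.
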