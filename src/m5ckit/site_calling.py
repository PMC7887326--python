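"""Per-cytosine methylation estimation and credible m5C site calling.

A cytosine is called in a condition only if in *every* replicate its
methylation level is >= ``min_level`` (default 0.1), its coverage is
>= ``min_coverage`` (default 10) and its binomial non-conversion p-value is
<= ``alpha``.  The emitted level/coverage are pooled by summing counts
across replicates.  All thresholds are inclusive (>=).
"""
from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SITE_KEY, TranscriptModel

logger = logging.getLogger(__name__)


def methylation_level(c_count: int, t_count: int) -> float:
    """Methylation level = unconverted / total reads at a cytosine."""
    if c_count < 0 or t_count < 0:
        raise ValueError("counts must be non-negative")
    total = c_count + t_count
    if total == 0:
        raise ValueError("zero coverage: methylation level is undefined")
    return c_count / total


def site_pvalue(c_count: int, coverage: int, non_conversion_rate: float) -> float:
    """Upper-tail binomial P(X >= c_count | n=coverage, p=non_conversion_rate).

    The null hypothesis is an unmethylated cytosine whose residual C signal
    comes only from incomplete bisulfite conversion.
    """
    if not (0.0 < non_conversion_rate < 0.5):
        raise ValueError("non_conversion_rate must lie in (0, 0.5)")
    if c_count < 0 or coverage < 1:
        raise ValueError("need 0 <= c_count <= coverage, coverage >= 1")
    if c_count > coverage:
        raise ValueError("c_count exceeds coverage")
    # sf(k-1) = P(X >= k); clamp away float underflow so p stays in (0, 1]
    return float(
        np.clip(stats.binom.sf(c_count - 1, coverage, non_conversion_rate), 1e-300, 1.0)
    )


def _attach_genes(
    sites: pd.DataFrame, transcriptome: list[TranscriptModel] | None
) -> pd.DataFrame:
    if transcriptome is None or sites.empty:
        if "gene" not in sites.columns:
            sites = sites.assign(gene="")
        return sites
    genes = []
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for m in transcriptome:
        by_chrom.setdefault(m.chrom, []).append(m)
    for row in sites.itertuples():
        gene = ""
        for m in by_chrom.get(row.chrom, []):
            if m.strand == row.strand and m.start <= row.pos < m.end:
                if m.genomic_to_spliced(row.pos) is not None:
                    gene = m.gene_id
                    break
        genes.append(gene)
    sites = sites.copy()
    sites["gene"] = genes
    return sites


def call_sites(
    pileups: pd.DataFrame,
    min_level: float = 0.1,
    min_coverage: int = 10,
    alpha: float = 0.05,
    non_conversion_rate: float = 0.005,
    require_all_replicates: bool = True,
    fdr: bool = False,
    transcriptome: list[TranscriptModel] | None = None,
) -> dict[str, pd.DataFrame]:
    """Call credible m5C sites per condition from a long pileup table.

    Returns ``{condition: sites DataFrame}`` with columns
    (chrom, pos, strand, gene, level, coverage, pvalue), level/coverage
    pooled over replicates by summing counts.  ``fdr=True`` replaces the
    per-replicate raw p-value threshold with a Benjamini-Hochberg adjusted
    one across the candidate cytosines of each replicate.
    """
    if pileups is None or len(pileups) == 0:
        raise ValueError("empty pileup set")
    df = pileups.copy()
    df["coverage"] = df["c_count"] + df["t_count"]
    covered = df["coverage"] > 0
    df["level"] = 0.0
    df.loc[covered, "level"] = df.loc[covered, "c_count"] / df.loc[covered, "coverage"]
    df["pvalue"] = 1.0
    df.loc[covered, "pvalue"] = stats.binom.sf(
        df.loc[covered, "c_count"] - 1,
        df.loc[covered, "coverage"],
        non_conversion_rate,
    )

    out: dict[str, pd.DataFrame] = {}
    for cond, sub in df.groupby("condition", sort=True):
        sub = sub.copy()
        n_expected = sub["replicate"].nunique()
        if fdr:
            sub["p_eff"] = np.nan
            for _rep, reps in sub.groupby("replicate"):
                adj = stats.false_discovery_control(reps["pvalue"].to_numpy())
                sub.loc[reps.index, "p_eff"] = adj
        else:
            sub["p_eff"] = sub["pvalue"]
        sub["ok"] = (
            (sub["coverage"] >= min_coverage)
            & (sub["level"] >= min_level)
            & (sub["p_eff"] <= alpha)
            & covered.reindex(sub.index, fill_value=False)
        )
        grouped = sub.groupby(SITE_KEY, sort=True)
        agg = grouped.agg(
            n_rep=("replicate", "nunique"),
            all_ok=("ok", "all"),
            c_sum=("c_count", "sum"),
            t_sum=("t_count", "sum"),
            min_lvl=("level", "min"),
            max_lvl=("level", "max"),
        ).reset_index()
        n_candidates = len(agg)
        passing = agg["all_ok"]
        if require_all_replicates:
            incomplete = agg["n_rep"] != n_expected
            if incomplete.any():
                logger.warning(
                    "%s: %d site(s) missing replicates were rejected",
                    cond,
                    int(incomplete.sum()),
                )
            passing = passing & ~incomplete
        called = agg[passing].copy()
        called["coverage"] = called["c_sum"] + called["t_sum"]
        called["level"] = called["c_sum"] / called["coverage"]
        called["pvalue"] = np.clip(
            stats.binom.sf(called["c_sum"] - 1, called["coverage"], non_conversion_rate),
            1e-300,
            1.0,
        )
        called = called[SITE_KEY + ["level", "coverage", "pvalue"]].reset_index(drop=True)
        called = _attach_genes(called, transcriptome)
        called = called[["chrom", "pos", "strand", "gene", "level", "coverage", "pvalue"]]
        logger.info(
            "%s: %d candidate cytosines -> %d credible sites "
            "(level >= %g, coverage >= %d, alpha %g, all replicates=%s)",
            cond, n_candidates, len(called), min_level, min_coverage, alpha,
            require_all_replicates,
        )
        out[cond] = called
    return out


def sites_overlap_summary(
    sites_cond_a: pd.DataFrame, sites_cond_b: pd.DataFrame
) -> dict[str, tuple[int, int, int]]:
    """Shared / A-only / B-only counts at site and gene granularity.

    Site identity is (chrom, pos, strand); gene identity is the annotated
    gene id (sites without a gene are ignored at gene granularity).
    """
    a_keys = {tuple(r) for r in sites_cond_a[SITE_KEY].itertuples(index=False)}
    b_keys = {tuple(r) for r in sites_cond_b[SITE_KEY].itertuples(index=False)}
    a_genes = {g for g in sites_cond_a.get("gene", pd.Series(dtype=str)) if g}
    b_genes = {g for g in sites_cond_b.get("gene", pd.Series(dtype=str)) if g}
    return {
        "site": (
            len(a_keys & b_keys),
            len(a_keys - b_keys),
            len(b_keys - a_keys),
        ),
        "gene": (
            len(a_genes & b_genes),
            len(a_genes - b_genes),
            len(b_genes - a_genes),
        ),
    }
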