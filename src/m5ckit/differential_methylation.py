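"""Hyper-/hypomethylated site identification between two conditions.

Counts are pooled (summed) across replicates within each condition and each
candidate site is tested with a two-sided Fisher exact test on the 2x2
table [[c_ctrl, t_ctrl], [c_treat, t_treat]].  The two-sided rule is the
point-probability method: the p-value sums the hypergeometric probabilities
of all tables (at fixed margins) no more probable than the observed one.
"""
from __future__ import annotations

import logging
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SITE_KEY

logger = logging.getLogger(__name__)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Computed by exact integer hypergeometric enumeration, so tie decisions
    (tables exactly as probable as the observed one) are bit-stable: a
    table qualifies iff its integer weight C(n1, x) * C(n2, k - x) is
    <= the observed weight.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("table cells must be non-negative")
    n1, n2, k = a + b, c + d, a + c
    n = n1 + n2
    if n == 0:
        raise ValueError("all-zero table")
    lo, hi = max(0, k - n2), min(k, n1)
    # integer weights via an exact multiplicative recurrence
    weights = []
    w = comb(n1, lo) * comb(n2, k - lo)
    weights.append(w)
    for x in range(lo, hi):
        w = w * (n1 - x) * (k - x) // ((x + 1) * (n2 - k + x + 1))
        weights.append(w)
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w <= w_obs)
    total = sum(weights)
    return max(num / total, 1e-300)


def pearson_correlation(levels_x, levels_y) -> float:
    """Standard product-moment correlation of two paired vectors."""
    x = np.asarray(levels_x, dtype=float)
    y = np.asarray(levels_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def _pooled_counts(pileups: pd.DataFrame) -> pd.DataFrame:
    pooled = (
        pileups.groupby(SITE_KEY + ["condition"], sort=True)[["c_count", "t_count"]]
        .sum()
        .reset_index()
    )
    return pooled


def compare_conditions(
    sites_ctrl: pd.DataFrame,
    sites_treat: pd.DataFrame,
    pileups: pd.DataFrame,
    condition_ctrl: str = "control",
    condition_treat: str = "treated",
    p_threshold: float = 0.01,
    min_level_diff: float = 0.0,
) -> pd.DataFrame:
    """Differential methylation over the union of credible sites.

    Candidate sites are those credible in either condition; each needs
    pooled counts in both conditions (others are excluded and logged).
    Returns a DataFrame with columns (chrom, pos, strand, gene, level_a,
    level_b, pvalue, direction) plus the pooled count columns; ``level_a``
    is control, ``level_b`` treatment, and ``direction`` is ``hyper`` when
    the treatment level is significantly higher.
    """
    keys = pd.concat(
        [sites_ctrl[SITE_KEY], sites_treat[SITE_KEY]], ignore_index=True
    ).drop_duplicates()
    gene_map: dict[tuple, str] = {}
    for df in (sites_ctrl, sites_treat):
        if "gene" in df.columns:
            for r in df.itertuples():
                gene_map.setdefault((r.chrom, r.pos, r.strand), r.gene)
    pooled = _pooled_counts(pileups)
    wide = pooled.pivot_table(
        index=SITE_KEY,
        columns="condition",
        values=["c_count", "t_count"],
        aggfunc="sum",
    )
    rows = []
    n_missing = 0
    for r in keys.itertuples(index=False):
        key = (r.chrom, r.pos, r.strand)
        try:
            cc = wide.loc[key, ("c_count", condition_ctrl)]
            tc = wide.loc[key, ("t_count", condition_ctrl)]
            ct = wide.loc[key, ("c_count", condition_treat)]
            tt = wide.loc[key, ("t_count", condition_treat)]
        except KeyError:
            n_missing += 1
            continue
        if any(pd.isna(v) for v in (cc, tc, ct, tt)) or (cc + tc == 0) or (ct + tt == 0):
            n_missing += 1
            continue
        cc, tc, ct, tt = int(cc), int(tc), int(ct), int(tt)
        p = fisher_exact_two_sided(cc, tc, ct, tt)
        la = cc / (cc + tc)
        lb = ct / (ct + tt)
        delta = lb - la
        if p <= p_threshold and abs(delta) >= min_level_diff and delta != 0:
            direction = "hyper" if delta > 0 else "hypo"
        else:
            direction = "ns"
        rows.append(
            (r.chrom, r.pos, r.strand, gene_map.get(key, ""), la, lb, p, direction,
             cc, tc, ct, tt)
        )
    if n_missing:
        logger.info("%d candidate site(s) lacked counts in one condition", n_missing)
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "strand", "gene", "level_a", "level_b", "pvalue",
            "direction", "c_ctrl", "t_ctrl", "c_treat", "t_treat",
        ],
    )
    return out.sort_values(SITE_KEY, ignore_index=True)


def summarize_direction_counts(
    records: pd.DataFrame, granularity: str = "site"
) -> dict[str, int]:
    """Count hyper/hypo calls at site or transcript granularity.

    At transcript granularity a gene is hyper if it has >= 1 hyper site and
    no hypo site (and vice versa); genes with both directions are reported
    as ``mixed`` and belong to neither total.
    """
    if granularity not in ("site", "transcript"):
        raise ValueError(f"unknown granularity {granularity!r}")
    if records is None or len(records) == 0:
        return {"hyper": 0, "hypo": 0} if granularity == "site" else {
            "hyper": 0, "hypo": 0, "mixed": 0
        }
    if granularity == "site":
        vc = records["direction"].value_counts()
        return {"hyper": int(vc.get("hyper", 0)), "hypo": int(vc.get("hypo", 0))}
    sig = records[records["direction"].isin(["hyper", "hypo"])]
    sig = sig[sig["gene"] != ""]
    counts = {"hyper": 0, "hypo": 0, "mixed": 0}
    for _gene, sub in sig.groupby("gene"):
        dirs = set(sub["direction"])
        if dirs == {"hyper"}:
            counts["hyper"] += 1
        elif dirs == {"hypo"}:
            counts["hypo"] += 1
        else:
            counts["mixed"] += 1
    return counts
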