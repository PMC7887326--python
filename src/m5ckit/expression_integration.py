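"""Joint analysis of differential methylation and differential expression.

Genes are classified as differentially expressed when the linear fold
change exceeds 1.5 (or falls below 1/1.5) at p < 0.01, both strict
inequalities.  Significant genes on both axes are placed in a four-quadrant
table (hyper/hypo x up/down), and the overall methylation-expression
relationship is summarised by the Pearson correlation between the per-gene
methylation-level change and log2 fold change.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .differential_methylation import pearson_correlation

logger = logging.getLogger(__name__)

#: pseudocount used for fold changes on counts, avoids division by zero
FC_EPSILON = 0.5


def classify_deg(
    mean_ctrl: float,
    mean_treat: float,
    pvalue: float,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.01,
    epsilon: float = FC_EPSILON,
) -> str:
    """'up' / 'down' / 'ns' from condition means and a DE p-value.

    FC = (mean_treat + eps) / (mean_ctrl + eps); up iff FC > fc_threshold
    and p < p_threshold, down iff FC < 1 / fc_threshold (symmetric
    reciprocal rule) and p < p_threshold.
    """
    if mean_ctrl < 0 or mean_treat < 0:
        raise ValueError("expression means must be non-negative")
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    fc = (mean_treat + epsilon) / (mean_ctrl + epsilon)
    if pvalue < p_threshold:
        if fc > fc_threshold:
            return "up"
        if fc < 1.0 / fc_threshold:
            return "down"
    return "ns"


def expression_test(counts_ctrl, counts_treat) -> float:
    """Two-sample t-test on log2-transformed normalised counts for one gene.

    A deliberately simple placeholder DE test; any external DE table
    (gene_id, log2fc, pvalue) can be supplied downstream instead.
    """
    x = np.asarray(counts_ctrl, dtype=float)
    y = np.asarray(counts_treat, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 replicates per condition")
    lx, ly = np.log2(x + 1.0), np.log2(y + 1.0)
    if np.ptp(np.concatenate([lx, ly])) == 0:
        raise ValueError("zero variance across all replicates")
    t = stats.ttest_ind(lx, ly, equal_var=True)
    p = float(t.pvalue)
    return 1.0 if np.isnan(p) else p


def differential_expression_table(counts: pd.DataFrame,
                                  condition_ctrl: str = "control",
                                  condition_treat: str = "treated") -> pd.DataFrame:
    """Per-gene DE table from a wide count matrix.

    ``counts`` must have a ``gene_id`` column plus ``<condition>_<rep>``
    columns.  Counts are normalised to counts-per-million before testing.
    Returns (gene_id, mean_ctrl, mean_treat, log2fc, pvalue).
    """
    ctrl_cols = [c for c in counts.columns if c.startswith(condition_ctrl + "_")]
    treat_cols = [c for c in counts.columns if c.startswith(condition_treat + "_")]
    if len(ctrl_cols) < 2 or len(treat_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")
    mat = counts[ctrl_cols + treat_cols].to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("a replicate has zero total counts")
    cpm = mat / lib * 1e6
    n_ctrl = len(ctrl_cols)
    rows = []
    for i, gene in enumerate(counts["gene_id"]):
        cc, ct = cpm[i, :n_ctrl], cpm[i, n_ctrl:]
        mean_ctrl, mean_treat = float(cc.mean()), float(ct.mean())
        lfc = float(np.log2((mean_treat + FC_EPSILON) / (mean_ctrl + FC_EPSILON)))
        try:
            p = expression_test(cc, ct)
        except ValueError:
            p = 1.0
        rows.append((gene, mean_ctrl, mean_treat, lfc, p))
    return pd.DataFrame(
        rows, columns=["gene_id", "mean_ctrl", "mean_treat", "log2fc", "pvalue"]
    )


def _gene_meth_directions(diff_records: pd.DataFrame) -> tuple[dict[str, str], int]:
    """Per-gene methylation direction; mixed genes excluded (count returned)."""
    sig = diff_records[diff_records["direction"].isin(["hyper", "hypo"])]
    sig = sig[sig["gene"] != ""]
    directions: dict[str, str] = {}
    n_mixed = 0
    for gene, sub in sig.groupby("gene"):
        dirs = set(sub["direction"])
        if len(dirs) == 1:
            directions[gene] = next(iter(dirs))
        else:
            n_mixed += 1
    return directions, n_mixed


def four_quadrant(
    diff_meth_records: pd.DataFrame,
    expression_records: pd.DataFrame,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.01,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Quadrant assignment for genes significant on both axes.

    Returns (per-gene records, counts dict over hyper-up / hyper-down /
    hypo-up / hypo-down).  Genes whose sites disagree on methylation
    direction are excluded and logged.
    """
    meth_dir, n_mixed = _gene_meth_directions(diff_meth_records)
    if n_mixed:
        logger.info("%d gene(s) with mixed methylation direction excluded", n_mixed)
    rows = []
    counts = {"hyper-up": 0, "hyper-down": 0, "hypo-up": 0, "hypo-down": 0}
    for r in expression_records.itertuples():
        md = meth_dir.get(r.gene_id)
        if md is None:
            continue
        ed = classify_deg(r.mean_ctrl, r.mean_treat, r.pvalue, fc_threshold, p_threshold)
        if ed == "ns":
            continue
        quadrant = f"{md}-{ed}"
        counts[quadrant] += 1
        rows.append((r.gene_id, md, ed, quadrant))
    table = pd.DataFrame(
        rows, columns=["gene_id", "meth_direction", "expr_direction", "quadrant"]
    )
    return table, counts


def meth_expr_correlation(
    diff_meth_records: pd.DataFrame, expression_records: pd.DataFrame
) -> float:
    """Pearson R between per-gene mean methylation change and log2FC."""
    meth = diff_meth_records[diff_meth_records["gene"] != ""].copy()
    if len(meth) == 0:
        raise ValueError("no annotated differential-methylation records")
    meth["delta"] = meth["level_b"] - meth["level_a"]
    per_gene = meth.groupby("gene")["delta"].mean()
    joined = expression_records.merge(
        per_gene.rename("delta"), left_on="gene_id", right_index=True
    )
    if len(joined) < 3:
        raise ValueError("need >= 3 joined genes for a correlation")
    return pearson_correlation(joined["delta"], joined["log2fc"])
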