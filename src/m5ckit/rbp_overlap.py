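"""Overlap statistics between m5C sites and RBP binding-site tracks.

Two normalisations are reported per RBP: the fraction of its binding sites
containing at least one m5C site, and the fraction of all m5C sites that
fall inside its binding sites.  The between-condition difference is
(value_treat - value_ctrl) / value_treat.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .datatypes import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RBPOverlapStats:
    rbp_name: str
    n_binding_sites: int
    n_binding_sites_with_m5c: int
    n_m5c_total: int
    n_m5c_in_binding: int

    def __post_init__(self) -> None:
        if self.n_binding_sites_with_m5c > self.n_binding_sites:
            raise ValueError("hit binding sites exceed total binding sites")
        if self.n_m5c_in_binding > self.n_m5c_total:
            raise ValueError("hit m5C sites exceed total m5C sites")

    @property
    def fraction_known_rbps(self) -> float:
        """Binding sites overlapping >= 1 m5C site / binding sites."""
        return self.n_binding_sites_with_m5c / self.n_binding_sites

    @property
    def m5c_per_rbp(self) -> float:
        """m5C sites inside the track / total m5C sites."""
        return self.n_m5c_in_binding / self.n_m5c_total

    @property
    def m5c_per_binding_site(self) -> float:
        """Alternative normalisation: m5C sites inside / binding sites."""
        return self.n_m5c_in_binding / self.n_binding_sites


def _strand_ok(site_strand: str, interval_strand: str, strand_mode: str) -> bool:
    if strand_mode == "ignore" or interval_strand == ".":
        return True
    return site_strand == interval_strand


def overlap_counts(
    sites: pd.DataFrame,
    intervals: Sequence[GenomicInterval],
    strand_mode: str = "ignore",
) -> tuple[int, int]:
    """(number of intervals containing >= 1 site, number of sites inside >= 1 interval).

    A site at ``pos`` hits the half-open interval [start, end) iff
    start <= pos < end on the same chromosome; with ``strand_mode='same'``
    the strands must also agree unless the interval is unstranded ('.').
    Both counts are deduplicated.
    """
    if strand_mode not in ("same", "ignore"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    trees: dict[str, IntervalTree] = {}
    for idx, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    hit_intervals: set[int] = set()
    n_sites_hit = 0
    for r in sites.itertuples():
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        hits = [
            h.data
            for h in tree.at(r.pos)
            if _strand_ok(r.strand, intervals[h.data].strand, strand_mode)
        ]
        if hits:
            n_sites_hit += 1
            hit_intervals.update(hits)
    return len(hit_intervals), n_sites_hit


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Strand-agnostic union of intervals (overlapping/adjacent runs merged)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted((iv.start, iv.end) for iv in by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e, ".", "merged"))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e, ".", "merged"))
    return merged


ALL_RBPS = "ALL"


def rbp_stats(
    sites: pd.DataFrame,
    rbp_tracks: Mapping[str, Sequence[GenomicInterval]],
    strand_mode: str = "ignore",
) -> list[RBPOverlapStats]:
    """Per-RBP overlap statistics plus a pooled record over the merged track.

    Empty tracks are skipped with a log entry (their fractions would divide
    by zero).
    """
    if not rbp_tracks:
        raise ValueError("need at least one RBP track")
    n_total = len(sites)
    out: list[RBPOverlapStats] = []
    all_ivs: list[GenomicInterval] = []
    for name in sorted(rbp_tracks):
        ivs = list(rbp_tracks[name])
        if not ivs:
            logger.warning("RBP %s: empty track skipped", name)
            continue
        all_ivs.extend(ivs)
        if n_total == 0:
            logger.warning("RBP %s: no m5C sites; record skipped", name)
            continue
        n_iv_hit, n_site_hit = overlap_counts(sites, ivs, strand_mode)
        out.append(RBPOverlapStats(name, len(ivs), n_iv_hit, n_total, n_site_hit))
    if all_ivs and n_total:
        merged = merge_intervals(all_ivs)
        n_iv_hit, n_site_hit = overlap_counts(sites, merged, strand_mode)
        out.append(
            RBPOverlapStats(ALL_RBPS, len(merged), n_iv_hit, n_total, n_site_hit)
        )
    return out


def condition_difference(
    stat_treat: RBPOverlapStats,
    stat_ctrl: RBPOverlapStats,
    which: str = "fraction_known_rbps",
) -> float | None:
    """(value_treat - value_ctrl) / value_treat for one RBP's statistic.

    Returns None when the treatment value is zero (difference undefined).
    """
    if which not in ("fraction_known_rbps", "m5c_per_rbp", "m5c_per_binding_site"):
        raise ValueError(f"unknown statistic {which!r}")
    if stat_treat.rbp_name != stat_ctrl.rbp_name:
        raise ValueError("statistics belong to different RBPs")
    vt = getattr(stat_treat, which)
    vc = getattr(stat_ctrl, which)
    if vt == 0:
        logger.warning("RBP %s: treatment value is zero; difference undefined",
                       stat_treat.rbp_name)
        return None
    return (vt - vc) / vt


def stats_table(stats_list: Sequence[RBPOverlapStats]) -> pd.DataFrame:
    rows = [
        (
            s.rbp_name, s.n_binding_sites, s.n_binding_sites_with_m5c,
            s.n_m5c_total, s.n_m5c_in_binding,
            s.fraction_known_rbps, s.m5c_per_rbp,
        )
        for s in stats_list
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "rbp_name", "n_binding_sites", "n_binding_sites_with_m5c",
            "n_m5c_total", "n_m5c_in_binding", "fraction_known_rbps", "m5c_per_rbp",
        ],
    )
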