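"""End-to-end orchestration: simulate -> call -> diff -> profile -> rbp -> integrate.

One flat YAML-style config drives every stage; the validated config is
echoed into the output directory and a run manifest records seeds, stage
outputs and row counts.  Re-running with the same config and seed
reproduces byte-identical TSV outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from . import differential_methylation as dm
from . import distribution_profiling as dp
from . import expression_integration as ei
from . import io_formats as io
from . import rbp_overlap as ro
from . import site_calling as sc
from . import synthetic_data as sd
from .synthetic_data import CONDITION_A, CONDITION_B, SimulationConfig

logger = logging.getLogger(__name__)

#: analysis-stage defaults; the thresholds are the credibility and
#: significance rules the pipeline applies throughout
ANALYSIS_DEFAULTS: dict[str, Any] = {
    "min_level": 0.1,
    "min_coverage": 10,
    "alpha": 0.05,
    "p_diff": 0.01,
    "min_level_diff": 0.0,
    "p_expr": 0.01,
    "fc_threshold": 1.5,
    "chrom_bin_size": 10_000,
    "metagene_scaling": "per_transcript",
    "strand_mode": "ignore",
}

_SIM_FIELDS = {f.name: f for f in dataclasses.fields(SimulationConfig)}
_TUPLE_FIELDS = {
    "utr5_range", "cds_codons_range", "utr3_range", "intron_range",
    "intergenic_range", "site_levels", "de_log2fc_range",
}

KNOWN_KEYS = set(_SIM_FIELDS) | set(ANALYSIS_DEFAULTS)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


def validate_config(config: Mapping[str, Any] | None) -> dict[str, Any]:
    """Normalise a flat config mapping: inject defaults, reject junk.

    Unknown keys raise (typo guard); out-of-range values raise with the
    field name.  Returns a plain dict with every known key present.
    """
    config = dict(config or {})
    config.setdefault("seed", 0)
    unknown = set(config) - KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    merged: dict[str, Any] = {}
    for name, f in _SIM_FIELDS.items():
        merged[name] = config.get(name, f.default)
    for name, default in ANALYSIS_DEFAULTS.items():
        merged[name] = config.get(name, default)
    for name in _TUPLE_FIELDS:
        merged[name] = tuple(merged[name])
    try:
        SimulationConfig(**{k: merged[k] for k in _SIM_FIELDS})
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    if not (0.0 <= merged["min_level"] <= 1.0):
        raise ConfigError(f"min_level must lie in [0, 1], got {merged['min_level']}")
    if merged["min_coverage"] < 1:
        raise ConfigError(f"min_coverage must be >= 1, got {merged['min_coverage']}")
    for key in ("alpha", "p_diff", "p_expr"):
        if not (0.0 < merged[key] <= 1.0):
            raise ConfigError(f"{key} must lie in (0, 1], got {merged[key]}")
    if merged["fc_threshold"] <= 1.0:
        raise ConfigError(f"fc_threshold must exceed 1, got {merged['fc_threshold']}")
    if merged["chrom_bin_size"] < 1:
        raise ConfigError("chrom_bin_size must be >= 1")
    if merged["metagene_scaling"] not in ("per_transcript", "median_rescaled"):
        raise ConfigError(f"unknown metagene_scaling {merged['metagene_scaling']!r}")
    if merged["strand_mode"] not in ("same", "ignore"):
        raise ConfigError(f"unknown strand_mode {merged['strand_mode']!r}")
    return merged


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a key/value mapping")
    return validate_config(raw)


def _sim_config(cfg: Mapping[str, Any]) -> SimulationConfig:
    return SimulationConfig(**{k: cfg[k] for k in _SIM_FIELDS})


# --------------------------------------------------------------------------
def run_pipeline(
    config: str | Path | Mapping[str, Any],
    out_dir: str | Path,
    force: bool = False,
) -> dict[str, Any]:
    """Execute all stages into ``out_dir`` and return the run manifest."""
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = validate_config(config)
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out} exists and is non-empty (use force=True / --force)"
        )
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg["seed"],
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in cfg.items()},
        "stages": {},
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(manifest["config"], fh, sort_keys=True)

    def record(stage: str, outputs: dict[str, Path], counts: dict[str, int]) -> None:
        manifest["stages"][stage] = {
            # relative paths keep the manifest byte-stable across run locations
            "outputs": {k: str(Path(p).relative_to(out)) for k, p in outputs.items()},
            "counts": counts,
        }
        logger.info("stage %s: %s", stage, counts)

    sim = _sim_config(cfg)

    # -- simulate ----------------------------------------------------------
    genome = sd.generate_genome(sim)
    transcriptome = sd.generate_transcriptome(genome, sim)
    truth = sd.plant_methylation(transcriptome, genome, sim)
    pileups = sd.simulate_pileups(truth, transcriptome, genome, sim)
    counts, gene_truth = sd.simulate_expression(transcriptome, sim)
    truth.genes = gene_truth
    tracks = sd.generate_rbp_tracks(transcriptome, truth, sim, genome)

    io.write_fasta(genome, out / "genome.fa")
    io.write_gtf(transcriptome, out / "annotation.gtf")
    io.write_site_table(pileups, out / "pileup.tsv", kind="pileup")
    counts.to_csv(out / "expression.tsv", sep="\t", index=False)
    truth.sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    for name, ivs in tracks.items():
        io.write_bed(ivs, out / f"rbp_{name}.bed")
    record(
        "simulate",
        {
            "genome": out / "genome.fa",
            "annotation": out / "annotation.gtf",
            "pileup": out / "pileup.tsv",
            "expression": out / "expression.tsv",
            "truth_sites": out / "truth_sites.tsv",
            "truth_genes": out / "truth_genes.tsv",
        },
        {
            "chromosomes": len(genome),
            "transcripts": len(transcriptome),
            "planted_sites": len(truth.sites),
            "pileup_rows": len(pileups),
            "rbp_tracks": len(tracks),
        },
    )

    # -- call --------------------------------------------------------------
    called = sc.call_sites(
        pileups,
        min_level=cfg["min_level"],
        min_coverage=cfg["min_coverage"],
        alpha=cfg["alpha"],
        non_conversion_rate=cfg["non_conversion_rate"],
        transcriptome=transcriptome,
    )
    site_paths = {}
    for cond, sites in called.items():
        p = out / f"sites_{cond}.tsv"
        io.write_site_table(sites, p, kind="sites")
        site_paths[cond] = p
    overlap = sc.sites_overlap_summary(
        called.get(CONDITION_A, pd.DataFrame(columns=list(io.SITE_COLUMNS))),
        called.get(CONDITION_B, pd.DataFrame(columns=list(io.SITE_COLUMNS))),
    )
    record(
        "call",
        {cond: p for cond, p in site_paths.items()},
        {
            **{f"sites_{cond}": len(df) for cond, df in called.items()},
            "sites_shared": overlap["site"][0],
            "genes_shared": overlap["gene"][0],
        },
    )

    # -- diff --------------------------------------------------------------
    diff = dm.compare_conditions(
        called[CONDITION_A],
        called[CONDITION_B],
        pileups,
        p_threshold=cfg["p_diff"],
        min_level_diff=cfg["min_level_diff"],
    )
    io.write_site_table(diff, out / "diff.tsv", kind="diff")
    tx_counts = dm.summarize_direction_counts(diff, "transcript")
    record(
        "diff",
        {"diff": out / "diff.tsv"},
        {
            "records": len(diff),
            "hyper_sites": int((diff["direction"] == "hyper").sum()),
            "hypo_sites": int((diff["direction"] == "hypo").sum()),
            **{f"{k}_transcripts": v for k, v in tx_counts.items()},
        },
    )

    # -- profile (per condition) --------------------------------------------
    profile_dir = out / "profile"
    profile_dir.mkdir(exist_ok=True)
    reps = dp.representative_transcripts(transcriptome)
    medians = dp.region_length_medians(transcriptome)
    chrom_lengths = {c: len(g) for c, g in genome.items()}
    profile_counts: dict[str, int] = {}
    profile_outputs: dict[str, Path] = {}
    for cond, sites in called.items():
        regions = dp.region_counts(sites, transcriptome)
        regions.to_csv(profile_dir / f"region_counts_{cond}.tsv", sep="\t", index=False)

        meta_rows = []
        for r in sites.itertuples():
            model = reps.get(r.gene)
            if model is None:
                continue
            x = dp.metagene_coordinate(
                r.pos, model, cfg["metagene_scaling"], region_medians=medians
            )
            if x is not None:
                meta_rows.append((r.chrom, r.pos, r.strand, r.gene, x))
        pd.DataFrame(
            meta_rows, columns=["chrom", "pos", "strand", "gene", "scaled_pos"]
        ).to_csv(profile_dir / f"metagene_{cond}.tsv", sep="\t", index=False)

        windows, ctx_rows = [], []
        for r in sites.itertuples():
            w = dp.extract_window(genome, r.chrom, r.pos, r.strand)
            windows.append(w)
            ctx = dp.classify_context(w)
            if ctx is not None:
                ctx_rows.append((r.chrom, r.pos, r.strand, ctx))
        contexts = pd.DataFrame(ctx_rows, columns=["chrom", "pos", "strand", "context"])
        contexts.to_csv(profile_dir / f"contexts_{cond}.tsv", sep="\t", index=False)
        if windows:
            dp.position_frequency_matrix(windows).to_csv(
                profile_dir / f"pfm_{cond}.tsv", sep="\t"
            )
        dp.sites_per_gene_distribution(sites).to_csv(
            profile_dir / f"sites_per_gene_{cond}.tsv", sep="\t", index=False
        )
        bins, totals = dp.chromosome_density(sites, chrom_lengths, cfg["chrom_bin_size"])
        dens_rows = [
            (chrom, i, int(v))
            for chrom in sorted(bins)
            for i, v in enumerate(bins[chrom])
        ]
        pd.DataFrame(dens_rows, columns=["chrom", "bin", "count"]).to_csv(
            profile_dir / f"chrom_density_{cond}.tsv", sep="\t", index=False
        )
        profile_counts[f"{cond}_sites_profiled"] = len(sites)
        profile_outputs[f"region_counts_{cond}"] = profile_dir / f"region_counts_{cond}.tsv"
    record("profile", profile_outputs, profile_counts)

    # -- rbp ----------------------------------------------------------------
    stats_by_cond = {
        cond: ro.rbp_stats(sites, tracks, strand_mode=cfg["strand_mode"])
        for cond, sites in called.items()
    }
    frames = []
    for cond, stats_list in stats_by_cond.items():
        t = ro.stats_table(stats_list)
        t.insert(0, "condition", cond)
        frames.append(t)
    rbp_table = pd.concat(frames, ignore_index=True)
    ctrl_by_name = {s.rbp_name: s for s in stats_by_cond.get(CONDITION_A, [])}
    diff_rows = []
    for s in stats_by_cond.get(CONDITION_B, []):
        c = ctrl_by_name.get(s.rbp_name)
        if c is None:
            continue
        for which in ("fraction_known_rbps", "m5c_per_rbp"):
            v = ro.condition_difference(s, c, which)
            diff_rows.append((s.rbp_name, which, v if v is not None else float("nan")))
    rbp_diff = pd.DataFrame(diff_rows, columns=["rbp_name", "statistic", "difference"])
    rbp_table.to_csv(out / "rbp_stats.tsv", sep="\t", index=False)
    rbp_diff.to_csv(out / "rbp_difference.tsv", sep="\t", index=False)
    record(
        "rbp",
        {"stats": out / "rbp_stats.tsv", "difference": out / "rbp_difference.tsv"},
        {"records": len(rbp_table)},
    )

    # -- integrate -----------------------------------------------------------
    de = ei.differential_expression_table(counts)
    de.to_csv(out / "de.tsv", sep="\t", index=False)
    quadrants, quad_counts = ei.four_quadrant(
        diff, de, fc_threshold=cfg["fc_threshold"], p_threshold=cfg["p_expr"]
    )
    quadrants.to_csv(out / "quadrants.tsv", sep="\t", index=False)
    try:
        r = ei.meth_expr_correlation(diff, de)
    except ValueError:
        r = float("nan")
    summary = {"pearson_r_meth_expr": r, **quad_counts}
    with open(out / "integration_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    record(
        "integrate",
        {
            "de": out / "de.tsv",
            "quadrants": out / "quadrants.tsv",
            "summary": out / "integration_summary.json",
        },
        {"de_genes": len(de), "quadrant_genes": len(quadrants)},
    )

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
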