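"""End-to-end orchestration: load -> scan -> window -> test -> stratify.

``run_full_analysis`` executes the stages in a fixed order and returns
a single provenance-stamped report (config echo, seed, per-stage
results). Optional stages (promoters, cytobands, cohorts, null model)
are skipped with a logged notice when their inputs are missing or
their preconditions (non-empty classes) fail.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import chromatin_breakdown, cohort_compare, promoter_breakdown
from .config import AnalysisConfig
from .cooccurrence import (
    distance_distribution,
    proximity_summary,
    summarize_window_contrast,
)
from .io_formats import (
    BreakpointTable,
    GenomeSequence,
    RegionSet,
    dedupe_breakpoints,
    read_breakpoints,
    read_cytoband,
    read_fasta,
    read_regions_bed,
    write_breakpoints_bed,
)
from .motif_scan import (
    build_pwm,
    pwm_conservation,
    scan_cpg,
    scan_cryptic_nonamers,
    write_cpgs_bed,
    write_hits_bed,
    write_pwm_tsv,
)
from .null_model import empirical_p, iterate_null, pct_windows_with_cpg, \
    pct_windows_with_pair
from .window_analysis import (
    breaks_per_mb,
    classify_windows,
    count_features_in_windows,
    tile_windows,
)

log = logging.getLogger("fragscan")


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def analyse(
    config: AnalysisConfig,
    genome: GenomeSequence,
    breaks: BreakpointTable,
    promoters: RegionSet | None = None,
    cytobands: RegionSet | None = None,
) -> dict:
    """Run the full analysis on in-memory inputs; returns the report dict."""
    breaks.validate_against(genome)
    deduped, n_dup = dedupe_breakpoints(breaks)
    log.info("dedupe: %d records -> %d unique breaks", len(breaks), len(deduped))

    hits = scan_cryptic_nonamers(genome, config)
    cpgs = scan_cpg(genome)
    log.info("scan: %d cryptic nonamer hits, %d CpG sites", len(hits), len(cpgs))

    density, per_chrom, corr = breaks_per_mb(deduped, genome)

    per_size: dict[int, dict] = {}
    windows_by_size: dict[int, pd.DataFrame] = {}
    for size in config.window_sizes:
        windows = tile_windows(genome, size)
        stats = count_features_in_windows(windows, deduped, hits, cpgs, genome, config)
        # internal audit: per-window counts must conserve totals
        assert int(stats["n_breaks"].sum()) == len(deduped)
        assert int(stats["n_nonamers"].sum()) == len(hits)
        assert int(stats["n_cpgs"].sum()) == len(cpgs)
        cls = classify_windows(stats, config.min_breaks_per_window)
        entry: dict = {"window_size": size, "class_sizes": cls.sizes}
        if len(cls.broken) and len(cls.unbroken):
            entry["contrast"] = summarize_window_contrast(cls)
        else:
            log.info("window size %d: a class is empty, contrast skipped", size)
        per_size[size] = entry
        windows_by_size[size] = stats

    prox = proximity_summary(deduped, hits, cpgs, config.breakpoint_radius)
    dist = distance_distribution(deduped, hits, cpgs, config)

    # null model on the smallest window size
    null_entry = None
    size0 = min(config.window_sizes)
    stats0 = windows_by_size[size0]
    cls0 = classify_windows(stats0, config.min_breaks_per_window)
    if len(cls0.broken):
        try:
            null_cpg = iterate_null(
                stats0, cls0.broken, config.null_iterations, config.random_seed,
                pct_windows_with_cpg, config.gc_tolerance,
            )
            null_pair = iterate_null(
                stats0, cls0.broken, config.null_iterations, config.random_seed,
                pct_windows_with_pair, config.gc_tolerance,
            )
            obs_cpg = float(cls0.broken["has_cpg"].mean() * 100)
            obs_pair = float(cls0.broken["has_pair"].mean() * 100)
            null_entry = {
                "window_size": size0,
                "iterations": config.null_iterations,
                "pct_with_cpg": {
                    "observed": obs_cpg,
                    "null": null_cpg.summary()[0],
                    "empirical_p_upper": empirical_p(obs_cpg, null_cpg, "upper"),
                },
                "pct_with_pair": {
                    "observed": obs_pair,
                    "null": null_pair.summary()[0],
                    "empirical_p_upper": empirical_p(obs_pair, null_pair, "upper"),
                },
            }
        except ValueError as exc:
            log.info("null model skipped: %s", exc)

    strat: dict = {}
    if promoters is not None and len(promoters):
        strat["promoter"] = promoter_breakdown(deduped, promoters, hits, cpgs, config)
    else:
        log.info("no promoter regions supplied; promoter stage skipped")
    if cytobands is not None and len(cytobands):
        strat["chromatin"] = chromatin_breakdown(deduped, hits, cpgs, cytobands, config)
    else:
        log.info("no cytobands supplied; chromatin stage skipped")

    cohorts = set(deduped.df["cohort"]) - {"unlabeled"}
    if len(cohorts) == 2:
        by_cohort = {}
        for cohort in sorted(cohorts):
            sub = BreakpointTable(
                deduped.df[deduped.df["cohort"] == cohort].reset_index(drop=True)
            )
            stats_c = count_features_in_windows(
                tile_windows(genome, size0), sub, hits, cpgs, genome, config
            )
            broken_c = classify_windows(stats_c, config.min_breaks_per_window).broken
            if len(broken_c):
                by_cohort[cohort] = broken_c
        if len(by_cohort) == 2:
            strat["cohort"] = cohort_compare(by_cohort)
        else:
            log.info("a cohort has no broken windows; cohort stage skipped")

    pwm_entry = None
    if len(hits):
        pwm, n_pwm = build_pwm(hits)
        pwm_entry = {
            "matrix": pwm.tolist(),
            "n_hits": n_pwm,
            "conservation": pwm_conservation(pwm, 0.6).to_dict(orient="records"),
        }

    report = {
        "software": {"name": "fragscan", "version": __version__},
        "config": config.to_dict(),
        "seed": config.random_seed,
        "genome": {"chromosomes": genome.lengths, "total_length": genome.total_length},
        "breaks": {
            "n_records": len(breaks),
            "n_unique": len(deduped),
            "n_duplicates_removed": n_dup,
        },
        "totals": {"n_nonamer_hits": len(hits), "n_cpgs": len(cpgs)},
        "breaks_per_mb": {
            "density": density,
            "length_correlation_r": None if np.isnan(corr) else corr,
            "per_chromosome": per_chrom.to_dict(orient="records"),
        },
        "windows": {str(k): v for k, v in per_size.items()},
        "proximity": prox.to_dict(),
        "distances": dist.to_dict(),
        "null_model": null_entry,
        "stratified": strat,
        "pwm": pwm_entry,
    }
    report["_tables"] = {
        "windows_by_size": windows_by_size,
        "hits": hits,
        "cpgs": cpgs,
        "deduped_breaks": deduped,
        "distances_per_break": dist.per_break,
    }
    return report


def run_full_analysis(
    config: AnalysisConfig,
    genome_path: str | Path,
    breaks_path: str | Path,
    breaks_dialect: str = "tsv",
    promoters_path: str | Path | None = None,
    cytoband_path: str | Path | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """File-based entry point; optionally writes the run directory.

    Outputs: report.json, windows_<size>.tsv, hits.bed, cpgs.bed,
    distances.tsv, null.tsv (when the null stage ran), pwm.tsv.
    """
    genome = read_fasta(genome_path)
    breaks = read_breakpoints(breaks_path, breaks_dialect)
    promoters = read_regions_bed(promoters_path) if promoters_path else None
    cytobands = read_cytoband(cytoband_path) if cytoband_path else None
    report = analyse(config, genome, breaks, promoters, cytobands)
    report["inputs"] = {
        "genome": {"path": str(genome_path), "sha256_16": _digest(genome_path)},
        "breaks": {"path": str(breaks_path), "sha256_16": _digest(breaks_path)},
    }
    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = report.pop("_tables", None)
    (outdir / "report.json").write_text(json.dumps(report, indent=1) + "\n")
    if tables:
        for size, stats in tables["windows_by_size"].items():
            stats.to_csv(outdir / f"windows_{size}.tsv", sep="\t", index=False)
        write_hits_bed(tables["hits"], outdir / "hits.bed")
        write_cpgs_bed(tables["cpgs"], outdir / "cpgs.bed")
        write_breakpoints_bed(tables["deduped_breaks"], outdir / "breaks.bed")
        tables["distances_per_break"].to_csv(
            outdir / "distances.tsv", sep="\t", index=False
        )
        if report.get("pwm"):
            write_pwm_tsv(np.array(report["pwm"]["matrix"]), outdir / "pwm.tsv")
        report["_tables"] = tables
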