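#!/usr/bin/env python
"""CpG-nonamer distances and promoter/chromatin/cohort stratification.

Measures the per-break minimal CpG-nonamer gap in fragile vs control
fixtures, the proximity fractions in the designed breakpoint cohort,
and the promoter, chromatin-class and lymphoid-vs-nonlymphoid
breakdowns. Writes results/strata/.
"""

import argparse
import json
from pathlib import Path

from fragscan.annotation import chromatin_breakdown, cohort_compare, \
    promoter_breakdown
from fragscan.cooccurrence import distance_distribution, proximity_summary
from fragscan.io_formats import BreakpointTable, dedupe_breakpoints
from fragscan.motif_scan import scan_cpg, scan_cryptic_nonamers
from fragscan.synthetic import make_distance_fixture, make_proximity_cohort, \
    make_scenario
from fragscan.window_analysis import classify_windows, \
    count_features_in_windows, tile_windows


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/strata")
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = {}

    for kind in ("fragile", "control"):
        genome, breaks, _, cfg = make_distance_fixture(kind, args.seed)
        hits = scan_cryptic_nonamers(genome, cfg)
        cpgs = scan_cpg(genome)
        s = distance_distribution(breaks, hits, cpgs, cfg)
        s.per_break.to_csv(outdir / f"distances_{kind}.tsv", sep="\t", index=False)
        out[f"distances_{kind}"] = s.to_dict()
        print(
            f"{kind} regions: median CpG-nonamer gap {s.median:.0f} bp, "
            f"{s.fraction_within_gap_max:.0%} of breaks with gap <= "
            f"{s.pair_gap_max} bp"
        )

    genome, breaks, _, cfg = make_proximity_cohort(args.seed)
    deduped, _ = dedupe_breakpoints(breaks)
    prox = proximity_summary(
        deduped, scan_cryptic_nonamers(genome, cfg), scan_cpg(genome),
        cfg.breakpoint_radius,
    )
    out["proximity"] = prox.to_dict()
    print(
        f"proximity cohort (n={prox.n_breakpoints}): "
        f"{prox.fraction_with_nonamer:.0%} of breaks near a nonamer, "
        f"{prox.fraction_with_cpg:.0%} near a CpG, "
        f"{prox.fraction_with_both:.0%} near both"
    )

    sp = make_scenario("promoter_fixture", args.seed)
    dp, _ = dedupe_breakpoints(sp.breaks)
    hp, cp = scan_cryptic_nonamers(sp.genome, sp.config), scan_cpg(sp.genome)
    out["promoter"] = promoter_breakdown(dp, sp.promoters, hp, cp, sp.config)
    print(
        f"promoters: {out['promoter']['fraction_in_promoters']:.1%} of breaks "
        f"inside promoters; {out['promoter']['fraction_with_pair']:.0%} of "
        f"those with CpG-nonamer clustering"
    )

    sc = make_scenario("paper_like", args.seed)
    d, _ = dedupe_breakpoints(sc.breaks)
    h, c = scan_cryptic_nonamers(sc.genome, sc.config), scan_cpg(sc.genome)
    chrom = chromatin_breakdown(d, h, c, sc.cytobands, sc.config)
    out["chromatin"] = chrom
    print(
        f"chromatin: {chrom['strata']['euchromatin']['fraction_of_classified']:.0%} "
        f"of breaks in euchromatin, "
        f"{chrom['strata']['heterochromatin']['fraction_of_classified']:.0%} "
        f"in heterochromatin"
    )

    sco = make_scenario("cohort_fixture", args.seed)
    dco, _ = dedupe_breakpoints(sco.breaks)
    hco, cco = scan_cryptic_nonamers(sco.genome, sco.config), scan_cpg(sco.genome)
    by_cohort = {}
    for cohort in ("lymphoid", "nonlymphoid"):
        sub = BreakpointTable(
            dco.df[dco.df["cohort"] == cohort].reset_index(drop=True)
        )
        stats = count_features_in_windows(
            tile_windows(sco.genome, 100), sub, hco, cco, sco.genome, sco.config
        )
        by_cohort[cohort] = classify_windows(
            stats, sco.config.min_breaks_per_window
        ).broken
    rep = cohort_compare(by_cohort)
    out["cohort"] = rep
    ly, nl = rep["cohorts"]["lymphoid"], rep["cohorts"]["nonlymphoid"]
    print(
        f"cohorts: lymphoid broken windows carry {ly['mean_nonamers']:.1f} "
        f"nonamers / {ly['mean_cpgs']:.1f} CpGs per 100 bp vs nonlymphoid "
        f"{nl['mean_nonamers']:.1f} / {nl['mean_cpgs']:.1f} "
        f"(CpG ratio {rep['ratios']['mean_cpgs']:.2f})"
    )

    (outdir / "strata.json").write_text(json.dumps(out, indent=1) + "\n")


if __name__ == "__main__":
    main()
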