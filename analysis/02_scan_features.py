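#!/usr/bin/env python
"""Scan the fragile-site scenario genome for cryptic nonamers and CpGs.

Reports genome-wide feature totals and densities, exports hits and CpG
sites as BED, and writes the position weight matrix of all detected
nonamers (results/features/).
"""

import argparse
from pathlib import Path

from fragscan.motif_scan import (
    build_pwm,
    pwm_conservation,
    scan_cpg,
    scan_cryptic_nonamers,
    write_cpgs_bed,
    write_hits_bed,
    write_pwm_tsv,
)
from fragscan.synthetic import make_scenario


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/features")
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sc = make_scenario("paper_like", args.seed)
    hits = scan_cryptic_nonamers(sc.genome, sc.config)
    cpgs = scan_cpg(sc.genome)
    kb = sc.genome.total_length / 1000
    print(
        f"{len(hits)} cryptic nonamer hits (<= {sc.config.max_mismatch} "
        f"mismatches, both strands) = {len(hits)/kb:.2f}/kb; "
        f"{len(cpgs)} CpGs = {len(cpgs)/kb:.2f}/kb"
    )
    write_hits_bed(hits, outdir / "hits.bed")
    write_cpgs_bed(cpgs, outdir / "cpgs.bed")

    pwm, n = build_pwm(hits)
    write_pwm_tsv(pwm, outdir / "pwm.tsv")
    cons = pwm_conservation(pwm, 0.6)
    conserved = cons[cons["conserved"]]["position"].tolist()
    print(f"PWM from {n} hits; positions conserved at >= 60%: {conserved}")


if __name__ == "__main__":
    main()
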