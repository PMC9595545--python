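# fragscan

Chromosomal translocations in lymphoid cancers frequently break at loci
that carry two sequence features in close proximity: a **cryptic RSS
nonamer** — a 9-mer within 4 substitutions of the canonical
recombination-signal-sequence nonamer `ACAAAAACC` bound by the RAG1
nonamer-binding domain — and a **CpG dinucleotide**, whose methylated
cytosine deaminates into a T/G mismatch that RAGs can nick. `fragscan`
is the in-silico side of that model: a tested pipeline that scans a
genome for both features, clusters patient breakpoints into fixed-size
windows, and asks whether break-cluster windows are enriched for close
CpG–nonamer pairs relative to GC-matched unbroken controls.

It is aimed at genome scientists studying translocation fragility who
have breakpoint coordinates (e.g. from TICdb/COSMIC-style compilations
mapped to a reference) and want reproducible, statistically explicit
answers to:

* Where are the degenerate nonamers (≤ *k* mismatches, both strands)
  and CpGs, and how conserved are the detected nonamers (PWM)?
* Which 100 bp / 1 kb windows are break clusters (≥ 3 unique breaks)?
* Are nonamers, CpGs and CpG–nonamer pairs (edge gap ≤ 80 bp) enriched
  in broken windows? (χ², Mann–Whitney, Welch *t*, plus an empirical
  *p* from 1000 GC-matched resampling iterations.)
* How do the signatures stratify by promoter regions, Giemsa chromatin
  class (gneg vs gpos/gvar) and lymphoid vs nonlymphoid cohort?

Because the patient compilations are external data, the package ships a
first-class synthetic-data generator (`fragscan.synthetic`) that
produces genomes with planted nonamers, CpG–nonamer pairs at controlled
gaps, and breakpoints whose per-base rate is elevated inside fragile
footprints — with full ground truth, so every stage is testable
offline.

## The statistics in brief

For a breakpoint at position *p*, features are searched in the
symmetric context `[p − r, p + r + 1)` (default *r* = 100 bp). The
CpG–nonamer distance is the edge-to-edge gap (overlap ⇒ 0); a
*fragility pair* is a pair with gap ≤ 80 bp. Windows are non-overlapping
tiles; a window is *broken* when it holds ≥ 3 deduplicated breaks and
*unbroken* at exactly 0 (intermediate windows are excluded from
contrasts). The 2×2 χ² uses the closed form
`N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d))` (Yates optional); the null model
draws, per iteration, one unbroken control window per broken window
within ± 0.02 GC, and reports the add-one empirical *p*.

## Worked example

```bash
fragscan simulate paper_like --seed 1 --outdir scenario
fragscan run scenario/genome.fa scenario/breaks.tsv \
    --config-file scenario/config.json \
    --promoters scenario/promoters.bed --cytobands scenario/cytoband.tsv \
    --outdir run1
```

prints

```
322 unique breaks; 100.0% with nonamer, 100.0% with CpG within 100 bp; report in run1/report.json
```

and the equivalent library-level analysis (`analysis/03_window_contrast.py --seed 1`) reports

```
39 broken windows (mean 8.4 nonamers, 3.2 CpGs) vs 1960 unbroken (mean 0.38 nonamers); chi-square on pair presence = 24.6 (p = 7.22e-07)
GC-matched null (1000 x 39 windows): 66.0% of control windows carry a CpG (2.5-97.5 pct 51.3-79.5%); observed broken-window value 100.0% (empirical p = 0.000999)
```

i.e. the 39 break-cluster windows of the simulated fragile-site genome
carry ~22× the cryptic-nonamer density of unbroken windows, every one
of them contains a CpG–nonamer pair, and no GC-matched control set of
39 unbroken windows reaches the observed CpG prevalence in 1000
resampling iterations. The numbered scripts under `analysis/`
(`01_simulate` … `04_distances_and_strata`) replay the full analysis
sequence — feature scan and PWM, window contrast with the null model,
distance contrast (fragile median ≈ 46 bp vs control ≈ 414 bp), and the
promoter (2%), chromatin (63%/37%) and cohort (CpG ratio ≈ 2)
stratifications — writing tables under `results/`.

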