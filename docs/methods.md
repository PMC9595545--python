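# Methods

## Model and procedure

The pipeline operationalizes a sequence-level model of RAG-mediated
chromosomal fragility: RAG1/2 can bind a *cryptic nonamer* — a 9-mer
conserving at least 5 of the 9 positions of the canonical RSS nonamer
`ACAAAAACC` (equivalently, Hamming distance ≤ 4) — and nick the DNA at a
nearby mismatch created by deamination of a (methylated) CpG cytosine.
Genomic loci where a CpG and a cryptic nonamer sit within a short edge
gap of each other are therefore candidate fragile sites, and patient
translocation breakpoints should cluster at them.

The analysis chain is: load genome and breakpoints → deduplicate
breakpoints to unique (chromosome, position) → scan both strands for
degenerate nonamers and CpGs → tile the genome into fixed windows and
count features → classify break-cluster windows → contrast broken vs
unbroken windows (χ², Mann–Whitney, Welch *t*) → measure per-break
CpG–nonamer distances → compare against GC-matched resampled controls →
stratify by promoters, Giemsa chromatin class and cohort → emit one
provenance-stamped report.

Coordinates are 0-based half-open throughout (BED-native); a breakpoint
is a point position. The heptamer (`CAC...`) is deliberately not part
of any statistic: mutagenesis evidence indicates nonamer-driven
recognition, with CAC removal leaving nicking activity intact.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `motif` | `ACAAAAACC` | 9-mer | canonical RSS nonamer |
| `max_mismatch` | 4 | substitutions | "≥ 5 of 9 conserved" definition of a cryptic nonamer |
| `breakpoint_radius` | 100 | bases | symmetric context `[p−r, p+r+1)` around a break |
| `pair_gap_max` | 80 | bases | largest CpG–nonamer edge gap that defines a fragility pair |
| `window_sizes` | 100, 1000 | bases | break-cluster scale and broad scale |
| `min_breaks_per_window` | 3 | breaks | break-cluster ("broken") threshold |
| `null_iterations` | 1000 | iterations | GC-matched resampling depth |
| `gc_tolerance` | 0.02 | GC fraction | "comparable GC" is not quantified anywhere authoritative; ±2 GC points on a 100 bp window (±2 bases) is the strictest matching that leaves a usable control pool, and it is exposed in the config |
| `require_positions` | ∅ | 1-based motif positions | optional stricter scan mode; positions 5–6 show elevated but not absolute conservation in bound regions, so they are **not** required by default |

Mismatch counting treats `N` as matching nothing (it always contributes
a mismatch), which conservatively suppresses hits in masked sequence
rather than inflating them. Exact matches (distance 0) count as cryptic
nonamers; the counting never separates exact from degenerate.

## Definitions that needed a decision

* **Edge-gap distance.** The CpG–nonamer distance is
  `max(0, later.start − earlier.end)`; overlap ⇒ 0. This is the only
  definition under which "within 10–80 bp" coexists with 9 bp motifs
  without negative values.
* **Window assignment.** A feature belongs to the window containing its
  start coordinate, so window counts always sum to genome totals; a
  containment rule would drop or double-count boundary straddlers.
* **`has_pair` context.** A window carries a fragility pair when at
  least one qualifying pair lies fully inside
  `[start − radius, end + radius)` — the same context a break anywhere
  in the window would see.
* **Unbroken means zero.** Windows with 1–2 breaks are excluded from
  contrasts rather than pooled into either class.
* **Chi-square variant.** No Yates correction by default (the flag
  exists); the *t*-test defaults to Welch. When several contrasts are
  emitted in one run, Benjamini–Hochberg adjusted p-values are reported
  alongside raw ones; raw values remain primary.
* **Null sampling.** Per-window GC matching (one control per broken
  window), without replacement within an iteration, with replacement
  across iterations; child seed = `SeedSequence((master, iteration))`;
  empirical p uses the add-one convention so it is never 0.
* **Chromatin classes.** gneg → euchromatin; gpos25/50/75/100 and gvar
  → heterochromatin; acen and stalk excluded. The class mapping is a
  package decision: cytogenetic staining gives only the labels.
* **Boundary semantics.** A break exactly at an interval boundary
  belongs to the interval it falls inside under `[start, end)`.

## What the synthetic generator emulates

`fragscan.synthetic` stands in for patient breakpoint compilations on a
reference genome. Backgrounds are i.i.d. bases at configurable GC with
an optional CpG obs/exp knob (default 0.25 in the fragile-site
scenario, emulating mammalian CpG depletion; 0 gives CpG-free fixtures).
Fragile sites are 100 bp windows carrying 8 planted nonamers (0–2
mismatches) and 2 planted CpGs — the break-cluster densities the
analysis targets. Breaks are per-base Bernoulli draws: rate 0.08/b
inside fragile footprints vs 1.6 × 10⁻⁶/b outside (the genome-scale
break density of real compilations) in the fragile-site scenario, and a
uniform 0.008/b in the null scenario so that break-cluster windows
exist without any sequence association. Plants destined for
exact-recovery checks sit in scrubbed buffers (re-randomized until free
of CpGs and exact-motif windows), making ground truth unambiguous;
incidental background hits elsewhere are expected realistic noise.

Desk-scale genomes force one deliberate departure from the reference
defaults: at `max_mismatch = 4`, 12 826 of the 262 144 possible 9-mers
qualify, so ~10 % of positions on a random genome carry a hit on one
strand or the other and window-level *presence* saturates. The
scenarios therefore analyze at `max_mismatch = 2` (the config default
stays 4), and the fixtures that check *exact* planted-gap or designed
proximity-fraction recovery use exact nonamers (`max_mismatch = 0`) on
CpG-free backgrounds. This is a property of scale, not of the method:
at reference-genome scale the ≤ 4 definition leaves informative
contrast because break clusters are ~10⁵ times rarer.

Consequently, passing tests demonstrate recovery of *planted* structure
and correct statistical calibration under the generator's assumptions
(i.i.d. background, point breaks, Bernoulli break model). They do not
demonstrate that real genomes show the enrichment — real chromatin,
repeat structure, and breakpoint mapping error are outside the
generator — nor do they reproduce any published genome-scale statistic,
which would require the original breakpoint compilations.

## Numerical and implementation notes

* The scanner compares every window against the motif and against its
  reverse complement (Hamming(revcomp(w), m) = Hamming(w, revcomp(m))),
  vectorized over a strided window view; output order is FASTA
  chromosome order, then start, then `+` before `−`. A brute-force
  scanner written independently in the test suite is the oracle.
* PWM columns renormalize over hits contributing a real base when `N`s
  are present; columns sum to 1 within 1e-9 by construction.
* Mann–Whitney U uses midranks with the tie-corrected normal
  approximation and continuity correction; a fully tied comparison
  returns p = 1 rather than dividing by zero. Degenerate 2×2 tables
  (a zero marginal) raise in the low-level API and are reported as
  absent statistics by the pipeline.
* Pearson correlation of break count vs chromosome length is NaN-flagged
  below 2 chromosomes or at zero variance; all-N windows carry NaN GC
  and are excluded from GC matching, as are terminal windows shorter
  than 90 % of nominal size.
* Problem sizes used by the shipped analyses: 100–300 kb scenario
  genomes, 1 Mb recovery fixture, 1000 null-model iterations, 100
  seeded enrichment runs and 1000 null-calibration datasets. These keep
  every stage to seconds-to-minutes on a single CPU while leaving all
  statistical checks well-powered.

## Known limitations

* The generator plants fragile sites at fixed within-window offsets;
  it varies content (mismatch counts, strands, gaps, break positions)
  but not site micro-architecture.
* GC matching is the only covariate matched in the null model (repeat
  content and gene density are not modeled, mirroring the analysis
  design).
* Cohort comparison assigns a window to a cohort via that cohort's own
  breaks; windows broken in both cohorts contribute to both.
* Wiggle/bigWig ChIP signal, BLAT remapping of junction sequences, and
  any wet-lab validation layer are out of scope; ChIP peaks can enter
  only as a generic region set.
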