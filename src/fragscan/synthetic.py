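"""Synthetic genomes, planted features and breakpoints with ground truth.

This module is the stand-in for the study's real inputs (patient
translocation breakpoints on a reference genome). It generates:

* i.i.d. background sequence with configurable GC content and optional
  CpG depletion (mammalian genomes show CpG observed/expected well
  below 1; the depletion knob removes a fraction of background CG
  dinucleotides);
* planted cryptic nonamers at exact Hamming distances 0..4 from the
  canonical nonamer, on a uniformly chosen strand;
* planted CpG-nonamer pairs at exact edge gaps;
* breakpoints from a per-base Bernoulli model whose rate is elevated
  inside "fragile footprints" around planted pairs.

Every plant and break is recorded in a :class:`SyntheticTruth` so
recovery can be tested. All randomness flows from a master seed through
named child streams (genome, plants, breaks).

Plants destined for exact-recovery checks are written into scrubbed
buffers: the surrounding sequence is re-randomized until it contains no
exact-motif window and no CpG, so the planted feature is provably the
only one in its neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig, CANONICAL_NONAMER
from .io_formats import (
    BreakpointTable,
    GenomeSequence,
    RegionSet,
    write_fasta,
    write_regions_bed,
)
from .motif_scan import encode, decode, reverse_complement

_BASES = "ACGT"
_MOTIF_ENC = encode(CANONICAL_NONAMER)
_RC_MOTIF_ENC = encode(reverse_complement(CANONICAL_NONAMER))


@dataclass
class SyntheticTruth:
    """Ground truth of everything the generator planted."""

    nonamers: list = field(default_factory=list)  # (chrom, start, strand, mismatches)
    cpgs: list = field(default_factory=list)  # (chrom, start)
    pair_gaps: list = field(default_factory=list)  # (chrom, break_pos, gap)
    footprints: list = field(default_factory=list)  # (chrom, start, end)
    provenance: list = field(default_factory=list)  # per break: footprint|background
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Scenario:
    """A complete, self-consistent set of pipeline inputs plus truth."""

    name: str
    seed: int
    genome: GenomeSequence
    breaks: BreakpointTable
    promoters: RegionSet | None
    cytobands: RegionSet | None
    truth: SyntheticTruth
    config: AnalysisConfig


# ---------------------------------------------------------------------------
# background sequence

def generate_codes(
    n: int, gc: float, rng: np.random.Generator, cpg_obs_exp: float = 1.0
) -> np.ndarray:
    """Random base codes with P(G)=P(C)=gc/2 and optional CpG depletion.

    With ``cpg_obs_exp < 1``, each background CG dinucleotide survives
    with that probability; destroyed CGs have their G replaced by A or
    T (which cannot create a new CG), so ``cpg_obs_exp=0`` yields a
    CpG-free sequence. The depletion slightly lowers realized GC.
    """
    if not 0 < gc < 1:
        if gc == 0.0:
            return rng.choice(
                np.array([0, 3], dtype=np.uint8), size=n
            )  # A/T only
        raise ValueError("gc must be in [0, 1)")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(np.arange(4, dtype=np.uint8), size=n, p=p)
    if cpg_obs_exp < 1.0 and n >= 2:
        cg = np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2))
        destroy = cg[rng.random(len(cg)) >= cpg_obs_exp]
        codes[destroy + 1] = rng.choice(np.array([0, 3], dtype=np.uint8), len(destroy))
    return codes


def generate_genome(
    lengths: dict[str, int],
    gc: float,
    seed_or_rng,
    cpg_obs_exp: float = 1.0,
) -> GenomeSequence:
    """i.i.d. genome over the given chromosome lengths; deterministic per seed."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return GenomeSequence(
        {
            name: decode(generate_codes(n, gc, rng, cpg_obs_exp))
            for name, n in lengths.items()
        }
    )


# ---------------------------------------------------------------------------
# planting

def make_variant(
    mismatches: int,
    rng: np.random.Generator,
    motif: str = CANONICAL_NONAMER,
    avoid_cpg: bool = False,
) -> str:
    """A 9-mer at exactly the requested Hamming distance from the motif.

    Mutated positions are chosen uniformly, substituted bases uniform
    over the 3 alternatives. ``avoid_cpg`` resamples until the variant
    contains no CG dinucleotide internally.
    """
    if not 0 <= mismatches <= 4:
        raise ValueError("mismatches must be in 0..4")
    for _ in range(200):
        positions = rng.choice(len(motif), size=mismatches, replace=False)
        bases = list(motif)
        for p in positions:
            alternatives = [b for b in _BASES if b != motif[p]]
            bases[p] = alternatives[rng.integers(3)]
        variant = "".join(bases)
        if not avoid_cpg or "CG" not in variant:
            return variant
    raise RuntimeError("could not construct a CG-free variant")


def plant_motif(
    codes: np.ndarray,
    position: int,
    mismatches: int,
    rng: np.random.Generator,
    motif: str = CANONICAL_NONAMER,
    strand: str | None = None,
    avoid_cpg: bool = False,
) -> tuple[str, str]:
    """Write a degenerate nonamer into the code array at ``position``.

    The observed 9-mer (hit-strand orientation) is at exactly
    ``mismatches`` from the motif; on the minus strand its reverse
    complement is written into the plus-strand text. Returns
    (strand, observed 9-mer).
    """
    if position < 0 or position + 9 > len(codes):
        raise ValueError(f"plant position {position} out of range")
    variant = make_variant(mismatches, rng, motif, avoid_cpg)
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    text = variant if strand == "+" else reverse_complement(variant)
    codes[position : position + 9] = encode(text)
    return strand, variant


def plant_pair(
    codes: np.ndarray,
    anchor: int,
    gap: int,
    rng: np.random.Generator,
    motif: str = CANONICAL_NONAMER,
    mismatches: int = 0,
    avoid_cpg: bool = True,
) -> dict:
    """Write a CpG and a nonamer separated by exactly ``gap`` bases.

    The order (CpG first or nonamer first along the chromosome) is
    chosen by the random stream. Returns the planted coordinates:
    ``{"cpg_start", "nonamer_start", "strand", "mismatches", "span"}``.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    total = 2 + gap + 9
    if anchor < 0 or anchor + total > len(codes):
        raise ValueError("insufficient room for pair plant")
    cpg_first = rng.random() < 0.5
    if cpg_first:
        cpg_start = anchor
        nonamer_start = anchor + 2 + gap
    else:
        nonamer_start = anchor
        cpg_start = anchor + 9 + gap
    strand, _ = plant_motif(
        codes, nonamer_start, mismatches, rng, motif, avoid_cpg=avoid_cpg
    )
    codes[cpg_start] = 1  # C
    codes[cpg_start + 1] = 2  # G
    return {
        "cpg_start": int(cpg_start),
        "nonamer_start": int(nonamer_start),
        "strand": strand,
        "mismatches": mismatches,
        "span": (int(anchor), int(anchor + total)),
    }


def scrub_region(
    codes: np.ndarray,
    lo: int,
    hi: int,
    rng: np.random.Generator,
    protected: np.ndarray | None = None,
    max_rounds: int = 50,
) -> None:
    """Remove every CpG and exact-motif window from ``codes[lo:hi]``.

    Only unprotected positions are rewritten (with A/T, which cannot
    form new CGs). Used to build buffers where a subsequently planted
    feature is provably unique.
    """
    lo, hi = max(0, lo), min(len(codes), hi)
    if protected is None:
        protected = np.zeros(len(codes), dtype=bool)
    at = np.array([0, 3], dtype=np.uint8)
    for _ in range(max_rounds):
        seg = codes[lo:hi]
        dirty = False
        cg = np.flatnonzero((seg[:-1] == 1) & (seg[1:] == 2)) + lo
        for s in cg:
            target = s + 1 if not protected[s + 1] else s
            if protected[target]:
                continue  # planted CpG
            codes[target] = at[rng.integers(2)]
            dirty = True
        if hi - lo >= 9:
            win = np.lib.stride_tricks.sliding_window_view(codes[lo:hi], 9)
            exact = np.flatnonzero(
                ((win != _MOTIF_ENC).sum(axis=1) == 0)
                | ((win != _RC_MOTIF_ENC).sum(axis=1) == 0)
            ) + lo
            for s in exact:
                free = [p for p in range(s, s + 9) if not protected[p]]
                if not free:
                    continue  # planted nonamer
                codes[free[len(free) // 2]] = at[rng.integers(2)]
                dirty = True
        if not dirty:
            return
    raise RuntimeError("scrub_region failed to converge")


# ---------------------------------------------------------------------------
# break simulation

def simulate_breakpoints(
    genome: GenomeSequence,
    footprints: list[tuple[str, int, int]],
    lam_bg: float,
    lam_frag: float,
    seed_or_rng,
    truth: SyntheticTruth | None = None,
    cohort_in_footprint: str = "lymphoid",
    cohort_background: str = "unlabeled",
    max_expected: float = 2_000_000,
) -> BreakpointTable:
    """Per-base Bernoulli breaks: rate lam_frag inside footprints, lam_bg outside.

    At most one break per base by construction. Provenance
    (footprint/background) is appended to ``truth`` when given.
    """
    if lam_bg < 0 or lam_frag < 0:
        raise ValueError("rates must be >= 0")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    foot_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in footprints:
        foot_by_chrom.setdefault(chrom, []).append((s, e))
    expected = 0.0
    for chrom, length in genome.lengths.items():
        foot_len = sum(e - s for s, e in foot_by_chrom.get(chrom, []))
        expected += lam_bg * (length - foot_len) + lam_frag * foot_len
    if expected > max_expected:
        raise ValueError(f"expected break count {expected:.0f} exceeds cap")
    rows = []
    provenance = []
    for chrom, length in genome.lengths.items():
        rates = np.full(length, lam_bg)
        in_foot = np.zeros(length, dtype=bool)
        for s, e in foot_by_chrom.get(chrom, []):
            rates[s:e] = lam_frag
            in_foot[s:e] = True
        hit = rng.random(length) < rates
        for pos in np.flatnonzero(hit):
            is_foot = bool(in_foot[pos])
            rows.append(
                (
                    chrom,
                    int(pos),
                    cohort_in_footprint if is_foot else cohort_background,
                    None,
                    None,
                )
            )
            provenance.append("footprint" if is_foot else "background")
    table = BreakpointTable(
        pd.DataFrame(rows, columns=list(BreakpointTable.COLUMNS))
    )
    if truth is not None:
        truth.provenance.extend(provenance)
    return table


# ---------------------------------------------------------------------------
# scenarios

#: per-site layout of a "fragile site": planted nonamer offsets within a
#: 100 bp window and CpG offsets in the spare bases between them; the
#: densities mirror the break-cluster windows the analysis targets
#: (~8 nonamers and ~2 CpGs per 100 bp).
SITE_NONAMER_OFFSETS = (0, 12, 24, 36, 48, 60, 72, 84)
SITE_CPG_OFFSETS = (9, 57)
WINDOW = 100


def _plant_fragile_site(
    codes: np.ndarray,
    chrom: str,
    window_start: int,
    rng: np.random.Generator,
    truth: SyntheticTruth,
    n_nonamers: int = 8,
    n_cpgs: int = 2,
    max_mm: int = 2,
) -> None:
    for off in SITE_NONAMER_OFFSETS[:n_nonamers]:
        mm = int(rng.integers(0, max_mm + 1))
        strand, _ = plant_motif(
            codes, window_start + off, mm, rng, avoid_cpg=True
        )
        truth.nonamers.append((chrom, int(window_start + off), strand, mm))
    for off in SITE_CPG_OFFSETS[:n_cpgs]:
        codes[window_start + off] = 1
        codes[window_start + off + 1] = 2
        truth.cpgs.append((chrom, int(window_start + off)))


def _alternating_cytobands(lengths: dict[str, int], band: int = 10_000) -> RegionSet:
    rows = []
    stains = ("gneg", "gpos50", "gneg", "gpos100", "gneg", "gvar")
    for chrom, length in lengths.items():
        k = 0
        for s in range(0, length, band):
            rows.append((chrom, s, min(s + band, length), stains[k % len(stains)]))
            k += 1
    return RegionSet("cytoband", pd.DataFrame(rows, columns=list(RegionSet.COLUMNS)))


def _fixture_promoters(lengths: dict[str, int]) -> RegionSet:
    # TSS-style intervals (-2000..+500 around a nominal TSS every 25 kb)
    rows = []
    for chrom, length in lengths.items():
        for tss in range(5_000, length - 1_000, 25_000):
            rows.append((chrom, tss - 2_000, tss + 500, "promoter"))
    return RegionSet("promoters", pd.DataFrame(rows, columns=list(RegionSet.COLUMNS)))


def _pick_site_windows(
    cytobands: RegionSet,
    lengths: dict[str, int],
    n_eu: int,
    n_het: int,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Distinct, well-separated 100 bp windows split between chromatin classes."""
    from .annotation import stain_to_class

    eu_windows, het_windows = [], []
    for row in cytobands.df.itertuples(index=False):
        cls = stain_to_class(row.label)
        if cls == "excluded":
            continue
        # candidate windows strictly inside the band, away from band edges
        for w in range((row.start // WINDOW) + 2, (row.end // WINDOW) - 2, 4):
            (eu_windows if cls == "euchromatin" else het_windows).append(
                (row.chrom, w * WINDOW)
            )
    eu_pick = rng.choice(len(eu_windows), size=n_eu, replace=False)
    het_pick = rng.choice(len(het_windows), size=n_het, replace=False)
    sites = [eu_windows[i] for i in eu_pick] + [het_windows[i] for i in het_pick]
    return sorted(sites)


def make_scenario(name: str, seed: int) -> Scenario:
    """Complete synthetic inputs for an end-to-end run, plus ground truth.

    Scenarios
    ---------
    paper_like
        200 kb genome (GC 0.45, CpG obs/exp 0.25), 40 fragile sites
        (8 planted nonamers with <=2 mismatches and 2 CpGs per 100 bp
        window, ~62/38 split between Giemsa classes), break rate 0.08/b
        inside footprints vs 1.6e-6/b outside (the genome-wide break
        density the analysis expects at reference scale).
    null
        100 kb genome with the same planted sites but a uniform break
        rate of 0.008/b everywhere: feature structure without
        enrichment, for type-I calibration.
    promoter_fixture
        300 kb CpG-free genome; 2% of 1000 breaks placed in promoters,
        half of those with a planted exact CpG-nonamer pair.
    cohort_fixture
        200 kb CpG-free genome; lymphoid fragile sites carry twice the
        planted nonamer and CpG density of nonlymphoid ones.
    """
    ss = np.random.SeedSequence(seed)
    rng_genome, rng_plants, rng_breaks, rng_misc = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    truth = SyntheticTruth()

    if name in ("paper_like", "null"):
        lengths = (
            {"chr1": 120_000, "chr2": 80_000}
            if name == "paper_like"
            else {"chr1": 100_000}
        )
        codes = {
            c: generate_codes(n, 0.45, rng_genome, cpg_obs_exp=0.25)
            for c, n in lengths.items()
        }
        cytobands = _alternating_cytobands(lengths)
        sites = _pick_site_windows(cytobands, lengths, n_eu=25, n_het=15, rng=rng_plants)
        for chrom, start in sites:
            _plant_fragile_site(codes[chrom], chrom, start, rng_plants, truth)
            truth.footprints.append((chrom, start, start + WINDOW))
        genome = GenomeSequence({c: decode(codes[c]) for c in lengths})
        if name == "paper_like":
            lam_bg, lam_frag = 1.6e-6, 0.08
        else:
            lam_bg = lam_frag = 0.008
        breaks = simulate_breakpoints(
            genome, truth.footprints, lam_bg, lam_frag, rng_breaks, truth
        )
        config = AnalysisConfig(max_mismatch=2, random_seed=seed)
        return Scenario(
            name, seed, genome, breaks, _fixture_promoters(lengths), cytobands,
            truth, config,
        )

    if name == "promoter_fixture":
        length = 300_000
        codes = generate_codes(length, 0.45, rng_genome, cpg_obs_exp=0.0)
        promoters = RegionSet(
            "promoters",
            pd.DataFrame(
                [("chr1", 10_000 + k * 35_000, 12_500 + k * 35_000, "promoter")
                 for k in range(8)],
                columns=list(RegionSet.COLUMNS),
            ),
        )
        scrub_region(codes, 0, length, rng_misc)
        n_breaks, n_prom, n_prom_pair = 1000, 20, 10
        prom = promoters.df[["start", "end"]].to_numpy()
        in_prom_mask = np.zeros(length, dtype=bool)
        for s, e in prom:
            in_prom_mask[s:e] = True
        prom_candidates = np.flatnonzero(in_prom_mask)
        prom_pos = []
        while len(prom_pos) < n_prom:  # keep planted pairs well separated
            p = int(prom_candidates[rng_breaks.integers(len(prom_candidates))])
            if all(abs(p - q) > 300 for q in prom_pos):
                prom_pos.append(p)
        prom_pos = np.array(prom_pos)
        out_pos = rng_breaks.choice(
            np.flatnonzero(~in_prom_mask[:-600]), n_breaks - n_prom, replace=False
        )
        protected = np.zeros(length, dtype=bool)
        for i, pos in enumerate(prom_pos):
            if i < n_prom_pair:
                # exact pair straddling the break: CpG left, nonamer right
                codes[pos - 20] = 1
                codes[pos - 19] = 2
                strand, _ = plant_motif(codes, pos + 15, 0, rng_plants, avoid_cpg=True)
                protected[pos - 20 : pos - 18] = True
                protected[pos + 15 : pos + 24] = True
                truth.cpgs.append(("chr1", int(pos - 20)))
                truth.nonamers.append(("chr1", int(pos + 15), strand, 0))
                truth.pair_gaps.append(("chr1", int(pos), 33))
        # re-scrub around planted features (junction CGs, chance exact hits)
        for pos in prom_pos[:n_prom_pair]:
            scrub_region(codes, pos - 150, pos + 150, rng_misc, protected)
        positions = np.concatenate([prom_pos, out_pos])
        rows = [("chr1", int(p), "lymphoid", None, None) for p in np.sort(positions)]
        breaks = BreakpointTable(
            pd.DataFrame(rows, columns=list(BreakpointTable.COLUMNS))
        )
        truth.extras = {
            "n_in_promoters": n_prom,
            "n_in_promoters_with_pair": n_prom_pair,
        }
        genome = GenomeSequence({"chr1": decode(codes)})
        config = AnalysisConfig(max_mismatch=0, random_seed=seed)
        return Scenario(
            name, seed, genome, breaks, promoters, None, truth, config
        )

    if name == "cohort_fixture":
        length = 200_000
        codes = generate_codes(length, 0.45, rng_genome, cpg_obs_exp=0.0)
        scrub_region(codes, 0, length, rng_misc)
        site_windows = np.arange(50, 1950, 38)[:50] * WINDOW  # 50 separated windows
        rng_plants.shuffle(site_windows)
        lymph, nonlymph = site_windows[:25], site_windows[25:50]
        rows = []
        for group, n_non, n_cpg, lam, cohort in (
            (lymph, 8, 2, 0.08, "lymphoid"),
            (nonlymph, 4, 1, 0.05, "nonlymphoid"),
        ):
            for start in group:
                _plant_fragile_site(
                    codes, "chr1", int(start), rng_plants, truth,
                    n_nonamers=n_non, n_cpgs=n_cpg,
                )
                truth.footprints.append(("chr1", int(start), int(start + WINDOW)))
                hit = np.flatnonzero(rng_breaks.random(WINDOW) < lam)
                for off in hit:
                    rows.append(("chr1", int(start + off), cohort, None, None))
                    truth.provenance.append("footprint")
        breaks = BreakpointTable(
            pd.DataFrame(rows, columns=list(BreakpointTable.COLUMNS))
        )
        genome = GenomeSequence({"chr1": decode(codes)})
        config = AnalysisConfig(max_mismatch=2, random_seed=seed)
        return Scenario(name, seed, genome, breaks, None, None, truth, config)

    raise ValueError(f"unknown scenario {name!r}")


# ---------------------------------------------------------------------------
# exact-recovery fixtures

def make_recovery_fixture(
    seed: int,
    n_nonamers: int = 200,
    n_pairs: int = 200,
    genome_len: int = 1_000_000,
    radius: int = 100,
) -> tuple[GenomeSequence, SyntheticTruth, BreakpointTable]:
    """1 Mb genome with planted nonamers (mismatches 0..4) and exact pairs.

    Nonamers occupy the first half in well-separated slots; each pair
    occupies a scrubbed buffer in the second half (no background CpG or
    exact-motif window within ``radius`` of its break), with a break
    planted between the CpG and the nonamer, so the minimal pair gap at
    that break equals the planted gap exactly.
    """
    ss = np.random.SeedSequence(seed)
    rng_genome, rng_plants, rng_misc = (np.random.default_rng(s) for s in ss.spawn(3))
    codes = generate_codes(genome_len, 0.45, rng_genome)
    truth = SyntheticTruth()
    stride = 2_000
    for i in range(n_nonamers):
        pos = 1_000 + i * stride
        mm = i % 5
        strand, _ = plant_motif(codes, pos, mm, rng_plants)
        truth.nonamers.append(("chr1", pos, strand, mm))
    break_rows = []
    base = genome_len // 2
    protected = np.zeros(genome_len, dtype=bool)
    for i in range(n_pairs):
        anchor = base + i * stride
        gap = int(rng_plants.integers(5, 81))
        scrub_region(codes, anchor - radius - 50, anchor + 11 + gap + radius + 50, rng_misc)
        info = plant_pair(codes, anchor, gap, rng_plants, mismatches=0)
        cs, ns = info["cpg_start"], info["nonamer_start"]
        protected[cs : cs + 2] = True
        protected[ns : ns + 9] = True
        # re-scrub flanks in case planting created junction CGs
        scrub_region(codes, anchor - radius - 50, anchor + 11 + gap + radius + 50,
                     rng_misc, protected)
        truth.cpgs.append(("chr1", cs))
        truth.nonamers.append(("chr1", ns, info["strand"], 0))
        first_end = cs + 2 if cs < ns else ns + 9
        second_start = ns if cs < ns else cs
        bp = (first_end + second_start) // 2
        break_rows.append(("chr1", bp, "lymphoid", None, None))
        truth.pair_gaps.append(("chr1", bp, gap))
    breaks = BreakpointTable(
        pd.DataFrame(break_rows, columns=list(BreakpointTable.COLUMNS))
    )
    genome = GenomeSequence({"chr1": decode(codes)})
    return genome, truth, breaks


def make_proximity_cohort(
    seed: int,
    n_breaks: int = 1000,
    frac_nonamer: float = 0.93,
    frac_cpg: float = 0.73,
    radius: int = 100,
) -> tuple[GenomeSequence, BreakpointTable, SyntheticTruth, AnalysisConfig]:
    """Breakpoint cohort with controlled feature-proximity fractions.

    Exactly ``round(frac_nonamer * n)`` breaks get an exact nonamer and
    ``round(frac_cpg * n)`` a CpG planted within the radius, on a
    CpG-free background scrubbed of exact-motif windows, so the
    measured proximity fractions equal the designed ones up to the rare
    background coincidence.
    """
    ss = np.random.SeedSequence(seed)
    rng_genome, rng_plants, rng_misc = (np.random.default_rng(s) for s in ss.spawn(3))
    stride = 2 * radius + 60
    length = n_breaks * stride + 1_000
    codes = generate_codes(length, 0.45, rng_genome, cpg_obs_exp=0.0)
    scrub_region(codes, 0, length, rng_misc)
    truth = SyntheticTruth()
    non_flags = np.zeros(n_breaks, dtype=bool)
    non_flags[: round(frac_nonamer * n_breaks)] = True
    rng_plants.shuffle(non_flags)
    cpg_flags = np.zeros(n_breaks, dtype=bool)
    cpg_flags[: round(frac_cpg * n_breaks)] = True
    rng_plants.shuffle(cpg_flags)
    protected = np.zeros(length, dtype=bool)
    rows = []
    for i in range(n_breaks):
        center = 500 + i * stride
        rows.append(("chr1", center, "lymphoid", None, None))
        if non_flags[i]:
            off = int(rng_plants.integers(15, 70))
            pos = center + off
            strand, _ = plant_motif(codes, pos, 0, rng_plants, avoid_cpg=True)
            protected[pos : pos + 9] = True
            truth.nonamers.append(("chr1", pos, strand, 0))
        if cpg_flags[i]:
            off = int(rng_plants.integers(15, 70))
            pos = center - off
            codes[pos] = 1
            codes[pos + 1] = 2
            protected[pos : pos + 2] = True
            truth.cpgs.append(("chr1", pos))
        scrub_region(codes, center - radius - 20, center + radius + 20, rng_misc, protected)
    truth.extras = {
        "frac_nonamer": float(non_flags.mean()),
        "frac_cpg": float(cpg_flags.mean()),
    }
    genome = GenomeSequence({"chr1": decode(codes)})
    breaks = BreakpointTable(
        pd.DataFrame(rows, columns=list(BreakpointTable.COLUMNS))
    )
    config = AnalysisConfig(max_mismatch=0, breakpoint_radius=radius, random_seed=seed)
    return genome, breaks, truth, config


def make_distance_fixture(
    kind: str,
    seed: int,
    n_regions: int = 100,
) -> tuple[GenomeSequence, BreakpointTable, SyntheticTruth, AnalysisConfig]:
    """Pair-distance fixtures: fragile (gaps U[10,80]) vs control (U[320,500]).

    Each region holds one exact CpG-nonamer pair in a scrubbed buffer
    with a break planted between the features, so the per-break minimal
    gap equals the planted one.
    """
    if kind == "fragile":
        gap_lo, gap_hi, radius = 10, 80, 100
    elif kind == "control":
        gap_lo, gap_hi, radius = 320, 500, 600
    else:
        raise ValueError(f"unknown distance fixture kind {kind!r}")
    ss = np.random.SeedSequence(seed)
    rng_genome, rng_plants, rng_misc = (np.random.default_rng(s) for s in ss.spawn(3))
    span_max = 11 + gap_hi
    stride = span_max + 2 * radius + 200
    length = n_regions * stride + 1_000
    codes = generate_codes(length, 0.45, rng_genome, cpg_obs_exp=0.0)
    truth = SyntheticTruth()
    protected = np.zeros(length, dtype=bool)
    rows = []
    for i in range(n_regions):
        anchor = 500 + i * stride
        gap = int(rng_plants.integers(gap_lo, gap_hi + 1))
        scrub_region(codes, anchor - radius - 50, anchor + span_max + radius + 50, rng_misc)
        info = plant_pair(codes, anchor, gap, rng_plants, mismatches=0)
        cs, ns = info["cpg_start"], info["nonamer_start"]
        protected[cs : cs + 2] = True
        protected[ns : ns + 9] = True
        scrub_region(codes, anchor - radius - 50, anchor + span_max + radius + 50,
                     rng_misc, protected)
        first_end = cs + 2 if cs < ns else ns + 9
        second_start = ns if cs < ns else cs
        bp = (first_end + second_start) // 2
        rows.append(("chr1", bp, "lymphoid", None, None))
        truth.pair_gaps.append(("chr1", bp, gap))
        truth.cpgs.append(("chr1", cs))
        truth.nonamers.append(("chr1", ns, info["strand"], 0))
    genome = GenomeSequence({"chr1": decode(codes)})
    breaks = BreakpointTable(
        pd.DataFrame(rows, columns=list(BreakpointTable.COLUMNS))
    )
    config = AnalysisConfig(
        max_mismatch=0, breakpoint_radius=radius, random_seed=seed
    )
    return genome, breaks, truth, config


# ---------------------------------------------------------------------------
# fixture export

def write_scenario(scenario: Scenario, outdir: str | Path) -> None:
    """Write FASTA/TSV/BED fixtures plus truth and config JSON."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(scenario.genome, outdir / "genome.fa")
    with open(outdir / "breaks.tsv", "w") as fh:
        for row in scenario.breaks.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.cohort}\t\t\n")
    if scenario.promoters is not None:
        write_regions_bed(scenario.promoters, outdir / "promoters.bed")
    if scenario.cytobands is not None:
        with open(outdir / "cytoband.tsv", "w") as fh:
            for row in scenario.cytobands.df.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\tband\t{row.label}\n"
                )
    (outdir / "truth.json").write_text(
        json.dumps(scenario.truth.to_dict(), indent=1) + "\n"
    )
    scenario.config.to_json(outdir / "config.json")
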