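"""Generator correctness: plants, breaks, scenarios, and recovery round-trips."""

import numpy as np
import pytest

from fragscan.config import AnalysisConfig
from fragscan.io_formats import dedupe_breakpoints
from fragscan.motif_scan import (
    encode,
    hamming_distance,
    reverse_complement,
    scan_cpg,
    scan_cryptic_nonamers,
)
from fragscan.synthetic import (
    generate_codes,
    generate_genome,
    make_proximity_cohort,
    make_scenario,
    make_variant,
    plant_motif,
    plant_pair,
    scrub_region,
    simulate_breakpoints,
    write_scenario,
)

MOTIF = "ACAAAAACC"


class TestGenerateGenome:
    def test_gc_concentration(self):
        g = generate_genome({"c": 100_000}, 0.5, 1)
        seq = g["c"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.01

    def test_gc_zero_at_only(self):
        g = generate_genome({"c": 1000}, 0.0, 1)
        assert set(g["c"]) <= {"A", "T"}

    def test_deterministic(self):
        assert generate_genome({"c": 5000}, 0.45, 9)["c"] == \
            generate_genome({"c": 5000}, 0.45, 9)["c"]

    def test_cpg_free_background(self):
        g = generate_genome({"c": 50_000}, 0.45, 3, cpg_obs_exp=0.0)
        assert "CG" not in g["c"]

    def test_cpg_depletion_reduces_density(self):
        rng_a, rng_b = np.random.default_rng(4), np.random.default_rng(4)
        full = generate_codes(100_000, 0.45, rng_a, cpg_obs_exp=1.0)
        depleted = generate_codes(100_000, 0.45, rng_b, cpg_obs_exp=0.25)
        def n_cg(codes):
            return int(((codes[:-1] == 1) & (codes[1:] == 2)).sum())
        assert n_cg(depleted) < 0.4 * n_cg(full)

    def test_background_cpg_density_iid(self):
        """GC=0.5 i.i.d.: P(CG) = 1/16 per dinucleotide position."""
        g = generate_genome({"c": 200_000}, 0.5, 5)
        n = len(scan_cpg(g))
        expected = 199_999 / 16
        assert abs(n - expected) < 4 * np.sqrt(expected)


class TestPlanting:
    @pytest.mark.parametrize("mm", [0, 1, 2, 3, 4])
    def test_variant_exact_distance(self, mm, rng):
        for _ in range(20):
            v = make_variant(mm, rng)
            assert hamming_distance(v, MOTIF) == mm

    def test_variant_rejects_five(self, rng):
        with pytest.raises(ValueError):
            make_variant(5, rng)

    def test_minus_strand_distance_at_least_five(self, rng):
        """Triangle bound: a <=4-mismatch variant is >=5 from the revcomp motif."""
        for mm in range(5):
            v = make_variant(mm, rng)
            assert hamming_distance(v, reverse_complement(MOTIF)) >= 5

    def test_plant_zero_mismatch_writes_motif_or_revcomp(self, rng):
        codes = generate_codes(100, 0.5, rng)
        strand, variant = plant_motif(codes, 30, 0, rng)
        from fragscan.motif_scan import decode
        written = decode(codes[30:39])
        assert written in (MOTIF, reverse_complement(MOTIF))
        assert variant == MOTIF

    def test_plant_out_of_range(self, rng):
        codes = generate_codes(20, 0.5, rng)
        with pytest.raises(ValueError):
            plant_motif(codes, 15, 0, rng)

    def test_plant_detected_only_at_its_mismatch_level(self, rng):
        """A 4-mismatch plant is seen at max_mismatch 4, not at 3."""
        from fragscan.io_formats import GenomeSequence
        from fragscan.motif_scan import decode
        codes = np.zeros(29, dtype=np.uint8)  # poly-A flanks
        strand, _ = plant_motif(codes, 10, 4, rng)
        g = GenomeSequence({"c": decode(codes)})
        hits4 = scan_cryptic_nonamers(g, AnalysisConfig(max_mismatch=4))
        assert (10, strand, 4) in set(
            zip(hits4["start"], hits4["strand"], hits4["mismatches"])
        )
        hits3 = scan_cryptic_nonamers(g, AnalysisConfig(max_mismatch=3))
        assert (10, strand) not in set(zip(hits3["start"], hits3["strand"]))

    def test_pair_gap_read_back(self, rng, default_config):
        from fragscan.io_formats import GenomeSequence, BreakpointTable
        from fragscan.motif_scan import decode
        from fragscan.cooccurrence import nearest_pair_gap
        for gap in (0, 8, 80):
            codes = generate_codes(400, 0.45, rng, cpg_obs_exp=0.0)
            scrub_region(codes, 0, 400, rng)
            info = plant_pair(codes, 150, gap, rng)
            g = GenomeSequence({"c": decode(codes)})
            hits = scan_cryptic_nonamers(g, AnalysisConfig(max_mismatch=0))
            cpgs = scan_cpg(g)
            bp = (info["span"][0] + info["span"][1]) // 2
            assert nearest_pair_gap("c", bp, hits, cpgs, 100) == gap

    def test_pair_insufficient_room(self, rng):
        codes = generate_codes(50, 0.5, rng)
        with pytest.raises(ValueError, match="room"):
            plant_pair(codes, 45, 10, rng)

    def test_scrub_region_removes_cpg_and_exact_hits(self, rng):
        codes = generate_codes(2000, 0.6, rng)
        codes[500:509] = encode(MOTIF)
        scrub_region(codes, 0, 2000, rng)
        from fragscan.motif_scan import decode
        seq = decode(codes)
        assert "CG" not in seq
        assert MOTIF not in seq and reverse_complement(MOTIF) not in seq


class TestSimulateBreakpoints:
    def _genome(self, n=50_000, seed=2):
        return generate_genome({"c": n}, 0.45, seed)

    def test_zero_background_all_in_footprints(self):
        g = self._genome()
        foot = [("c", 1000, 2000), ("c", 30_000, 31_000)]
        t = simulate_breakpoints(g, foot, 0.0, 0.05, 3)
        assert len(t) > 0
        for pos in t.df["pos"]:
            assert any(s <= pos < e for _, s, e in foot)

    def test_zero_rates_empty(self):
        t = simulate_breakpoints(self._genome(), [], 0.0, 0.0, 3)
        assert len(t) == 0

    def test_poisson_total(self):
        g = generate_genome({"c": 1_000_000}, 0.45, 4)
        t = simulate_breakpoints(g, [], 1e-4, 1e-4, 5)
        assert abs(len(t) - 100) <= 3 * 10  # Poisson(100) within 3 sd

    def test_rate_cap_guard(self):
        with pytest.raises(ValueError, match="cap"):
            simulate_breakpoints(self._genome(), [], 1.0, 1.0, 3, max_expected=100)

    def test_provenance_fractions(self):
        from fragscan.synthetic import SyntheticTruth
        g = generate_genome({"c": 500_000}, 0.45, 6)
        foot = [("c", i * 10_000, i * 10_000 + 1000) for i in range(50)]
        truth = SyntheticTruth()
        t = simulate_breakpoints(g, foot, 1e-4, 1e-3, 7, truth)
        n_foot = sum(p == "footprint" for p in truth.provenance)
        expected_foot = 1e-3 * 50_000
        expected_bg = 1e-4 * 450_000
        assert abs(n_foot - expected_foot) < 3 * np.sqrt(expected_foot)
        assert abs((len(t) - n_foot) - expected_bg) < 3 * np.sqrt(expected_bg)


class TestScenarios:
    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            make_scenario("bogus", 1)

    def test_null_scenario_equal_rates_footprints_defined(self):
        sc = make_scenario("null", 3)
        assert len(sc.truth.footprints) == 40
        # breaks are spread over the genome, not concentrated in footprints
        foot_len = sum(e - s for _, s, e in sc.truth.footprints)
        frac_in_foot = np.mean([p == "footprint" for p in sc.truth.provenance])
        assert frac_in_foot < 3 * foot_len / sc.genome.total_length

    def test_scenario_fixtures_byte_identical(self, tmp_path):
        for run in ("a", "b"):
            write_scenario(make_scenario("paper_like", 11), tmp_path / run)
        for fn in ("genome.fa", "breaks.tsv", "promoters.bed", "cytoband.tsv",
                   "truth.json", "config.json"):
            assert (tmp_path / "a" / fn).read_bytes() == \
                (tmp_path / "b" / fn).read_bytes(), fn

    def test_paper_like_plants_recovered_by_scanner(self):
        sc = make_scenario("paper_like", 5)
        hits = scan_cryptic_nonamers(sc.genome, sc.config)
        found = set(zip(hits["chrom"], hits["start"], hits["strand"], hits["mismatches"]))
        for chrom, start, strand, mm in sc.truth.nonamers:
            assert (chrom, start, strand, mm) in found
        cpgs = set(zip(scan_cpg(sc.genome)["chrom"], scan_cpg(sc.genome)["start"]))
        for chrom, start in sc.truth.cpgs:
            assert (chrom, start) in cpgs

    def test_promoter_fixture_design(self):
        sc = make_scenario("promoter_fixture", 7)
        assert len(sc.breaks) == 1000
        assert sc.truth.extras["n_in_promoters"] == 20
        # the only CpGs are the planted ones (background is scrubbed)
        cpgs = scan_cpg(sc.genome)
        assert set(zip(cpgs["chrom"], cpgs["start"])) == set(sc.truth.cpgs)
        deduped, _ = dedupe_breakpoints(sc.breaks)
        assert len(deduped) == 1000

    def test_cohort_fixture_densities(self):
        sc = make_scenario("cohort_fixture", 9)
        cohorts = set(sc.breaks.df["cohort"])
        assert cohorts == {"lymphoid", "nonlymphoid"}
        assert len(sc.truth.footprints) == 50


class TestProximityCohort:
    def test_designed_fractions_recorded(self):
        g, breaks, truth, cfg = make_proximity_cohort(3, n_breaks=200)
        assert truth.extras["frac_nonamer"] == pytest.approx(0.93, abs=0.005)
        assert truth.extras["frac_cpg"] == pytest.approx(0.73, abs=0.005)
        assert len(breaks) == 200
        assert cfg.max_mismatch == 0
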