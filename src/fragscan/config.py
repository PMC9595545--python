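"""Run configuration for the breakpoint-fragility pipeline.

A single :class:`AnalysisConfig` carries every numeric threshold used by
the scanners, the windowing, the co-occurrence statistics and the null
model, and is echoed verbatim into every report for provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

VALID_BASES = frozenset("ACGTN")
#: Canonical RSS nonamer bound by the RAG1 nonamer-binding domain.
CANONICAL_NONAMER = "ACAAAAACC"


@dataclass
class AnalysisConfig:
    """All tunable parameters of a run.

    Parameters
    ----------
    motif:
        Reference 9-mer; cryptic occurrences are degenerate matches of it.
    max_mismatch:
        Maximum Hamming distance for a window to count as a cryptic
        nonamer (default 4, i.e. at least 5 of 9 positions conserved).
    breakpoint_radius:
        Half-width in bases of the symmetric context searched around a
        breakpoint for nonamers and CpGs.
    pair_gap_max:
        Largest CpG-to-nonamer edge gap (bases) that still counts as a
        fragility pair.
    window_sizes:
        Genome tiling sizes in bases.
    min_breaks_per_window:
        Deduplicated break count at which a window is called a break
        cluster ("broken").
    null_iterations:
        Number of GC-matched resampling iterations for the null model.
    gc_tolerance:
        Maximum |GC difference| between a control window and the broken
        window it is matched to.
    random_seed:
        Master seed; all randomness derives from it.
    require_positions:
        Optional 1-based motif positions that must match exactly
        (stricter scan mode; empty by default).
    """

    motif: str = CANONICAL_NONAMER
    max_mismatch: int = 4
    breakpoint_radius: int = 100
    pair_gap_max: int = 80
    window_sizes: tuple[int, ...] = (100, 1000)
    min_breaks_per_window: int = 3
    null_iterations: int = 1000
    gc_tolerance: float = 0.02
    random_seed: int = 0
    require_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.motif = self.motif.upper()
        if len(self.motif) != 9 or not set(self.motif) <= set("ACGT"):
            raise ValueError(f"motif must be a 9-mer over ACGT, got {self.motif!r}")
        if not 0 <= self.max_mismatch <= 9:
            raise ValueError("max_mismatch must be in [0, 9]")
        if self.breakpoint_radius <= 0:
            raise ValueError("breakpoint_radius must be > 0")
        if self.pair_gap_max < 0:
            raise ValueError("pair_gap_max must be >= 0")
        self.window_sizes = tuple(int(w) for w in self.window_sizes)
        if any(w <= 0 for w in self.window_sizes):
            raise ValueError("window sizes must be > 0")
        if self.min_breaks_per_window < 1:
            raise ValueError("min_breaks_per_window must be >= 1")
        if self.null_iterations < 1:
            raise ValueError("null_iterations must be >= 1")
        if not 0 < self.gc_tolerance <= 1:
            raise ValueError("gc_tolerance must be in (0, 1]")
        self.require_positions = frozenset(int(p) for p in self.require_positions)
        if any(not 1 <= p <= 9 for p in self.require_positions):
            raise ValueError("require_positions are 1-based motif positions in 1..9")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window_sizes"] = list(self.window_sizes)
        d["require_positions"] = sorted(self.require_positions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "window_sizes" in d:
            d["window_sizes"] = tuple(d["window_sizes"])
        if "require_positions" in d:
            d["require_positions"] = frozenset(d["require_positions"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
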