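"""Genome tiling, per-window feature counting, and break-cluster calling.

Windows are non-overlapping tiles starting at 0; the terminal window is
truncated at the chromosome end and flagged (GC-matched sampling skips
windows shorter than 90% of nominal size). Every feature is assigned to
exactly one window by its start coordinate, so per-window counts always
sum to the genome-wide totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io_formats import BreakpointTable, GenomeSequence

WINDOW_COLUMNS = (
    "chrom",
    "start",
    "end",
    "full",
    "n_breaks",
    "n_nonamers",
    "n_cpgs",
    "gc",
    "has_cpg",
    "has_pair",
)

#: windows shorter than this fraction of nominal size are not "full"
FULL_FRACTION = 0.9


def tile_windows(genome: GenomeSequence, size: int) -> pd.DataFrame:
    """Tile every chromosome into [0,size), [size,2*size), ... windows."""
    if size <= 0:
        raise ValueError("window size must be >= 1")
    frames = []
    for chrom, length in genome.lengths.items():
        if length == 0:
            continue
        starts = np.arange(0, length, size, dtype=np.int64)
        ends = np.minimum(starts + size, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(frames, ignore_index=True)


def gc_fraction(seq: str) -> float:
    """(#G + #C) / (#non-N bases); NaN when the sequence is all N."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    non_n = int((arr != ord("N")).sum())
    if non_n == 0:
        return float("nan")
    gc = int(((arr == ord("G")) | (arr == ord("C"))).sum())
    return gc / non_n


def _per_window_gc(seq: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = np.concatenate(([0], np.cumsum((arr == ord("G")) | (arr == ord("C")))))
    is_base = np.concatenate(([0], np.cumsum(arr != ord("N"))))
    denom = is_base[ends] - is_base[starts]
    num = is_gc[ends] - is_gc[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, num / np.maximum(denom, 1), np.nan)


def _pair_spans(
    hits: pd.DataFrame, cpgs: pd.DataFrame, chrom: str, pair_gap_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Spans [s,e) of CpG-nonamer pairs with edge gap <= pair_gap_max.

    For each hit only its nearest CpG on either side is considered: if
    any qualifying pair lies inside some context, the pair using the
    nearest CpG on that side lies inside it too, so existence queries
    are unaffected.
    """
    h = hits.loc[hits["chrom"] == chrom, ["start", "end"]].to_numpy()
    c = cpgs.loc[cpgs["chrom"] == chrom, "start"].to_numpy()
    c = np.sort(c)
    if not len(h) or not len(c):
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    hs, he = h[:, 0], h[:, 1]
    idx = np.searchsorted(c, hs)
    spans_s, spans_e = [], []
    for side in (-1, 0):
        j = np.clip(idx + side, 0, len(c) - 1)
        cs, ce = c[j], c[j] + 2
        gap = np.maximum(0, np.maximum(hs, cs) - np.minimum(he, ce))
        keep = gap <= pair_gap_max
        spans_s.append(np.minimum(hs, cs)[keep])
        spans_e.append(np.maximum(he, ce)[keep])
    return np.concatenate(spans_s), np.concatenate(spans_e)


def count_features_in_windows(
    windows: pd.DataFrame,
    breaks: BreakpointTable,
    hits: pd.DataFrame,
    cpgs: pd.DataFrame,
    genome: GenomeSequence,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Per-window break/nonamer/CpG counts, GC, and pair presence.

    ``has_pair`` is true when at least one CpG-nonamer pair with edge
    gap <= ``pair_gap_max`` lies fully inside the window's +/- radius
    context ``[start - breakpoint_radius, end + breakpoint_radius)``.
    Feature assignment for the counts uses the start coordinate.
    """
    breaks.validate_against(genome)
    lengths = genome.lengths
    out_frames = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        size = int((ends - starts).max())
        n_win = len(sub)
        length = lengths[chrom]

        def _counts(positions: np.ndarray) -> np.ndarray:
            positions = np.asarray(positions, dtype=np.int64)
            if len(positions) and (
                positions.min() < 0 or positions.max() >= length
            ):
                raise ValueError(f"feature coordinate outside {chrom!r}")
            return np.bincount(positions // size, minlength=n_win)[:n_win]

        n_breaks = _counts(breaks.positions(chrom))
        hit_starts = hits.loc[hits["chrom"] == chrom, "start"].to_numpy()
        cpg_starts = cpgs.loc[cpgs["chrom"] == chrom, "start"].to_numpy()
        n_nonamers = _counts(hit_starts)
        n_cpgs = _counts(cpg_starts)
        gc = _per_window_gc(genome[chrom], starts, ends)

        has_pair = np.zeros(n_win, dtype=bool)
        ps, pe = _pair_spans(hits, cpgs, chrom, config.pair_gap_max)
        if len(ps):
            r = config.breakpoint_radius
            # window k covers span iff k*size - r <= ps and pe <= k*size + size + r
            k_min = np.ceil((pe - size - r) / size).astype(np.int64)
            k_max = np.floor((ps + r) / size).astype(np.int64)
            k_min = np.clip(k_min, 0, n_win - 1)
            k_max = np.clip(k_max, -1, n_win - 1)
            valid = k_min <= k_max
            if valid.any():
                diff = np.zeros(n_win + 1, dtype=np.int64)
                np.add.at(diff, k_min[valid], 1)
                np.add.at(diff, k_max[valid] + 1, -1)
                has_pair = np.cumsum(diff[:-1]) > 0

        out_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "full": (ends - starts) >= FULL_FRACTION * size,
                    "n_breaks": n_breaks,
                    "n_nonamers": n_nonamers,
                    "n_cpgs": n_cpgs,
                    "gc": gc,
                    "has_cpg": n_cpgs > 0,
                    "has_pair": has_pair,
                }
            )
        )
    if not out_frames:
        return pd.DataFrame(columns=list(WINDOW_COLUMNS))
    return pd.concat(out_frames, ignore_index=True)


@dataclass
class WindowClassification:
    """Partition of windows into broken / unbroken / intermediate.

    "Broken" windows are break clusters (n_breaks >= threshold);
    "unbroken" windows have exactly zero breaks; windows with an
    intermediate break count are excluded from contrasts.
    """

    broken: pd.DataFrame
    unbroken: pd.DataFrame
    intermediate: pd.DataFrame
    min_breaks: int

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "broken": len(self.broken),
            "unbroken": len(self.unbroken),
            "intermediate": len(self.intermediate),
        }


def classify_windows(stats: pd.DataFrame, min_breaks: int) -> WindowClassification:
    if min_breaks < 1:
        raise ValueError("min_breaks must be >= 1")
    broken = stats[stats["n_breaks"] >= min_breaks]
    unbroken = stats[stats["n_breaks"] == 0]
    inter = stats[(stats["n_breaks"] > 0) & (stats["n_breaks"] < min_breaks)]
    return WindowClassification(
        broken.reset_index(drop=True),
        unbroken.reset_index(drop=True),
        inter.reset_index(drop=True),
        min_breaks,
    )


def breaks_per_mb(
    breaks: BreakpointTable, genome: GenomeSequence
) -> tuple[float, pd.DataFrame, float]:
    """Global deduplicated break density and its scaling with chromosome size.

    Returns (breaks per Mb, per-chromosome table, Pearson r between
    per-chromosome break count and chromosome length). The correlation
    is NaN when there are fewer than 2 chromosomes or no breaks.
    """
    total_bases = genome.total_length
    if total_bases == 0:
        raise ValueError("zero-length genome")
    per_chrom = pd.DataFrame(
        {
            "chrom": genome.names,
            "length": [genome.lengths[c] for c in genome.names],
            "n_breaks": [
                len(np.unique(breaks.positions(c))) for c in genome.names
            ],
        }
    )
    total_breaks = int(per_chrom["n_breaks"].sum())
    density = total_breaks / (total_bases / 1e6)
    if len(per_chrom) < 2 or total_breaks == 0:
        r = float("nan")
    else:
        x = per_chrom["length"].to_numpy(dtype=float)
        y = per_chrom["n_breaks"].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            r = float("nan")
        else:
            r = float(np.corrcoef(x, y)[0, 1])
    return density, per_chrom, r
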