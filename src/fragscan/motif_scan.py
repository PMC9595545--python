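"""Degenerate nonamer scanning, CpG detection, and PWM construction.

A "cryptic nonamer" is any 9-mer within ``max_mismatch`` Hamming
distance of the canonical RSS nonamer ACAAAAACC, on either strand. Every
genome position is tested independently, so overlapping hits are
reported, and a single window may hit on both strands. N matches
nothing: it always contributes a mismatch, which conservatively
suppresses hits in masked regions.

Hits and CpG sites are returned as DataFrames (the natural tabular
container for downstream windowing and BED export):

* hits:  ``chrom, start, end, strand, mismatches, seq`` where ``seq`` is
  the observed 9-mer read 5'->3' on the hit strand;
* CpGs:  ``chrom, start, end`` with ``start`` the position of the C on
  the plus strand.

Output order is deterministic: FASTA chromosome order, then start, then
strand with "+" before "-".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io_formats import GenomeSequence

HIT_COLUMNS = ("chrom", "start", "end", "strand", "mismatches", "seq")
CPG_COLUMNS = ("chrom", "start", "end")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base codes: A=0 C=1 G=2 T=3 N=4; N differs from every motif code
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENCODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an {A,C,G,T,N} string as a uint8 code array."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        pos = int(np.argmax(arr == 255))
        raise ValueError(f"illegal character {seq[pos]!r} at offset {pos}")
    return arr


_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def hamming_distance(a: str, b: str) -> int:
    """Positions where the strings differ; N never matches anything."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths {len(a)} and {len(b)}")
    return sum(x != y or x == "N" or y == "N" for x, y in zip(a, b))


def reverse_complement(seq: str) -> str:
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"illegal character(s) {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def scan_cryptic_nonamers(
    genome: GenomeSequence, config: AnalysisConfig
) -> pd.DataFrame:
    """Find all degenerate nonamer occurrences on both strands.

    For every chromosome and every start ``i`` with ``i + 9 <= length``,
    the window is compared to the motif on the plus strand and its
    reverse complement is compared to the motif on the minus strand;
    windows with ``mismatches <= max_mismatch`` that match every
    position in ``config.require_positions`` are emitted.
    """
    motif = config.motif
    motif_enc = encode(motif)
    # Hamming(revcomp(w), m) == Hamming(w, revcomp(m)): compare windows
    # against the reverse-complemented motif for the minus strand.
    rc_motif_enc = encode(reverse_complement(motif))
    k = len(motif)

    frames = []
    for chrom, seq in genome.chromosomes.items():
        if len(seq) < k:
            continue
        arr = encode(seq)
        win = np.lib.stride_tricks.sliding_window_view(arr, k)
        plus_mm = (win != motif_enc[None, :]).sum(axis=1, dtype=np.int16)
        minus_mm = (win != rc_motif_enc[None, :]).sum(axis=1, dtype=np.int16)
        plus_ok = plus_mm <= config.max_mismatch
        minus_ok = minus_mm <= config.max_mismatch
        for p in config.require_positions:
            # plus strand: window base p must equal motif base p
            plus_ok &= win[:, p - 1] == motif_enc[p - 1]
            # minus strand: revcomp(window)[p-1] == motif[p-1]
            # <=> window[k-p] == complement(motif[p-1])
            comp = encode(reverse_complement(motif[p - 1]))[0]
            minus_ok &= win[:, k - p] == comp

        for strand, ok, mm in (("+", plus_ok, plus_mm), ("-", minus_ok, minus_mm)):
            starts = np.flatnonzero(ok)
            if not len(starts):
                continue
            seqs = [seq[s : s + k] for s in starts]
            if strand == "-":
                seqs = [reverse_complement(s) for s in seqs]
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts.astype(np.int64),
                        "end": starts.astype(np.int64) + k,
                        "strand": strand,
                        "mismatches": mm[starts].astype(np.int64),
                        "seq": seqs,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=list(HIT_COLUMNS))
    out = pd.concat(frames, ignore_index=True)
    chrom_order = {name: i for i, name in enumerate(genome.names)}
    out["_c"] = out["chrom"].map(chrom_order)
    out = out.sort_values(["_c", "start", "strand"], kind="mergesort")
    return out.drop(columns="_c").reset_index(drop=True)


def scan_cpg(genome: GenomeSequence) -> pd.DataFrame:
    """Locate every CG dinucleotide (start = position of the C)."""
    frames = []
    for chrom, seq in genome.chromosomes.items():
        if len(seq) < 2:
            continue
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        starts = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        if len(starts):
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts.astype(np.int64),
                        "end": starts.astype(np.int64) + 2,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=list(CPG_COLUMNS))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# position weight matrix

PWM_ROWS = ("A", "C", "G", "T")


def build_pwm(hit_seqs) -> tuple[np.ndarray, int]:
    """Base-frequency matrix (4 rows A,C,G,T x 9 columns) from observed 9-mers.

    ``hit_seqs`` may be a hits DataFrame (its ``seq`` column is used,
    already in hit-strand orientation) or any iterable of 9-mers. N
    bases distribute no mass: each column is normalized over the hits
    that carry a real base there. Returns ``(matrix, n_hits)``.
    """
    if isinstance(hit_seqs, pd.DataFrame):
        seqs = list(hit_seqs["seq"])
    else:
        seqs = list(hit_seqs)
    if not seqs:
        raise ValueError("cannot build a PWM from an empty hit list")
    k = len(seqs[0])
    counts = np.zeros((4, k), dtype=np.int64)
    contributing = np.zeros(k, dtype=np.int64)
    for s in seqs:
        if len(s) != k:
            raise ValueError("hit sequences must all have the same length")
        for j, base in enumerate(s):
            if base == "N":
                continue
            counts["ACGT".index(base), j] += 1
            contributing[j] += 1
    if (contributing == 0).any():
        raise ValueError("a PWM column received no contributing bases")
    pwm = counts / contributing[None, :]
    return pwm, len(seqs)


def pwm_conservation(pwm: np.ndarray, threshold: float) -> pd.DataFrame:
    """Per-position consensus base, max frequency and conserved flag.

    A position is conserved iff its maximum base frequency is at least
    ``threshold``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    best = pwm.argmax(axis=0)
    return pd.DataFrame(
        {
            "position": np.arange(1, pwm.shape[1] + 1),
            "consensus": [PWM_ROWS[i] for i in best],
            "max_frequency": pwm.max(axis=0),
            "conserved": pwm.max(axis=0) >= threshold,
        }
    )


def write_pwm_tsv(pwm: np.ndarray, path) -> None:
    """Export as a 4x9 tab-separated matrix (rows A,C,G,T) for logo tools."""
    df = pd.DataFrame(pwm, index=list(PWM_ROWS))
    df.columns = [str(i + 1) for i in range(pwm.shape[1])]
    df.to_csv(path, sep="\t", index_label="base")


def write_hits_bed(hits: pd.DataFrame, path) -> None:
    """Export hits as BED6; score = 9 - mismatches."""
    with open(path, "w") as fh:
        for row in hits.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.seq}\t"
                f"{9 - row.mismatches}\t{row.strand}\n"
            )


def write_cpgs_bed(cpgs: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in cpgs.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tCpG\n")
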