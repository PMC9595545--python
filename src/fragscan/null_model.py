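"""GC-matched control sampling and iteration-based null distributions.

Each broken ("reference") window is matched to one control drawn
uniformly without replacement from the unbroken pool within the GC
tolerance; a fresh sample is drawn per iteration (with replacement
across iterations). Child seeds derive deterministically from
``(master_seed, iteration)`` so the full run is bit-reproducible and
iterations could be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd


@dataclass
class NullSample:
    """One GC-matched draw of control windows."""

    indices: np.ndarray  # positional indices into the eligible pool
    iteration: int
    seed: int
    target_gc: np.ndarray
    achieved_gc: np.ndarray

    def windows(self, pool: pd.DataFrame) -> pd.DataFrame:
        return eligible_pool(pool).iloc[self.indices]


@dataclass
class NullDistribution:
    """Per-iteration summary values over the resampled control sets."""

    values: np.ndarray  # shape (iterations,) or (iterations, k)
    iterations: int
    seed: int

    def summary(self) -> dict:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        out = {}
        for j in range(v.shape[1]):
            col = v[:, j]
            out[j] = {
                "mean": float(col.mean()),
                "min": float(col.min()),
                "max": float(col.max()),
                "p2.5": float(np.percentile(col, 2.5)),
                "p50": float(np.percentile(col, 50)),
                "p97.5": float(np.percentile(col, 97.5)),
            }
        return out


def eligible_pool(pool: pd.DataFrame) -> pd.DataFrame:
    """Unbroken, full-length, non-all-N windows only."""
    ok = (pool["n_breaks"] == 0) & pool["full"] & pool["gc"].notna()
    return pool[ok].reset_index(drop=True)


def sample_gc_matched(
    pool: pd.DataFrame,
    reference: pd.DataFrame,
    tolerance: float,
    seed: int,
    iteration: int = 0,
) -> NullSample:
    """Match one control window to every reference window.

    The pool is filtered to unbroken, full-length, defined-GC windows.
    For each reference window (in order), an eligible unused pool
    window with |GC difference| <= tolerance is drawn uniformly without
    replacement. Raises when a reference window has no remaining
    eligible partner, naming the window and its GC. Deterministic for a
    given (seed, iteration).
    """
    pool = eligible_pool(pool)
    if len(pool) < len(reference):
        raise ValueError(
            f"pool ({len(pool)} eligible windows) smaller than reference "
            f"({len(reference)})"
        )
    rng = np.random.default_rng(np.random.SeedSequence((seed, iteration)))
    pool_gc = pool["gc"].to_numpy()
    used = np.zeros(len(pool), dtype=bool)
    chosen = np.empty(len(reference), dtype=np.int64)
    target = reference["gc"].to_numpy()
    for i, g in enumerate(target):
        candidates = np.flatnonzero((np.abs(pool_gc - g) <= tolerance) & ~used)
        if not len(candidates):
            ref_row = reference.iloc[i]
            raise ValueError(
                f"no eligible control for reference window "
                f"{ref_row['chrom']}:{ref_row['start']}-{ref_row['end']} "
                f"(GC {g:.4f}, tolerance {tolerance})"
            )
        pick = candidates[rng.integers(len(candidates))]
        used[pick] = True
        chosen[i] = pick
    achieved = pool_gc[chosen]
    assert (np.abs(achieved - target) <= tolerance + 1e-12).all()
    return NullSample(chosen, iteration, seed, target, achieved)


def iterate_null(
    pool: pd.DataFrame,
    reference: pd.DataFrame,
    iterations: int,
    seed: int,
    summarizer: Callable[[pd.DataFrame], float | Sequence[float]],
    tolerance: float = 0.02,
) -> NullDistribution:
    """Build a null distribution of control-set summaries.

    Iteration ``i`` draws a GC-matched sample seeded from ``(seed, i)``
    and applies ``summarizer`` to the selected windows.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    pool = eligible_pool(pool)
    values = []
    for i in range(iterations):
        sample = sample_gc_matched(pool, reference, tolerance, seed, i)
        values.append(summarizer(pool.iloc[sample.indices]))
    return NullDistribution(np.asarray(values, dtype=float), iterations, seed)


def empirical_p(observed: float, null: NullDistribution, side: str = "upper") -> float:
    """Add-one empirical p-value of an observed summary against the null.

    p = (1 + #{iterations as or more extreme}) / (1 + iterations);
    ``side`` is "upper", "lower" or "two-sided" (twice the smaller
    one-sided value, capped at 1).
    """
    v = np.asarray(null.values, dtype=float)
    if v.ndim != 1:
        raise ValueError("empirical_p expects a scalar-summary null")
    if not len(v):
        raise ValueError("null distribution is empty")
    b = len(v)
    p_upper = (1 + int((v >= observed).sum())) / (1 + b)
    p_lower = (1 + int((v <= observed).sum())) / (1 + b)
    if side == "upper":
        return p_upper
    if side == "lower":
        return p_lower
    if side == "two-sided":
        return min(1.0, 2 * min(p_upper, p_lower))
    raise ValueError(f"unknown side {side!r}")


def pct_windows_with_cpg(windows: pd.DataFrame) -> float:
    """Summarizer: percentage of windows containing at least one CpG."""
    return float(windows["has_cpg"].mean() * 100)


def pct_windows_with_pair(windows: pd.DataFrame) -> float:
    """Summarizer: percentage of windows with a CpG-nonamer pair."""
    return float(windows["has_pair"].mean() * 100)


def mean_nonamers(windows: pd.DataFrame) -> float:
    return float(windows["n_nonamers"].mean())
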