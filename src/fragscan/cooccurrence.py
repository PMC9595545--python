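"""Breakpoint / nonamer / CpG co-occurrence statistics.

Conventions:

* the context of a point break at ``p`` is the symmetric interval
  ``[p - radius, p + radius + 1)``; a feature is "within radius" iff its
  interval overlaps that context;
* the distance between a CpG and a nonamer is the edge-to-edge gap,
  ``max(0, later.start - earlier.end)`` — overlapping features have
  gap 0.

The paper-style contrasts (chi-square on pair presence, Mann-Whitney
and t-test on per-window counts) are computed here; when more than one
contrast is emitted in a run, Benjamini-Hochberg adjusted p-values are
reported alongside the raw ones, which remain primary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AnalysisConfig
from .io_formats import BreakpointTable
from .window_analysis import WindowClassification


# ---------------------------------------------------------------------------
# proximity

@dataclass
class ProximitySummary:
    n_breakpoints: int
    n_with_nonamer: int
    n_with_cpg: int
    n_with_both: int
    radius: int

    @property
    def fraction_with_nonamer(self) -> float:
        return self.n_with_nonamer / self.n_breakpoints if self.n_breakpoints else float("nan")

    @property
    def fraction_with_cpg(self) -> float:
        return self.n_with_cpg / self.n_breakpoints if self.n_breakpoints else float("nan")

    @property
    def fraction_with_both(self) -> float:
        return self.n_with_both / self.n_breakpoints if self.n_breakpoints else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_breakpoints": self.n_breakpoints,
            "n_with_nonamer": self.n_with_nonamer,
            "n_with_cpg": self.n_with_cpg,
            "n_with_both": self.n_with_both,
            "fraction_with_nonamer": self.fraction_with_nonamer,
            "fraction_with_cpg": self.fraction_with_cpg,
            "fraction_with_both": self.fraction_with_both,
            "radius": self.radius,
        }


def _within_radius_mask(
    positions: np.ndarray, starts: np.ndarray, width: int, radius: int
) -> np.ndarray:
    """For each break position, does any [s, s+width) overlap its context?

    Overlap with [p - radius, p + radius + 1) requires
    s < p + radius + 1 and s + width > p - radius.
    """
    starts = np.sort(starts)
    lo = np.searchsorted(starts, positions - radius - width, side="right")
    hi = np.searchsorted(starts, positions + radius + 1, side="left")
    return hi > lo


def proximity_summary(
    breaks: BreakpointTable,
    hits: pd.DataFrame,
    cpgs: pd.DataFrame,
    radius: int,
) -> ProximitySummary:
    """Count breakpoints with a nonamer / CpG / both within the radius."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    n_non = n_cpg = n_both = 0
    for chrom, sub in breaks.df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        h = hits.loc[hits["chrom"] == chrom, "start"].to_numpy()
        c = cpgs.loc[cpgs["chrom"] == chrom, "start"].to_numpy()
        near_h = _within_radius_mask(pos, h, 9, radius)
        near_c = _within_radius_mask(pos, c, 2, radius)
        n_non += int(near_h.sum())
        n_cpg += int(near_c.sum())
        n_both += int((near_h & near_c).sum())
    return ProximitySummary(len(breaks), n_non, n_cpg, n_both, radius)


# ---------------------------------------------------------------------------
# CpG-nonamer distances

def _edge_gap(s1: int, e1: int, s2: int, e2: int) -> int:
    return max(0, max(s1, s2) - min(e1, e2))


def nearest_pair_gap(
    chrom: str,
    position: int,
    hits: pd.DataFrame,
    cpgs: pd.DataFrame,
    radius: int,
    mismatch: int | None = None,
) -> int | None:
    """Minimal CpG-nonamer edge gap among features within radius of a break.

    Both the CpG and the nonamer must overlap the break context
    ``[position - radius, position + radius + 1)``. Returns None when no
    such pair exists. ``mismatch`` restricts the nonamers to one
    mismatch class.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    h = hits[hits["chrom"] == chrom]
    if mismatch is not None:
        h = h[h["mismatches"] == mismatch]
    c = cpgs[cpgs["chrom"] == chrom]
    lo, hi = position - radius, position + radius + 1
    h = h[(h["start"] < hi) & (h["end"] > lo)]
    c = c[(c["start"] < hi) & (c["end"] > lo)]
    if not len(h) or not len(c):
        return None
    best: int | None = None
    for hs, he in zip(h["start"], h["end"]):
        for cs, ce in zip(c["start"], c["end"]):
            g = _edge_gap(hs, he, cs, ce)
            if best is None or g < best:
                best = g
                if best == 0:
                    return 0
    return best


@dataclass
class DistanceSummary:
    """Per-breakpoint minimal CpG-nonamer gaps and their summaries."""

    per_break: pd.DataFrame  # chrom, pos, gap (NaN when absent)
    pair_gap_max: int
    by_mismatch: dict[int, pd.Series] = field(default_factory=dict)

    @property
    def gaps(self) -> np.ndarray:
        return self.per_break["gap"].dropna().to_numpy()

    @property
    def empty(self) -> bool:
        return len(self.gaps) == 0

    @property
    def median(self) -> float:
        return float(np.median(self.gaps)) if not self.empty else float("nan")

    @property
    def fraction_below_50(self) -> float:
        g = self.gaps
        return float((g < 50).mean()) if len(g) else float("nan")

    @property
    def fraction_within_gap_max(self) -> float:
        g = self.gaps
        return float((g <= self.pair_gap_max).mean()) if len(g) else float("nan")

    def to_dict(self) -> dict:
        d = {
            "n_breaks": int(len(self.per_break)),
            "n_with_pair": int(len(self.gaps)),
            "median_gap": self.median,
            "fraction_below_50": self.fraction_below_50,
            "fraction_within_gap_max": self.fraction_within_gap_max,
            "pair_gap_max": self.pair_gap_max,
            "empty": self.empty,
        }
        d["by_mismatch"] = {
            int(m): {
                "n_with_pair": int(s.notna().sum()),
                "median_gap": float(s.dropna().median()) if s.notna().any() else None,
            }
            for m, s in self.by_mismatch.items()
        }
        return d


def distance_distribution(
    breaks: BreakpointTable,
    hits: pd.DataFrame,
    cpgs: pd.DataFrame,
    config: AnalysisConfig,
    mismatch_classes: tuple[int, ...] = (2, 3, 4),
) -> DistanceSummary:
    """Minimal CpG-nonamer gap per breakpoint, overall and per mismatch class."""
    rows = []
    per_class: dict[int, list] = {m: [] for m in mismatch_classes}
    for row in breaks.df.itertuples(index=False):
        g = nearest_pair_gap(
            row.chrom, row.pos, hits, cpgs, config.breakpoint_radius
        )
        rows.append((row.chrom, row.pos, np.nan if g is None else g))
        for m in mismatch_classes:
            gm = nearest_pair_gap(
                row.chrom, row.pos, hits, cpgs, config.breakpoint_radius, mismatch=m
            )
            per_class[m].append(np.nan if gm is None else gm)
    per_break = pd.DataFrame(rows, columns=["chrom", "pos", "gap"])
    by_mismatch = {m: pd.Series(v, dtype=float) for m, v in per_class.items()}
    return DistanceSummary(per_break, config.pair_gap_max, by_mismatch)


# ---------------------------------------------------------------------------
# classical tests

def chi_square_2x2(
    table, yates: bool = False
) -> tuple[float, float, int]:
    """Chi-square test of independence on a 2x2 contingency table.

    statistic = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); with the Yates
    flag, |ad - bc| is reduced by N/2 before squaring (floored at 0).
    Returns (statistic, p, df=1). Raises on a zero marginal.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("cells must be non-negative")
    a, b, c, d = t.ravel()
    n = a + b + c + d
    marginals = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in marginals):
        raise ValueError(f"zero marginal in table {t.tolist()}")
    det = abs(a * d - b * c)
    if yates:
        det = max(0.0, det - n / 2)
    stat = n * det**2 / np.prod(marginals)
    p = float(sps.chi2.sf(stat, df=1))
    return float(stat), p, 1


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U from rank sums with midranks for ties.

    Returns (U of the first sample, two-sided p). The p-value uses the
    normal approximation with tie correction and continuity correction;
    a degenerate variance (all values tied) yields p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not len(x) or not len(y):
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12 * (n + 1 - tie_term)
    if var <= 0:
        return float(u1), 1.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
    p = float(min(1.0, 2 * sps.norm.sf(max(z, 0.0))))
    return float(u1), p


def two_sample_t(x, y, welch: bool = True) -> tuple[float, float, float]:
    """Two-sided two-sample t-test (Welch by default).

    Returns (t, p, df). Raises when both samples have zero variance or
    either has fewer than 2 observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue), float(res.df)


def benjamini_hochberg(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# broken-vs-unbroken window contrast

def summarize_window_contrast(
    classification: WindowClassification,
    controls: pd.DataFrame | None = None,
) -> dict:
    """Compare broken windows against controls (default: all unbroken).

    Reports per-class means/medians and totals of nonamers, CpGs and
    breaks; percentages of windows with CpGs and with CpG-nonamer
    pairs; a chi-square on the pair-presence x class table; a
    Mann-Whitney on per-window nonamer counts; and a t-test on the same
    counts. Chi-square degeneracy (a zero marginal) is reported as a
    None statistic rather than an error.
    """
    broken = classification.broken
    unbroken = classification.unbroken if controls is None else controls
    if not len(broken) or not len(unbroken):
        raise ValueError("both window classes must be non-empty")

    def _cls(df: pd.DataFrame) -> dict:
        return {
            "n_windows": int(len(df)),
            "mean_nonamers": float(df["n_nonamers"].mean()),
            "median_nonamers": float(df["n_nonamers"].median()),
            "total_nonamers": int(df["n_nonamers"].sum()),
            "mean_cpgs": float(df["n_cpgs"].mean()),
            "median_cpgs": float(df["n_cpgs"].median()),
            "total_cpgs": int(df["n_cpgs"].sum()),
            "mean_breaks": float(df["n_breaks"].mean()),
            "total_breaks": int(df["n_breaks"].sum()),
            "pct_with_cpg": float(df["has_cpg"].mean() * 100),
            "pct_with_pair": float(df["has_pair"].mean() * 100),
        }

    table = [
        [int(broken["has_pair"].sum()), int((~broken["has_pair"]).sum())],
        [int(unbroken["has_pair"].sum()), int((~unbroken["has_pair"]).sum())],
    ]
    try:
        chi_stat, chi_p, _ = chi_square_2x2(table)
    except ValueError:
        chi_stat, chi_p = None, None
    u, u_p = mann_whitney_u(
        broken["n_nonamers"].to_numpy(), unbroken["n_nonamers"].to_numpy()
    )
    try:
        t, t_p, t_df = two_sample_t(
            broken["n_nonamers"].to_numpy(), unbroken["n_nonamers"].to_numpy()
        )
    except ValueError:
        t = t_p = t_df = None

    raw = [p for p in (chi_p, u_p, t_p) if p is not None]
    adjusted = benjamini_hochberg(raw).tolist() if len(raw) > 1 else raw
    return {
        "min_breaks": classification.min_breaks,
        "broken": _cls(broken),
        "unbroken": _cls(unbroken),
        "pair_table": table,
        "chi_square": {"statistic": chi_stat, "p": chi_p, "df": 1},
        "mann_whitney": {"U": u, "p": u_p},
        "t_test": {"t": t, "p": t_p, "df": t_df},
        "bh_adjusted_p": adjusted,
    }
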