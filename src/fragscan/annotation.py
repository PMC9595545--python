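"""Stratification by promoters, chromatin class (Giemsa bands) and cohort.

Chromatin classes are derived from cytoband gieStain labels: gneg is
euchromatin; gpos25/50/75/100 and gvar are heterochromatin; acen and
stalk (centromeres, rDNA stalks) are excluded from both classes. Breaks
falling outside any band are counted separately as "uncovered".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .cooccurrence import chi_square_2x2, nearest_pair_gap
from .io_formats import BreakpointTable, RegionSet

STAIN_CLASSES = {
    "gneg": "euchromatin",
    "gpos25": "heterochromatin",
    "gpos50": "heterochromatin",
    "gpos75": "heterochromatin",
    "gpos100": "heterochromatin",
    "gvar": "heterochromatin",
    "acen": "excluded",
    "stalk": "excluded",
}


def stain_to_class(label: str) -> str:
    try:
        return STAIN_CLASSES[label]
    except KeyError:
        raise ValueError(f"unrecognized gieStain label {label!r}") from None


def intersect_regions(a: RegionSet, b: RegionSet) -> RegionSet:
    """All maximal overlap intervals between two region sets.

    Inputs are flattened first; overlap requires strictly positive
    shared length (half-open abutment does not overlap).
    """
    fa, fb = a.flatten(), b.flatten()
    rows = []
    for chrom, sub_a in fa.df.groupby("chrom", sort=False):
        sub_b = fb.df[fb.df["chrom"] == chrom]
        if not len(sub_b):
            continue
        ia = jb = 0
        sa = sub_a[["start", "end"]].to_numpy()
        sb = sub_b[["start", "end"]].to_numpy()
        while ia < len(sa) and jb < len(sb):
            s = max(sa[ia, 0], sb[jb, 0])
            e = min(sa[ia, 1], sb[jb, 1])
            if s < e:
                rows.append((chrom, int(s), int(e), None))
            if sa[ia, 1] <= sb[jb, 1]:
                ia += 1
            else:
                jb += 1
    df = pd.DataFrame(rows, columns=list(RegionSet.COLUMNS))
    return RegionSet(f"{a.name}&{b.name}", df, flattened=True)


def _locate(positions: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Index of the disjoint sorted interval containing each position, or -1."""
    idx = np.searchsorted(starts, positions, side="right") - 1
    out = np.full(len(positions), -1, dtype=np.int64)
    ok = idx >= 0
    ok[ok] &= positions[ok] < ends[idx[ok]]
    out[ok] = idx[ok]
    return out


def _break_has_pair(
    breaks_df: pd.DataFrame,
    hits: pd.DataFrame,
    cpgs: pd.DataFrame,
    config: AnalysisConfig,
) -> np.ndarray:
    """Per-break flag: CpG-nonamer pair with gap <= pair_gap_max in radius."""
    flags = np.zeros(len(breaks_df), dtype=bool)
    for i, row in enumerate(breaks_df.itertuples(index=False)):
        g = nearest_pair_gap(
            row.chrom, row.pos, hits, cpgs, config.breakpoint_radius
        )
        flags[i] = g is not None and g <= config.pair_gap_max
    return flags


def chromatin_breakdown(
    breaks: BreakpointTable,
    hits: pd.DataFrame,
    cpgs: pd.DataFrame,
    cytobands: RegionSet,
    config: AnalysisConfig,
) -> dict:
    """Per-chromatin-class break fractions and pair co-occurrence.

    Returns a stratified report with, per class, the break count, its
    fraction of classified breaks, and the fraction of its breaks with
    CpG-nonamer clustering, plus a 2x2 chi-square of class x pair
    presence (euchromatin vs heterochromatin).
    """
    if not len(cytobands):
        raise ValueError("empty cytoband region set")
    classes = cytobands.df["label"].map(stain_to_class)  # validates labels
    band = cytobands.sorted()
    per_break_class = []
    for row in breaks.df.itertuples(index=False):
        sub = band.df[band.df["chrom"] == row.chrom]
        idx = _locate(
            np.array([row.pos]),
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
        )[0]
        if idx < 0:
            per_break_class.append("uncovered")
        else:
            per_break_class.append(stain_to_class(sub.iloc[idx]["label"]))
    per_break_class = np.array(per_break_class)
    has_pair = _break_has_pair(breaks.df, hits, cpgs, config)

    classified = np.isin(per_break_class, ("euchromatin", "heterochromatin"))
    n_classified = int(classified.sum())
    strata = {}
    for cls in ("euchromatin", "heterochromatin", "excluded", "uncovered"):
        mask = per_break_class == cls
        n = int(mask.sum())
        strata[cls] = {
            "n_breaks": n,
            "fraction_of_classified": (
                n / n_classified
                if n_classified and cls in ("euchromatin", "heterochromatin")
                else None
            ),
            "fraction_with_pair": float(has_pair[mask].mean()) if n else None,
        }
    eu = per_break_class == "euchromatin"
    het = per_break_class == "heterochromatin"
    table = [
        [int(has_pair[eu].sum()), int((~has_pair[eu]).sum())],
        [int(has_pair[het].sum()), int((~has_pair[het]).sum())],
    ]
    try:
        chi_stat, chi_p, _ = chi_square_2x2(table)
    except ValueError:
        chi_stat = chi_p = None
    assert sum(s["n_breaks"] for s in strata.values()) == len(breaks)
    return {
        "strata": strata,
        "n_classified": n_classified,
        "pair_table": table,
        "chi_square": {"statistic": chi_stat, "p": chi_p, "df": 1},
    }


def promoter_breakdown(
    breaks: BreakpointTable,
    promoters: RegionSet,
    hits: pd.DataFrame,
    cpgs: pd.DataFrame,
    config: AnalysisConfig,
) -> dict:
    """Breaks inside promoter intervals and their pair clustering.

    A break is "in promoter" iff its position lies inside a (flattened)
    promoter interval under half-open semantics.
    """
    flat = promoters.flatten()
    in_prom = np.zeros(len(breaks), dtype=bool)
    for chrom, sub in breaks.df.groupby("chrom", sort=False):
        bands = flat.df[flat.df["chrom"] == chrom]
        if not len(bands):
            continue
        loc = _locate(
            sub["pos"].to_numpy(),
            bands["start"].to_numpy(),
            bands["end"].to_numpy(),
        )
        in_prom[sub.index.to_numpy()] = loc >= 0
    prom_df = breaks.df[in_prom]
    has_pair = _break_has_pair(prom_df, hits, cpgs, config)
    n_in = int(in_prom.sum())
    return {
        "n_breaks": len(breaks),
        "n_in_promoters": n_in,
        "fraction_in_promoters": n_in / len(breaks) if len(breaks) else float("nan"),
        "n_in_promoters_with_pair": int(has_pair.sum()),
        "fraction_with_pair": float(has_pair.mean()) if n_in else float("nan"),
    }


def cohort_compare(stats_by_cohort: dict[str, pd.DataFrame]) -> dict:
    """Per-cohort means over broken windows plus a pooled chi-square.

    ``stats_by_cohort`` maps cohort name to that cohort's broken-window
    WindowStats table. Reports per-window means and totals of nonamers,
    CpGs and breaks; the ratio table between the two cohorts; and a
    chi-square on the pooled (nonamer, CpG) totals.
    """
    if len(stats_by_cohort) != 2:
        raise ValueError("cohort_compare needs exactly two cohorts")
    for name, df in stats_by_cohort.items():
        if not len(df):
            raise ValueError(f"cohort {name!r} has no broken windows")
    (name_a, df_a), (name_b, df_b) = stats_by_cohort.items()

    def _means(df: pd.DataFrame) -> dict:
        return {
            "n_windows": int(len(df)),
            "mean_nonamers": float(df["n_nonamers"].mean()),
            "mean_cpgs": float(df["n_cpgs"].mean()),
            "mean_breaks": float(df["n_breaks"].mean()),
            "total_nonamers": int(df["n_nonamers"].sum()),
            "total_cpgs": int(df["n_cpgs"].sum()),
            "total_breaks": int(df["n_breaks"].sum()),
        }

    ma, mb = _means(df_a), _means(df_b)
    ratios = {
        key: (ma[key] / mb[key] if mb[key] else float("nan"))
        for key in ("mean_nonamers", "mean_cpgs", "mean_breaks")
    }
    table = [
        [ma["total_nonamers"], ma["total_cpgs"]],
        [mb["total_nonamers"], mb["total_cpgs"]],
    ]
    try:
        chi_stat, chi_p, _ = chi_square_2x2(table)
    except ValueError:
        chi_stat = chi_p = None
    return {
        "cohorts": {name_a: ma, name_b: mb},
        "ratios": ratios,
        "pooled_table": table,
        "chi_square": {"statistic": chi_stat, "p": chi_p, "df": 1},
    }
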