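"""Readers and writers for the external file formats.

All internal coordinates are 0-based half-open (BED-native). A breakpoint
is a single base position; BED intervals wider than one base contribute
their start. Every downstream module consumes the containers defined
here and never touches files directly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .config import VALID_BASES

COHORTS = ("lymphoid", "nonlymphoid", "unlabeled")

_ILLEGAL = re.compile(r"[^ACGTN]")


@dataclass
class GenomeSequence:
    """Named chromosome sequences over the {A,C,G,T,N} alphabet."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            m = _ILLEGAL.search(seq)
            if m:
                raise ValueError(
                    f"illegal character {m.group()!r} in record {name!r} "
                    f"at offset {m.start()}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes


@dataclass
class BreakpointTable:
    """Per-patient breakpoint positions with cohort/gene labels.

    Backed by a DataFrame with columns
    ``chrom, pos, cohort, gene, source_id`` in file order.
    """

    df: pd.DataFrame

    COLUMNS = ("chrom", "pos", "cohort", "gene", "source_id")

    def __post_init__(self) -> None:
        df = self.df.reindex(columns=list(self.COLUMNS))
        if len(df):
            if (df["pos"] < 0).any():
                bad = df[df["pos"] < 0].iloc[0]
                raise ValueError(f"negative coordinate {bad['chrom']}:{bad['pos']}")
            unknown = set(df["cohort"].fillna("unlabeled")) - set(COHORTS)
            if unknown:
                raise ValueError(f"unknown cohort label(s): {sorted(unknown)}")
            dup = df.duplicated(subset=["chrom", "pos", "source_id"], keep=False)
            # identical (chrom, pos, source_id) triples are double entries
            if (dup & df["source_id"].notna()).any():
                bad = df[dup & df["source_id"].notna()].iloc[0]
                raise ValueError(
                    f"duplicate record {bad['chrom']}:{bad['pos']} "
                    f"from source {bad['source_id']!r}"
                )
        df["cohort"] = df["cohort"].fillna("unlabeled")
        df["pos"] = df["pos"].astype(np.int64)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def validate_against(self, genome: GenomeSequence) -> None:
        lengths = genome.lengths
        for chrom, sub in self.df.groupby("chrom", sort=False):
            if chrom not in lengths:
                raise ValueError(f"breakpoint chromosome {chrom!r} not in genome")
            if (sub["pos"] >= lengths[chrom]).any():
                bad = sub[sub["pos"] >= lengths[chrom]].iloc[0]
                raise ValueError(
                    f"breakpoint {chrom}:{bad['pos']} beyond chromosome "
                    f"end {lengths[chrom]}"
                )

    def positions(self, chrom: str) -> np.ndarray:
        return np.sort(self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy())


@dataclass
class RegionSet:
    """Named set of half-open intervals with an optional per-interval label."""

    name: str
    df: pd.DataFrame  # columns: chrom, start, end, label
    flattened: bool = False

    COLUMNS = ("chrom", "start", "end", "label")

    def __post_init__(self) -> None:
        df = self.df.reindex(columns=list(self.COLUMNS))
        if len(df):
            if (df["start"] < 0).any():
                raise ValueError(f"negative start in region set {self.name!r}")
            if (df["end"] <= df["start"]).any():
                bad = df[df["end"] <= df["start"]].iloc[0]
                raise ValueError(
                    f"empty or inverted interval {bad['chrom']}:"
                    f"{bad['start']}-{bad['end']} in region set {self.name!r}"
                )
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def sorted(self) -> "RegionSet":
        df = self.df.sort_values(["chrom", "start", "end"], kind="mergesort")
        return RegionSet(self.name, df.reset_index(drop=True), self.flattened)

    def flatten(self) -> "RegionSet":
        """Merge overlapping/abutting intervals; labels are dropped."""
        rows = []
        for chrom, sub in self.sorted().df.groupby("chrom", sort=False):
            cur_s = cur_e = None
            for s, e in zip(sub["start"], sub["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e, None))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                rows.append((chrom, cur_s, cur_e, None))
        df = pd.DataFrame(rows, columns=list(self.COLUMNS))
        return RegionSet(self.name, df, flattened=True)

    def total_length(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())


# ---------------------------------------------------------------------------
# readers

def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a (possibly multi-record, wrapped) FASTA file.

    Sequences are uppercased; any character outside {A,C,G,T,N} raises
    with the offending record and offset. Duplicate record names and
    empty sequences are rejected.
    """
    chromosomes: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chromosomes:
            raise ValueError(f"duplicate FASTA record name {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {record.id!r}")
        chromosomes[record.id] = seq
    if not chromosomes:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(chromosomes)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_breakpoints(path: str | Path, dialect: str = "bed") -> BreakpointTable:
    """Read breakpoints from a BED or TSV file.

    BED: 0-based half-open intervals; the breakpoint is the interval
    start; an optional 4th column is kept as ``source_id``. TSV: columns
    ``chrom, position`` plus optional ``cohort, gene, source_id``.
    """
    if dialect not in ("bed", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if dialect == "bed":
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                if start < 0:
                    raise ValueError(f"{path}:{lineno}: negative coordinate")
                if end <= start:
                    raise ValueError(
                        f"{path}:{lineno}: empty interval {chrom}:{start}-{end}"
                    )
                source = fields[3] if len(fields) > 3 and fields[3] != "." else None
                rows.append((chrom, start, "unlabeled", None, source))
            else:
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: TSV needs >= 2 columns")
                chrom, pos = fields[0], int(fields[1])
                cohort = fields[2] if len(fields) > 2 and fields[2] else "unlabeled"
                gene = fields[3] if len(fields) > 3 and fields[3] else None
                source = fields[4] if len(fields) > 4 and fields[4] else None
                rows.append((chrom, pos, cohort, gene, source))
    df = pd.DataFrame(rows, columns=list(BreakpointTable.COLUMNS))
    return BreakpointTable(df)


def write_breakpoints_bed(table: BreakpointTable, path: str | Path) -> None:
    """Write breakpoints as single-base BED interval per record."""
    with open(path, "w") as fh:
        for row in table.df.itertuples(index=False):
            name = row.source_id if row.source_id else "."
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{name}\n")


def read_regions_bed(path: str | Path, name: str | None = None) -> RegionSet:
    """Read a generic BED3+ region file; column 4 becomes the label."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            label = fields[3] if len(fields) > 3 else None
            rows.append((fields[0], int(fields[1]), int(fields[2]), label))
    df = pd.DataFrame(rows, columns=list(RegionSet.COLUMNS))
    return RegionSet(name or Path(path).stem, df)


def write_regions_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in regions.df.itertuples(index=False):
            label = row.label if row.label else "."
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{label}\n")


def read_cytoband(path: str | Path) -> RegionSet:
    """Read a UCSC cytoBand-style TSV (chrom, start, end, band, gieStain).

    The gieStain value becomes the per-interval label. Exactly five
    columns are required; a missing gieStain column is an error.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(
                    f"{path}:{lineno}: cytoBand rows need 5 columns "
                    f"(chrom, start, end, name, gieStain); got {len(fields)}"
                )
            rows.append((fields[0], int(fields[1]), int(fields[2]), fields[4]))
    df = pd.DataFrame(rows, columns=list(RegionSet.COLUMNS))
    return RegionSet("cytoband", df)


# ---------------------------------------------------------------------------
# operations

def dedupe_breakpoints(table: BreakpointTable) -> tuple[BreakpointTable, int]:
    """Collapse to one record per (chromosome, position).

    The cohort label is kept when all records at a position agree and
    reset to "unlabeled" otherwise. Returns the deduplicated table and
    the number of removed duplicate records.
    """
    df = table.df
    if not len(df):
        return BreakpointTable(df.copy()), 0
    n_before = len(df)
    grouped = df.groupby(["chrom", "pos"], sort=False)
    rows = []
    for (chrom, pos), sub in grouped:
        cohorts = set(sub["cohort"])
        cohort = cohorts.pop() if len(cohorts) == 1 else "unlabeled"
        genes = set(sub["gene"].dropna())
        gene = genes.pop() if len(genes) == 1 else None
        rows.append((chrom, pos, cohort, gene, None))
    out = pd.DataFrame(rows, columns=list(BreakpointTable.COLUMNS))
    return BreakpointTable(out), n_before - len(out)
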