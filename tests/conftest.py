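import numpy as np
import pandas as pd
import pytest

from fragscan.config import AnalysisConfig
from fragscan.io_formats import BreakpointTable, GenomeSequence


@pytest.fixture
def default_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def tiny_genome() -> GenomeSequence:
    # 60 bp with one canonical nonamer at 10 and CpGs at 25 and 40
    seq = list("ATATATATAT" + "ACAAAAACC" + "TATATA" + "CG" + "ATATATATATATA" + "CG" + "ATATATATATATATATAT")
    return GenomeSequence({"chr1": "".join(seq)[:60]})


def breakpoint_table(rows):
    """rows: iterable of (chrom, pos[, cohort[, gene[, source]]])."""
    full = [tuple(r) + (None,) * (5 - len(r)) for r in rows]
    df = pd.DataFrame(full, columns=list(BreakpointTable.COLUMNS))
    return BreakpointTable(df)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
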