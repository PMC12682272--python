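import numpy as np
import pandas as pd
import pytest

from karyofuse.io_formats import PSYNT_COLUMNS, SyntenyTable


def make_table(assignments) -> SyntenyTable:
    """Build a valid synteny table from [(scaffold_a, scaffold_b), ...]
    gene assignments; ranks/positions assigned in input order per
    scaffold."""
    rank_a: dict[str, int] = {}
    rank_b: dict[str, int] = {}
    rows = []
    for i, (sa, sb) in enumerate(assignments):
        ra = rank_a.get(sa, 0)
        rb = rank_b.get(sb, 0)
        rank_a[sa] = ra + 1
        rank_b[sb] = rb + 1
        rows.append((f"o{i:05d}", sa, float(ra * 10_000), ra, sb, float(rb * 10_000), rb))
    return SyntenyTable(pd.DataFrame(rows, columns=PSYNT_COLUMNS))


@pytest.fixture
def two_block_table() -> SyntenyTable:
    """10 orthologs on (A1, B1) and 10 on (A2, B2)."""
    return make_table([("A1", "B1")] * 10 + [("A2", "B2")] * 10)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
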