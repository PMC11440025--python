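import numpy as np
import pandas as pd
import pytest

from neuromr.harmonize import HarmonizedInstruments
from neuromr.sumstats import CANONICAL_COLUMNS, SummaryStatsTable


def make_table(rows: list[dict], name: str = "trait",
               trait_type: str = "continuous") -> SummaryStatsTable:
    """Build a SummaryStatsTable from sparse row dicts with sane defaults."""
    defaults = dict(chrom="1", pos=1_000_000, effect_allele="A",
                    other_allele="G", eaf=0.3, beta=0.1, se=0.02,
                    pvalue=1e-10, n=100_000)
    full = []
    for i, r in enumerate(rows):
        d = dict(defaults, snp_id=f"rs{i + 1}", pos=1_000_000 + i * 50_000_000)
        d.update(r)
        full.append(d)
    df = pd.DataFrame(full)[CANONICAL_COLUMNS]
    return SummaryStatsTable(name, trait_type, df)


def random_harmonized(seed: int, j: int = 20) -> HarmonizedInstruments:
    """Random small harmonized fixture with heterogeneous ratios."""
    rng = np.random.default_rng(seed)
    bx = rng.normal(0.0, 0.05, j)
    bx[np.abs(bx) < 0.005] = 0.01
    sx = rng.uniform(0.002, 0.01, j)
    sy = rng.uniform(0.005, 0.02, j)
    by = rng.normal(0.3 * bx, sy)
    ids = np.array([f"rs{i}" for i in range(j)], dtype=object)
    return HarmonizedInstruments(["x"], "y", ids, bx, sx, by, sy)


@pytest.fixture
def h_random():
    return random_harmonized(seed=11, j=20)
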