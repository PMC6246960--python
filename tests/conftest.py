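import numpy as np
import pandas as pd
import pytest

from ctdna_concord.reads import READ_COLUMNS


def make_reads(rows):
    """Build a read table from (chrom, start, end, umi, allele) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "umi", "allele"])
    df.insert(0, "sample_id", "S1")
    df["strand"] = "+"
    return df.loc[:, READ_COLUMNS]


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
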