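import numpy as np
import pandas as pd
import pytest

from mspscan.io import MERGED_COLUMNS, MergedTable, SampleManifest, _sorted_table


def bedmethyl_line(chrom="chr1", start=100, strand="+", coverage=15,
                   meth="80.00", name="m"):
    end = start + 1
    return "\t".join([chrom, str(start), str(end), name,
                      str(min(coverage, 1000)), strand, str(start), str(end),
                      "0,0,0", str(coverage), str(meth)])


def make_table(rows, groups):
    """rows: (chrom, start, strand, sample, coverage, meth_pct)."""
    df = pd.DataFrame(
        [(c, s, s + 1, st, cov, meth, sam) for c, s, st, sam, cov, meth in rows],
        columns=MERGED_COLUMNS)
    return _sorted_table(df, SampleManifest(groups))


@pytest.fixture
def two_group_manifest():
    return SampleManifest({"c1": "control", "c2": "control", "c3": "control",
                           "d1": "disease", "d2": "disease"})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
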