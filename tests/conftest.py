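import numpy as np
import pandas as pd
import pytest

from pleioscan.sumstats import CANONICAL_COLUMNS, StudyMeta, SumStatsTable


def make_sumstats_df(rows):
    """Build a canonical summary-statistics frame from row dicts."""
    defaults = dict(maf=np.nan, info=np.nan, n_eff=np.nan)
    full = [dict(defaults, **r) for r in rows]
    return pd.DataFrame(full)[CANONICAL_COLUMNS]


def make_table(rows, trait="trait", **meta_kwargs):
    return SumStatsTable(df=make_sumstats_df(rows), meta=StudyMeta(trait_name=trait, **meta_kwargs))


def write_tsv(df, path):
    df.to_csv(path, sep="\t", index=False)
    return str(path)


@pytest.fixture
def three_variant_rows():
    return [
        dict(id="rs1", chrom="chr1", pos=1000, a1="A", a2="G", beta=0.10, se=0.02, p=5e-7),
        dict(id="rs2", chrom="chr1", pos=2000, a1="T", a2="C", beta=-0.05, se=0.01, p=6e-7),
        dict(id="rs3", chrom="chr2", pos=3000, a1="G", a2="C", beta=0.02, se=0.03, p=0.5),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
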