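import numpy as np
import pytest

from cgishores import CpGIsland, GenomicInterval, Methylome


def make_island(chrom="chr1", start=1000, end=2000, **kw):
    defaults = dict(score=100, gc_fraction=0.6, obs_exp_ratio=0.8, source="unmasked")
    defaults.update(kw)
    return CpGIsland(GenomicInterval(chrom, start, end), **defaults)


def make_methylome(sites, label="test"):
    """sites: iterable of (chrom, pos, n_meth, n_unmeth) or (pos, percent)
    shorthand with chrom='chr1' and 10 reads."""
    records = []
    for s in sites:
        if len(s) == 2:
            pos, pct = s
            nm = int(round(pct / 10))
            records.append(("chr1", pos, nm, 10 - nm))
        else:
            records.append(tuple(s))
    return Methylome.from_records(records, label=label)


@pytest.fixture
def island():
    return make_island()


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
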