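import numpy as np
import pandas as pd
import pytest

from editqtl.quant import SiteCounts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_counts(a, g, chrom="chr1", positions=None, strand="+"):
    """Build a SiteCounts from plain 2-D arrays (sites x samples)."""
    a = np.atleast_2d(np.asarray(a))
    g = np.atleast_2d(np.asarray(g))
    n_sites, n_samples = a.shape
    if positions is None:
        positions = 1000 + 10 * np.arange(n_sites)
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "strand": strand,
            "gene": [f"gene{i}" for i in range(n_sites)],
        },
        index=pd.Index([f"site{i}" for i in range(n_sites)], name="site"),
    )
    cols = [f"s{j}" for j in range(n_samples)]
    return SiteCounts(
        sites=sites,
        a=pd.DataFrame(a, index=sites.index, columns=cols),
        g=pd.DataFrame(g, index=sites.index, columns=cols),
    )


@pytest.fixture
def counts_factory():
    return make_counts
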