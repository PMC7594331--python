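import numpy as np
import pytest

from gdf15mr import SimulationConfig, SNPAssociation, SummaryStatsSet, simulate_pair
from gdf15mr.harmonize import HarmonizedInstrument


def snp(rsid="rs1", ea="A", oa="G", beta=0.1, se=0.01, pval=1e-10, eaf=0.3, **kw):
    return SNPAssociation(
        rsid=rsid, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, pval=pval, eaf=eaf, **kw,
    )


def hinst(rsid="rs1", bx=0.1, sx=0.01, by=0.02, sy=0.01, action="unchanged"):
    return HarmonizedInstrument(
        rsid=rsid, beta_exposure=bx, se_exposure=sx,
        beta_outcome=by, se_outcome=sy, action=action,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_pair():
    """5-SNP valid-instrument pair with theta = 0.1."""
    cfg = SimulationConfig(n_snps=5, theta=0.1, seed=7)
    return simulate_pair(cfg)


@pytest.fixture
def random_sets(rng):
    """A batch of randomly generated SummaryStatsSet for round-trip checks."""
    sets = []
    for k in range(3):
        cfg = SimulationConfig(n_snps=8, theta=0.05, seed=100 + k)
        exp, out, _ = simulate_pair(cfg)
        sets += [exp, out]
    return sets
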