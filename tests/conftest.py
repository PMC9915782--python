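import numpy as np
import pytest

from corrmr import GenotypePanel, LDMatrix, SummaryStatRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_panel(rng):
    """A 500-sample, 8-variant panel with independent binomial dosages."""
    mafs = rng.uniform(0.1, 0.4, size=8)
    dosages = rng.binomial(2, mafs, size=(500, 8)).astype(float)
    return GenotypePanel(
        variant_ids=[f"rs{i}" for i in range(8)],
        dosages=dosages,
        sample_ids=[f"S{i}" for i in range(500)],
    )


def make_record(vid="rs1", ea="A", oa="G", beta=0.1, se=0.02, eaf=0.3, **kw):
    return SummaryStatRecord(
        variant_id=vid, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, eaf=eaf, **kw,
    )


def random_pd_corr(rng, k):
    """Random correlation matrix via normalized Wishart-style factors."""
    A = rng.standard_normal((k, k + 5))
    S = A @ A.T
    d = np.sqrt(np.diag(S))
    r = S / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return LDMatrix([f"v{i}" for i in range(k)], r)
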