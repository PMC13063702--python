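import numpy as np
import pytest

from cismr.sumstats import HarmonizedSet, LDMatrix, VariantAssociation


def make_variant(
    vid="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.01, pval=1e-10,
    n=10000, chrom="1", pos=1_000_000, n_events=None,
):
    return VariantAssociation(
        variant_id=vid, effect_allele=ea, other_allele=oa, eaf=eaf,
        beta=beta, se=se, pval=pval, n=n, chrom=chrom, pos=pos,
        n_events=n_events,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def k2_independent_set():
    """The two-instrument closed-form worked case (identity correlation)."""
    return HarmonizedSet.from_arrays(
        ["rs1", "rs2"],
        bx=np.array([0.5, 0.25]), se_x=np.array([0.0, 0.0]),
        by=np.array([0.03, 0.02]), se_y=np.array([0.01, 0.02]),
    )


def random_harmonized_set(rng, k=None, correlated=False):
    """Random valid instrument set for property/oracle sweeps."""
    if k is None:
        k = int(rng.integers(2, 12))
    bx = rng.normal(0.3, 0.2, k)
    bx[np.abs(bx) < 0.02] = 0.05  # keep ratios well-defined
    se_x = rng.uniform(0.005, 0.02, k)
    by = rng.normal(0.02, 0.03, k)
    se_y = rng.uniform(0.01, 0.05, k)
    if correlated:
        a = rng.normal(size=(k, k + 3))
        cov = a @ a.T
        d = np.sqrt(np.diag(cov))
        ld = LDMatrix([f"rs{i}" for i in range(k)], cov / np.outer(d, d))
    else:
        ld = LDMatrix.identity([f"rs{i}" for i in range(k)])
    return HarmonizedSet.from_arrays(
        [f"rs{i}" for i in range(k)], bx, se_x, by, se_y, ld
    )
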