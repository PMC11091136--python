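import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from mrmediate.summary_io import HarmonizedSet, SnpAssociation  # noqa: E402


def make_assoc(snp_id="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.01, pval=None, n=10000):
    """SnpAssociation with a p-value consistent with beta/se unless given."""
    from scipy import stats

    if pval is None:
        pval = float(max(2 * stats.norm.sf(abs(beta / se)), 1e-300))
    return SnpAssociation(snp_id, ea, oa, eaf, beta, se, pval, n)


def make_harmonized(bx, bx_se, by, by_se, outcome_is_binary=False, n_exp=100_000, n_out=100_000):
    """HarmonizedSet straight from arrays (single exposure)."""
    import pandas as pd

    bx = np.asarray(bx, dtype=float)
    j = len(bx)
    ids = np.array([f"rs{i:04d}" for i in range(j)], dtype=object)
    return HarmonizedSet(
        snp_ids=ids,
        exposure_betas=bx.reshape(-1, 1),
        exposure_ses=np.asarray(bx_se, dtype=float).reshape(-1, 1),
        exposure_ns=np.full((j, 1), n_exp, dtype=float),
        outcome_betas=np.asarray(by, dtype=float),
        outcome_ses=np.asarray(by_se, dtype=float),
        outcome_ns=np.full(j, n_out, dtype=float),
        outcome_is_binary=outcome_is_binary,
        exposure_names=["exposure"],
        provenance=pd.DataFrame(columns=["snp", "collection", "action", "reason"]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_harmonized(rng):
    """A well-behaved random 12-SNP instrument set with a true slope of 0.3."""
    j = 12
    bx = rng.uniform(0.05, 0.2, j) * rng.choice([-1, 1], j)
    bx_se = rng.uniform(0.005, 0.02, j)
    by_se = rng.uniform(0.01, 0.03, j)
    by = 0.3 * bx + rng.normal(0, 1, j) * by_se
    return make_harmonized(bx, bx_se, by, by_se)
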