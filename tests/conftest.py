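import numpy as np
import pandas as pd
import pytest

from targetmr import SimulationParams, simulate_study


@pytest.fixture(scope="session")
def small_bundle():
    """A 12-gene two-tissue study with reduced regions, for fast tests."""
    params = SimulationParams(m_snps=20)
    return simulate_study(12, (0.4, 0.1, 0.1, 0.1, 0.3), params, seed=42)


def make_summary(snp_ids, pos, beta, se, chrom="1", eaf=0.3,
                 effect_allele="A", other_allele="G", n=10_000, pvalue=None):
    """Hand-build a summary-statistics frame for unit tests."""
    from scipy import stats

    beta = np.asarray(beta, dtype=float)
    se = np.broadcast_to(np.asarray(se, dtype=float), beta.shape)
    if pvalue is None:
        pvalue = 2 * stats.norm.sf(np.abs(beta / se))
    return pd.DataFrame(
        {
            "snp_id": list(snp_ids),
            "chrom": chrom,
            "pos": pos,
            "effect_allele": effect_allele,
            "other_allele": other_allele,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": pvalue,
            "n": n,
        }
    )
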