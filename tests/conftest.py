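import numpy as np
import pandas as pd
import pytest

from cpgcfdr import MixtureSpec, SumstatTable, simulate_sumstats_pair, merge_traits


def make_sumstats(
    n: int = 20,
    seed: int = 0,
    label: str = "trait",
    chrom: str = "1",
    pvals=None,
) -> SumstatTable:
    """Small well-formed summary-statistics table for unit tests."""
    rng = np.random.default_rng(seed)
    se = rng.uniform(0.01, 0.05, n)
    z = rng.standard_normal(n)
    from scipy import stats

    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n)],
            "chrom": chrom,
            "pos": np.arange(1, n + 1) * 1000,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": rng.uniform(0.05, 0.95, n),
            "beta": z * se,
            "se": se,
            "pval": pvals if pvals is not None else 2 * stats.norm.sf(np.abs(z)),
        }
    )
    return SumstatTable(trait_label=label, df=df, n_samples=10_000)


@pytest.fixture(scope="session")
def mixture_bundle():
    """One medium synthetic study shared across tests (read-only)."""
    spec = MixtureSpec(seed=7, n_snps=4000)
    t1, t2, truth, catalog = simulate_sumstats_pair(spec)
    panel = merge_traits(t1, t2)
    return {"spec": spec, "t1": t1, "t2": t2, "truth": truth, "catalog": catalog, "panel": panel}
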