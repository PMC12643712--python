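import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from medimr.sumstats import PAIR_COLUMNS, HarmonizedSet, SummaryStatsTable, TraitMeta

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(rows, trait_id="trait", role="exposure", sample_size=10_000):
    """Build a SummaryStatsTable from compact tuples.

    Row format: (variant_id, chrom, pos, ea, oa, eaf, beta, se, pvalue).
    """
    df = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chromosome", "position", "effect_allele",
            "other_allele", "eaf", "beta", "se", "pvalue",
        ],
    )
    df["n"] = sample_size
    meta = TraitMeta(trait_id, trait_id, role, "continuous", sample_size)
    return SummaryStatsTable(meta, df)


def make_hset(beta_exp, se_exp, beta_out, se_out):
    """Build a HarmonizedSet directly from effect arrays."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    k = len(beta_exp)
    pairs = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(k)],
            "beta_exp": beta_exp,
            "se_exp": np.broadcast_to(np.asarray(se_exp, dtype=float), (k,)),
            "pvalue_exp": 1e-8,
            "beta_out": np.asarray(beta_out, dtype=float),
            "se_out": np.broadcast_to(np.asarray(se_out, dtype=float), (k,)),
            "eaf_exp": 0.3,
            "eaf_out": 0.3,
            "palindromic": False,
            "action": "kept_as_is",
        },
        columns=PAIR_COLUMNS,
    )
    return HarmonizedSet(
        TraitMeta("exp"), TraitMeta("out", role="outcome"), pairs
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_hset(rng):
    """A 6-instrument harmonized set with mild heterogeneity."""
    k = 6
    bx = np.abs(rng.normal(0.2, 0.05, k))
    so = rng.uniform(0.02, 0.05, k)
    by = 0.02 + 0.3 * bx + rng.normal(0, 2 * so)
    return make_hset(bx, 0.01, by, so)
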