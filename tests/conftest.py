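import numpy as np
import pandas as pd
import pytest

from bevmr.instruments import HarmonizedSet


@pytest.fixture
def three_snp_hset():
    """Hand-checkable harmonized set: ratios 0.40/0.55/0.70, weights 100/25/100."""
    pairs = pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2", "rs3"],
            "beta_exp": [1.0, 1.0, 1.0],
            "se_exp": [0.1, 0.1, 0.1],
            "beta_out": [0.40, 0.55, 0.70],
            "se_out": [0.10, 0.20, 0.10],
            "eaf_exp": [0.3, 0.3, 0.3],
            "eaf_out": [0.3, 0.3, 0.3],
        }
    )
    return HarmonizedSet(pairs=pairs, outcome_binary=False)


@pytest.fixture
def wm_hset():
    """Weighted-median fixture: ratios 0.1/0.2/0.3 with weights 1/1/2."""
    pairs = pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2", "rs3"],
            "beta_exp": [1.0, 1.0, 1.0],
            "se_exp": [0.1, 0.1, 0.1],
            "beta_out": [0.1, 0.2, 0.3],
            "se_out": [1.0, 1.0, 1.0 / np.sqrt(2.0)],
            "eaf_exp": [0.3, 0.3, 0.3],
            "eaf_out": [0.3, 0.3, 0.3],
        }
    )
    return HarmonizedSet(pairs=pairs, outcome_binary=False)


def random_hset(rng, k=5, binary=False):
    """Random well-behaved harmonized set for identity/oracle checks."""
    pairs = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(k)],
            "beta_exp": rng.uniform(0.05, 0.2, k),
            "se_exp": rng.uniform(0.005, 0.02, k),
            "beta_out": rng.normal(0.05, 0.03, k),
            "se_out": rng.uniform(0.01, 0.05, k),
            "eaf_exp": rng.uniform(0.1, 0.4, k),
            "eaf_out": rng.uniform(0.1, 0.4, k),
        }
    )
    return HarmonizedSet(pairs=pairs, outcome_binary=binary)


@pytest.fixture
def four_subject_cox():
    """Closed-form Cox instance: score equation gives beta = 0.5 * ln 2."""
    return pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 0, 1],
            "x": [1.0, 0.0, 1.0, 0.0],
        }
    )


def make_summary_df(rng=None, m=6, p_values=None):
    """Small canonical summary-statistic frame for instrument tests."""
    rng = rng or np.random.default_rng(0)
    if p_values is None:
        p_values = rng.uniform(1e-12, 1e-6, m)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(m)],
            "chrom": "1",
            "pos": [(i + 1) * 100_000 for i in range(m)],
            "effect_allele": ["A"] * m,
            "other_allele": ["G"] * m,
            "eaf": rng.uniform(0.1, 0.4, m),
            "beta": rng.normal(0.1, 0.02, m),
            "se": rng.uniform(0.01, 0.02, m),
            "p": p_values,
            "n": 10_000.0,
        }
    )
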