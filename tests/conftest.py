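import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from summr.harmonize import PAIR_COLUMNS, STATUS_OK, HarmonizedTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SEED = 1234  # frozen unit-test seed


def make_harmonized(bx, sx, by, sy, n_exp=None, n_out=None, outcome_binary=False):
    """Build a HarmonizedTable directly from effect arrays (all status ok)."""
    bx = np.asarray(bx, float)
    J = len(bx)
    df = pd.DataFrame({
        "snp_id": [f"s{i:03d}" for i in range(J)],
        "effect_allele": ["A"] * J,
        "other_allele": ["G"] * J,
        "beta_exp": bx,
        "se_exp": np.asarray(sx, float),
        "beta_out": np.asarray(by, float),
        "se_out": np.asarray(sy, float),
        "eaf_exp": [0.3] * J,
        "eaf_out": [0.3] * J,
        "n_exp": [n_exp or 100_000] * J,
        "n_out": [n_out or 100_000] * J,
        "status": [STATUS_OK] * J,
    }, columns=list(PAIR_COLUMNS))
    return HarmonizedTable(pairs=df, exposure_name="X", outcome_name="Y",
                           outcome_binary=outcome_binary)


def random_harmonized(rng, J=8, theta=0.3):
    """A small random (heterogeneous) harmonized table for oracle checks."""
    bx = rng.normal(0.15, 0.05, J)
    sx = rng.uniform(0.005, 0.02, J)
    sy = rng.uniform(0.005, 0.02, J)
    by = theta * bx + rng.normal(0, 0.01, J)
    return make_harmonized(bx, sx, by, sy)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture
def gwas_frame():
    """A small, fully valid canonical GWAS frame."""
    return pd.DataFrame({
        "snp_id": ["rs1", "rs2", "rs3", "rs4", "rs5"],
        "effect_allele": ["A", "C", "G", "T", "A"],
        "other_allele": ["G", "T", "A", "C", "C"],
        "eaf": [0.2, 0.4, 0.6, 0.8, 0.3],
        "beta": [0.10, -0.05, 0.08, 0.02, -0.03],
        "se": [0.01, 0.012, 0.02, 0.015, 0.011],
        "pval": [1e-23, 3e-5, 6e-5, 0.18, 0.006],
        "n": [100000] * 5,
    })
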