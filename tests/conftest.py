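import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def worked_instruments() -> pd.DataFrame:
    """The 3-instrument hand-arithmetic instance used across estimator and
    heterogeneity tests: Wald ratios (0.3, 0.1, 0.2), weights (100, 400, 400)."""
    return pd.DataFrame({
        "snp_id": ["rs1", "rs2", "rs3"],
        "beta_exposure": [0.1, 0.2, 0.4],
        "se_exposure": [0.01, 0.01, 0.01],
        "beta_outcome": [0.03, 0.02, 0.08],
        "se_outcome": [0.01, 0.01, 0.02],
        "eaf": [0.3, 0.4, 0.5],
        "proxy_of": [None, None, None],
    })


def summary_text(rows, header="SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN"):
    """Build an in-memory default-dialect summary table from row tuples."""
    lines = [header] + ["\t".join(str(v) for v in r) for r in rows]
    return io.StringIO("\n".join(lines) + "\n")


@pytest.fixture
def summary_factory():
    return summary_text


def random_instruments(rng: np.random.Generator, k: int = 20,
                       slope: float = 0.1) -> pd.DataFrame:
    """Random but well-behaved harmonized instruments for property tests."""
    bx = rng.uniform(0.05, 0.3, k) * rng.choice([-1, 1], k)
    byse = rng.uniform(0.005, 0.02, k)
    by = slope * bx + rng.normal(0, byse)
    return pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(k)],
        "beta_exposure": bx,
        "se_exposure": np.full(k, 0.003),
        "beta_outcome": by,
        "se_outcome": byse,
        "eaf": rng.uniform(0.1, 0.9, k),
        "proxy_of": [None] * k,
    })
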