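import numpy as np
import pandas as pd
import pytest

from pqtlmr.sumstats import LDMatrix, SummaryStatsTable


@pytest.fixture
def toy_table() -> SummaryStatsTable:
    """Five well-formed variants on chromosome 1."""
    df = pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(1, 6)],
            "chr": "1",
            "pos": [100, 200, 300, 400, 500],
            "ea": ["A", "C", "G", "T", "A"],
            "nea": ["G", "T", "A", "C", "C"],
            "eaf": [0.1, 0.2, 0.3, 0.4, 0.5],
            "beta": [0.1, -0.2, 0.05, 0.0, 0.3],
            "se": [0.02, 0.03, 0.01, 0.05, 0.04],
            "pval": [1e-8, 1e-10, 1e-6, 1.0, 1e-12],
            "n": 3301,
        }
    )
    return SummaryStatsTable("protein", df)


def ar1_ld(p: int, rho: float, prefix: str = "rs") -> LDMatrix:
    idx = np.arange(p)
    return LDMatrix([f"{prefix}{i + 1}" for i in range(p)], rho ** np.abs(idx[:, None] - idx[None, :]))


def mvmr_plim_oracle(
    a: float = 0.2,
    b: float = 0.5,
    direct: float = 0.05,
    g2: float = 0.1,
    k: int = 17,
    gm2: float = 0.005,
    n_x: int = 35_559,
    n_m: int = 40_000,
) -> np.ndarray:
    """Probability limit of the two-exposure weighted regression under the
    mediation panel's errors-in-variables design: (T'T + N)^-1 T'T beta,
    where T'T is the noise-free instrument cross-product and N the
    accumulated measurement-error variance of each exposure column. Closed
    form, independent of the estimator implementation; captures the small
    attenuation/leakage the finite GWAS sample sizes induce.
    """
    m = k + 1
    tt = np.array([[g2, a * g2], [a * g2, a * a * g2 + k * gm2]])
    noise = np.diag([m / n_x, m / n_m])
    return np.linalg.solve(tt + noise, tt @ np.array([direct, b]))


def wald_plim_oracle(total: float = 0.15, g2: float = 0.1, n_x: int = 35_559) -> float:
    """Second-order expectation of the single-instrument ratio total*g/(g+e):
    total * (1 + cv^2) with cv^2 = se_x^2 / g^2 = 1/(n_x g2)."""
    return total * (1.0 + 1.0 / (n_x * g2))
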