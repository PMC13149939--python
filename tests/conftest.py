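"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metsel.simulate import SimulationConfig, simulate_met


# ---------------------------------------------------------------------------
# independent oracles (kept free of the package's estimation code paths)
# ---------------------------------------------------------------------------

def anova_components_oracle(df: pd.DataFrame) -> dict[str, float]:
    """Expected-mean-square variance-component estimators for a balanced
    genotype x environment x block layout, computed from raw sums of
    squares (independent of the package's REML machinery)."""
    env = sorted(df["ENV"].unique())
    gen = sorted(df["GEN"].unique())
    blk = sorted(df["BLOCK"].unique())
    e, g, b = len(env), len(gen), len(blk)
    y = df.pivot_table(index="GEN", columns=["ENV", "BLOCK"], values="VALUE")
    assert y.notna().all().all(), "oracle needs balanced data"

    grand = float(df["VALUE"].mean())
    cell = df.groupby(["ENV", "GEN"])["VALUE"].mean().unstack()       # e x g
    env_mean = df.groupby("ENV")["VALUE"].mean()
    gen_mean = df.groupby("GEN")["VALUE"].mean()
    blk_mean = df.groupby(["ENV", "BLOCK"])["VALUE"].mean()

    ss_env = g * b * float(((env_mean - grand) ** 2).sum())
    ss_gen = e * b * float(((gen_mean - grand) ** 2).sum())
    ss_blk = g * float(((blk_mean - env_mean.reindex(
        blk_mean.index.get_level_values("ENV")).to_numpy()) ** 2).sum())
    inter = cell.sub(env_mean, axis=0).sub(gen_mean, axis=1) + grand
    ss_gei = b * float((inter**2).to_numpy().sum())
    ss_tot = float(((df["VALUE"] - grand) ** 2).sum())
    ss_res = ss_tot - ss_env - ss_gen - ss_blk - ss_gei

    ms_env = ss_env / (e - 1)
    ms_blk = ss_blk / (e * (b - 1))
    ms_gen = ss_gen / (g - 1)
    ms_gei = ss_gei / ((g - 1) * (e - 1))
    ms_res = ss_res / (e * (b - 1) * (g - 1))
    return {
        "resid": ms_res,
        "gei": (ms_gei - ms_res) / b,
        "gen": (ms_gen - ms_gei) / (e * b),
        "block_env": (ms_blk - ms_res) / g,
        "env": (ms_env - ms_blk - ms_gei + ms_res) / (g * b),
    }


def waasb_bruteforce(scores: np.ndarray, ep: np.ndarray) -> np.ndarray:
    """Direct weighted-average-of-absolute-scores evaluation."""
    out = np.zeros(scores.shape[0])
    for i in range(scores.shape[0]):
        num = sum(abs(scores[i, k]) * ep[k] for k in range(len(ep)))
        out[i] = num / sum(ep)
    return out


def varimax_objective(loadings: np.ndarray) -> float:
    """Summed column variance of squared loadings (raw varimax objective)."""
    L2 = np.asarray(loadings) ** 2
    p = L2.shape[0]
    return float(sum(np.mean(L2[:, j] ** 2) - np.mean(L2[:, j]) ** 2
                     for j in range(L2.shape[1])))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_gen=18, n_env=6, n_blocks=3, grand_mean=10.0,
        sigma2_env=1.0, sigma2_block_env=0.5, sigma2_gen=1.0,
        sigma2_gei=0.5, sigma2_resid=1.0, seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_met(small_config)


@pytest.fixture(scope="session")
def fitted_model(small_dataset):
    from metsel.lmm import ModelSpec, fit_met

    return fit_met(small_dataset, ModelSpec(trait="VALUE"))
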