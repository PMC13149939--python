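"""Synthetic multi-environment trial (MET) data with known ground truth.

Generates plot-level observations from a randomized complete block design
(RCBD) repeated across environments,

    y_ijk = mu + E_j + B_k(j) + G_i + GE_ij + eps_ijk,

with independent zero-mean Gaussian environment, block-within-environment,
genotype and residual effects, and a genotype-by-environment interaction
(GEI) built as an exact low-rank bilinear (AMMI-style) term so that the
interaction principal-component spectrum is a controlled ground truth.
Several genetically correlated traits can be simulated at once, which is
what the multi-trait stability index downstream needs.

The realized effect vectors travel with the dataset (``METDataset.truth``)
so parameter-recovery tests can compare estimates against what was drawn.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InvalidConfigError",
    "SimulationConfig",
    "SimulationTruth",
    "METDataset",
    "make_gei_lowrank",
    "simulate_met",
    "simulate_multitrait_met",
    "rice_trial_config",
    "RICE_TRAITS",
]


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# Default eight-trait rice panel: name, desirability direction, grand mean,
# and variance components (sigma2_env, sigma2_block_env, sigma2_gen,
# sigma2_gei, sigma2_resid) on each trait's own scale.  Grain yield is in
# kg/ha with the trial-wide mean 4360 kg/ha; the other scales are typical
# for irrigated rice (height in cm, weights in g, fertility in %).
RICE_TRAITS: list[dict] = [
    dict(name="PH", direction="lower", mean=130.0, s2=(60.0, 6.0, 45.0, 12.0, 25.0)),
    dict(name="TN", direction="higher", mean=14.0, s2=(3.0, 0.4, 2.0, 0.8, 2.5)),
    dict(name="PL", direction="higher", mean=27.0, s2=(2.5, 0.3, 1.8, 0.6, 1.5)),
    dict(name="FG", direction="higher", mean=110.0, s2=(150.0, 15.0, 120.0, 60.0, 90.0)),
    dict(name="UNFG", direction="lower", mean=25.0, s2=(20.0, 3.0, 18.0, 16.0, 12.0)),
    dict(name="FP", direction="higher", mean=82.0, s2=(12.0, 2.0, 10.0, 11.0, 8.0)),
    dict(name="HGW", direction="higher", mean=2.6, s2=(0.015, 0.002, 0.012, 0.005, 0.008)),
    dict(name="GY", direction="higher", mean=4360.0,
         s2=(3.6e5, 2.0e4, 1.2e5, 8.0e4, 1.9e5)),
]

# GEI eigenvalue profile used by default: shares of the interaction sum of
# squares per bilinear axis, emulating a spectrum dominated by the first
# axis with a slowly decaying tail (five axes for an 18 x 6 trial).
DEFAULT_GEI_SHARES: tuple[float, ...] = (0.68, 0.15, 0.10, 0.05, 0.02)


def _as_vector(x, n: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.size == 1:
        arr = np.full(n, arr.item())
    if arr.size != n:
        raise InvalidConfigError(f"{name} must be scalar or length {n}, got {arr.size}")
    return arr


@dataclass
class SimulationConfig:
    """Parameters of the synthetic RCBD-across-environments trial.

    Variance fields and ``grand_mean`` accept either a scalar (shared by all
    traits) or a vector of length ``n_traits``.  The GEI term can be
    specified either through ``gei_axis_scales`` (the singular values of the
    realized genotype x environment matrix) or, more conveniently, through
    ``sigma2_gei`` plus ``gei_eigenvalue_shares``: scales are then derived
    so that ``sum(scale_k^2) = sigma2_gei * (n_gen-1) * (n_env-1)``, which
    makes the expected balanced-ANOVA (and REML) interaction component equal
    the nominal ``sigma2_gei``.
    """

    n_gen: int = 18
    n_env: int = 6
    n_blocks: int = 3
    grand_mean: float | Sequence[float] = 4360.0
    sigma2_env: float | Sequence[float] = 3.6e5
    sigma2_block_env: float | Sequence[float] = 2.0e4
    sigma2_gen: float | Sequence[float] = 1.2e5
    sigma2_resid: float | Sequence[float] = 1.9e5
    sigma2_gei: float | Sequence[float] = 8.0e4
    gei_rank: int | None = None
    gei_eigenvalue_shares: Sequence[float] = DEFAULT_GEI_SHARES
    gei_axis_scales: Sequence[float] | None = None
    gei_structure: str = "lowrank"  # or "iid": per-cell Gaussian interaction
    n_traits: int = 1
    trait_names: Sequence[str] | None = None
    trait_directions: Sequence[str] | None = None
    gen_corr: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for fname in ("n_gen", "n_env", "n_blocks", "n_traits"):
            if int(getattr(self, fname)) < 1:
                raise InvalidConfigError(f"{fname} must be a positive integer")
        self.n_gen, self.n_env = int(self.n_gen), int(self.n_env)
        self.n_blocks, self.n_traits = int(self.n_blocks), int(self.n_traits)

        t = self.n_traits
        self.grand_mean = _as_vector(self.grand_mean, t, "grand_mean")
        for fname in ("sigma2_env", "sigma2_block_env", "sigma2_gen",
                      "sigma2_resid", "sigma2_gei"):
            v = _as_vector(getattr(self, fname), t, fname)
            if np.any(v < 0):
                raise InvalidConfigError(f"{fname} must be non-negative")
            setattr(self, fname, v)

        if self.gei_structure not in ("lowrank", "iid"):
            raise InvalidConfigError("gei_structure must be 'lowrank' or 'iid'")
        max_rank = min(self.n_gen, self.n_env) - 1
        if self.gei_axis_scales is not None:
            scales = np.asarray(self.gei_axis_scales, dtype=float)
            if scales.ndim != 1:
                raise InvalidConfigError("gei_axis_scales must be a 1-d sequence")
            if np.any(scales <= 0):
                raise InvalidConfigError("gei_axis_scales must be positive")
            if np.any(np.diff(scales) > 1e-12):
                raise InvalidConfigError("gei_axis_scales must be non-increasing")
            self.gei_rank = scales.size
        elif self.gei_rank is None:
            # default rank: as many axes as the share profile supports
            self.gei_rank = min(max_rank, len(self.gei_eigenvalue_shares))
        self.gei_rank = int(self.gei_rank)
        if not 0 <= self.gei_rank <= max_rank:
            raise InvalidConfigError(
                f"gei_rank must be in [0, {max_rank}] for a "
                f"{self.n_gen} x {self.n_env} trial, got {self.gei_rank}"
            )

        if self.trait_names is None:
            self.trait_names = (
                ["VALUE"] if t == 1 else [f"T{i + 1}" for i in range(t)]
            )
        self.trait_names = list(self.trait_names)
        if len(self.trait_names) != t:
            raise InvalidConfigError("trait_names length must equal n_traits")
        if self.trait_directions is None:
            self.trait_directions = ["higher"] * t
        self.trait_directions = list(self.trait_directions)
        if len(self.trait_directions) != t:
            raise InvalidConfigError("trait_directions length must equal n_traits")
        for d in self.trait_directions:
            if d not in ("higher", "lower"):
                raise InvalidConfigError(f"unknown trait direction {d!r}")

        if self.gen_corr is None:
            self.gen_corr = np.eye(t)
        self.gen_corr = np.asarray(self.gen_corr, dtype=float)
        if self.gen_corr.shape != (t, t):
            raise InvalidConfigError(f"gen_corr must be {t} x {t}")
        if not np.allclose(self.gen_corr, self.gen_corr.T, atol=1e-10):
            raise InvalidConfigError("gen_corr must be symmetric")
        if not np.allclose(np.diag(self.gen_corr), 1.0, atol=1e-10):
            raise InvalidConfigError("gen_corr must have unit diagonal")
        if np.linalg.eigvalsh(self.gen_corr).min() < -1e-8:
            raise InvalidConfigError("gen_corr must be positive semi-definite")

    def axis_scales_for_trait(self, trait_idx: int) -> np.ndarray:
        """Singular values imposed on the GEI matrix of one trait."""
        if self.gei_rank == 0:
            return np.zeros(0)
        if self.gei_axis_scales is not None:
            return np.asarray(self.gei_axis_scales, dtype=float)
        shares = np.asarray(self.gei_eigenvalue_shares, dtype=float)[: self.gei_rank]
        shares = shares / shares.sum()
        total_ss = (
            float(self.sigma2_gei[trait_idx])
            * (self.n_gen - 1)
            * (self.n_env - 1)
        )
        return np.sqrt(shares * total_ss)


@dataclass
class SimulationTruth:
    """Realized effects used to generate a dataset (one entry per trait)."""

    grand_mean: np.ndarray                      # (n_traits,)
    env_effects: np.ndarray                     # (n_env, n_traits)
    block_effects: np.ndarray                   # (n_env, n_blocks, n_traits)
    gen_effects: np.ndarray                     # (n_gen, n_traits)
    gei: list[np.ndarray]                       # per trait (n_gen, n_env)
    resid: np.ndarray                           # (n_env, n_gen, n_blocks, n_traits)


@dataclass
class METDataset:
    """Long-format plot observations with optional generating truth."""

    data: pd.DataFrame  # columns ENV, GEN, BLOCK, TRAIT, VALUE
    truth: SimulationTruth | None = None

    def __post_init__(self) -> None:
        required = ["ENV", "GEN", "BLOCK", "TRAIT", "VALUE"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"METDataset missing columns: {missing}")
        dup = self.data.duplicated(subset=["ENV", "GEN", "BLOCK", "TRAIT"])
        if dup.any():
            lines = (self.data.index[dup] + 2).tolist()  # +2: header + 0-base
            raise ValueError(f"duplicate plot rows at lines {lines}")
        if not np.all(np.isfinite(self.data["VALUE"].to_numpy(dtype=float))):
            raise ValueError("non-finite VALUE entries")

    @property
    def traits(self) -> list[str]:
        return list(pd.unique(self.data["TRAIT"]))

    def trait_frame(self, trait: str) -> pd.DataFrame:
        sub = self.data[self.data["TRAIT"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not present")
        return sub.reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _centered_orthonormal(rng: np.random.Generator, n: int, rank: int) -> np.ndarray:
    """Random n x rank orthonormal columns, each orthogonal to the 1-vector."""
    raw = rng.standard_normal((n, rank))
    raw -= raw.mean(axis=0, keepdims=True)
    q, r = np.linalg.qr(raw)
    # fix QR sign indeterminacy for reproducibility across BLAS builds
    q *= np.sign(np.diag(r))
    return q[:, :rank]


def make_gei_lowrank(
    n_gen: int,
    n_env: int,
    rank: int,
    axis_scales: Sequence[float] | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Low-rank double-centered GEI matrix sum_k scale_k * u_k v_k'.

    ``u_k`` / ``v_k`` are random orthonormal vectors orthogonal to the
    1-vector, so every row and column of the result sums to zero and the
    singular values equal ``axis_scales`` exactly.
    """
    if not 0 <= rank <= min(n_gen, n_env) - 1:
        raise InvalidConfigError(
            f"rank must be in [0, {min(n_gen, n_env) - 1}], got {rank}"
        )
    if rank == 0:
        return np.zeros((n_gen, n_env))
    scales = np.asarray(
        axis_scales if axis_scales is not None else np.ones(rank), dtype=float
    )
    if scales.size != rank:
        raise InvalidConfigError("axis_scales must have length rank")
    if np.any(scales <= 0):
        raise InvalidConfigError("axis_scales must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = _centered_orthonormal(rng, n_gen, rank)
    v = _centered_orthonormal(rng, n_env, rank)
    return (u * scales) @ v.T


def _draw_truth(config: SimulationConfig) -> SimulationTruth:
    g, e, b, t = config.n_gen, config.n_env, config.n_blocks, config.n_traits
    root = np.random.SeedSequence(config.seed)
    # one sub-stream per effect family so adding traits never perturbs the
    # environment (or any earlier family's) draws
    rng_env, rng_blk, rng_gen, rng_gei, rng_res = (
        np.random.default_rng(s) for s in root.spawn(5)
    )

    # draw trait-by-trait within each family stream: appending a trait can
    # then never change the draws of the traits before it
    env = np.column_stack(
        [rng_env.standard_normal(e) for _ in range(t)]
    ) * np.sqrt(config.sigma2_env)
    blk = np.stack(
        [rng_blk.standard_normal((e, b)) for _ in range(t)], axis=-1
    ) * np.sqrt(config.sigma2_block_env)

    # genotype effects: correlated across traits through gen_corr
    w, vecs = np.linalg.eigh(config.gen_corr)
    chol_like = vecs @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng_gen.standard_normal((g, t))
    gen = (z @ chol_like.T) * np.sqrt(config.sigma2_gen)

    gei = []
    for k in range(t):
        if config.gei_structure == "iid":
            # model-consistent unstructured interaction: i.i.d. cells, so
            # margins fluctuate the way the mixed model expects
            gei.append(
                rng_gei.standard_normal((g, e)) * np.sqrt(config.sigma2_gei[k])
            )
            continue
        scales = config.axis_scales_for_trait(k)
        scales = scales[scales > 0]  # sigma2_gei = 0 => no interaction
        gei.append(
            make_gei_lowrank(g, e, scales.size, scales if scales.size else None,
                             rng_gei)
        )
    res = np.stack(
        [rng_res.standard_normal((e, g, b)) for _ in range(t)], axis=-1
    ) * np.sqrt(config.sigma2_resid)
    return SimulationTruth(
        grand_mean=np.asarray(config.grand_mean, float),
        env_effects=env,
        block_effects=blk,
        gen_effects=gen,
        gei=gei,
        resid=res,
    )


def _assemble(config: SimulationConfig, truth: SimulationTruth) -> pd.DataFrame:
    g, e, b = config.n_gen, config.n_env, config.n_blocks
    env_ids = [f"E{j + 1}" for j in range(e)]
    gen_ids = [f"G{i + 1}" for i in range(g)]
    blk_ids = [f"B{k + 1}" for k in range(b)]
    frames = []
    ej, ig, kb = np.meshgrid(np.arange(e), np.arange(g), np.arange(b), indexing="ij")
    ej, ig, kb = ej.ravel(), ig.ravel(), kb.ravel()
    for ti, trait in enumerate(config.trait_names):
        y = (
            truth.grand_mean[ti]
            + truth.env_effects[ej, ti]
            + truth.block_effects[ej, kb, ti]
            + truth.gen_effects[ig, ti]
            + truth.gei[ti][ig, ej]
            + truth.resid[ej, ig, kb, ti]
        )
        frames.append(
            pd.DataFrame(
                {
                    "ENV": np.array(env_ids)[ej],
                    "GEN": np.array(gen_ids)[ig],
                    "BLOCK": np.array(blk_ids)[kb],
                    "TRAIT": trait,
                    "VALUE": y,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_met(config: SimulationConfig) -> METDataset:
    """Simulate a single-trait (or the first-trait marginal) MET dataset."""
    truth = _draw_truth(config)
    return METDataset(data=_assemble(config, truth), truth=truth)


def simulate_multitrait_met(config: SimulationConfig) -> METDataset:
    """Simulate a multi-trait MET dataset with correlated genotype effects."""
    if config.n_traits < 2:
        raise InvalidConfigError("simulate_multitrait_met requires n_traits >= 2")
    return simulate_met(config)


def rice_trial_config(seed: int = 0, traits: Sequence[Mapping] | None = None,
                      gen_corr: np.ndarray | None = None) -> SimulationConfig:
    """The default eight-trait, 18-genotype x 6-environment x 3-block trial.

    Mirrors the layout of a two-year, three-location irrigated rice panel.
    Genotype effects of the eight traits are moderately correlated: filled
    grains, fertility and yield move together, unfilled grains against
    fertility.
    """
    traits = list(traits if traits is not None else RICE_TRAITS)
    t = len(traits)
    if gen_corr is None:
        corr = np.eye(t)
        idx = {spec["name"]: i for i, spec in enumerate(traits)}

        def set_r(a: str, b: str, r: float) -> None:
            if a in idx and b in idx:
                corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r

        set_r("FG", "FP", 0.5)
        set_r("FG", "GY", 0.5)
        set_r("FP", "GY", 0.4)
        set_r("UNFG", "FP", -0.5)
        set_r("UNFG", "FG", -0.3)
        set_r("HGW", "GY", 0.3)
        set_r("TN", "PL", 0.3)
        set_r("PH", "PL", 0.3)
        # guarantee positive definiteness regardless of user-edited entries
        w = np.linalg.eigvalsh(corr).min()
        if w < 1e-6:
            corr = (corr + (1e-6 - w) * np.eye(t)) / (1 + 1e-6 - w)
        gen_corr = corr
    s2 = np.array([spec["s2"] for spec in traits], dtype=float)
    return SimulationConfig(
        n_gen=18,
        n_env=6,
        n_blocks=3,
        grand_mean=[spec["mean"] for spec in traits],
        sigma2_env=s2[:, 0],
        sigma2_block_env=s2[:, 1],
        sigma2_gen=s2[:, 2],
        sigma2_gei=s2[:, 3],
        sigma2_resid=s2[:, 4],
        n_traits=t,
        trait_names=[spec["name"] for spec in traits],
        trait_directions=[spec["direction"] for spec in traits],
        gen_corr=gen_corr,
        seed=seed,
    )
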