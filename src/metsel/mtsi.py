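"""Multi-trait stability index (MTSI) via factor analysis of WAASBY values.

The genotype x trait matrix of WAASBY indices (each column direction-
adjusted so 100 is best) is standardized and summarized by an exploratory
factor analysis: principal-axis loadings from the trait correlation
matrix, Kaiser retention (eigenvalue >= 1), varimax rotation with Kaiser
normalization, and regression factor scores Z R^-1 L.  The ideotype is a
virtual genotype scoring 100 on every trait, pushed through the same
standardization and score equation.  MTSI is the Euclidean distance of a
genotype's factor scores to the ideotype's; the lowest-distance genotypes
are selected at the chosen intensity, and per-trait selection differentials
and gains (scaled by heritability) are reported for both the mean-
performance and the WAASBY scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .waasb import waasby

__all__ = [
    "FactorModel",
    "MTSIResult",
    "build_index_matrix",
    "factor_analysis",
    "varimax",
    "varimax_criterion",
    "ideotype_scores",
    "mtsi_scores",
    "selection_gains",
]

logger = logging.getLogger(__name__)


def build_index_matrix(
    per_trait_stability: Mapping[str, pd.DataFrame],
    directions: Mapping[str, str],
    theta_y: float = 50.0,
    theta_s: float = 50.0,
) -> pd.DataFrame:
    """Genotype x trait WAASBY matrix, each column direction-adjusted.

    ``per_trait_stability`` maps trait name to that trait's stability table
    (columns MEAN and WAASB); WAASBY is recomputed per trait with its
    desirability direction so that 100 is always the best end (lower-better
    traits get their performance rescaling reversed).
    """
    traits = list(per_trait_stability)
    if not traits:
        raise ValueError("no traits supplied")
    base = list(per_trait_stability[traits[0]].index)
    cols = {}
    for t in traits:
        tab = per_trait_stability[t]
        if list(tab.index) != base:
            extra = sorted(set(tab.index) ^ set(base))
            raise ValueError(f"genotype sets differ across traits (trait {t!r}: "
                             f"offenders {extra})")
        if t not in directions:
            raise ValueError(f"no desirability direction for trait {t!r}")
        cols[t] = waasby(tab["MEAN"], tab["WAASB"], theta_y=theta_y,
                         theta_s=theta_s, direction=directions[t])
    return pd.DataFrame(cols).rename_axis("GEN")


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax objective: summed variance of squared loadings per factor."""
    L2 = np.asarray(loadings, dtype=float) ** 2
    p = L2.shape[0]
    return float(np.sum(L2**2) / p - np.sum((L2.sum(axis=0) / p) ** 2))


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Varimax rotation; returns (rotated loadings, rotation matrix, converged)."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k), True
    h = np.sqrt(np.sum(L**2, axis=1))
    h[h == 0] = 1.0
    Ln = L / h[:, None] if kaiser_normalize else L
    R = np.eye(k)
    d = 0.0
    converged = False
    for _ in range(max_iter):
        B = Ln @ R
        G = Ln.T @ (B**3 - B @ np.diag(np.sum(B**2, axis=0)) / p)
        u, s, vt = np.linalg.svd(G)
        R = u @ vt
        d_new = float(np.sum(s))
        if d_new <= d * (1.0 + tol):
            converged = True
            break
        d = d_new
    rotated = (Ln @ R) * (h[:, None] if kaiser_normalize else 1.0)
    return rotated, R, converged


@dataclass
class FactorModel:
    """Exploratory factor model of the standardized WAASBY matrix."""

    eigenvalues: np.ndarray               # of the trait correlation matrix
    n_retained: int
    loadings: pd.DataFrame                # trait x factor, varimax-rotated
    communalities: pd.Series
    uniquenesses: pd.Series
    scores: pd.DataFrame                  # genotype x factor (regression method)
    rotation_converged: bool
    col_means: pd.Series                  # standardization used for scores
    col_sds: pd.Series                    # population (ddof=0) SDs
    corr: pd.DataFrame
    score_weights: np.ndarray             # R^-1 L, trait x factor


def factor_analysis(m: pd.DataFrame) -> FactorModel:
    """Fit the factor model used by the MTSI.

    Eigen-decomposition of the trait correlation matrix; factors with
    eigenvalue >= 1 retained (at least one); initial loadings are
    eigenvector * sqrt(eigenvalue); varimax rotation with Kaiser
    normalization; regression factor scores Z R^-1 L.
    """
    traits = list(m.columns)
    x = m.to_numpy(dtype=float)
    n, p = x.shape
    if n <= p:
        warnings.warn(
            f"only {n} genotypes for {p} traits: factor model is weakly "
            "determined", stacklevel=2,
        )
    means = x.mean(axis=0)
    sds = x.std(axis=0)  # population SD; a constant column is invalid input
    if np.any(sds == 0):
        const = [t for t, s in zip(traits, sds) if s == 0]
        raise ValueError(f"constant columns in the index matrix: {const}")
    z = (x - means) / sds
    corr = np.corrcoef(z, rowvar=False)

    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    n_ret = max(1, int(np.sum(w >= 1.0)))
    init = v[:, :n_ret] * np.sqrt(np.clip(w[:n_ret], 0.0, None))
    rotated, _, conv = varimax(init)
    # sign convention: each factor's largest-|loading| trait loads positively
    for k in range(n_ret):
        i = np.argmax(np.abs(rotated[:, k]))
        if rotated[i, k] < 0:
            rotated[:, k] = -rotated[:, k]

    comm = np.sum(rotated**2, axis=1)
    try:
        r_inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation matrix: ridge-regularized inverse",
                      stacklevel=2)
        r_inv = np.linalg.inv(corr + 1e-8 * np.eye(p))
    if not np.all(np.isfinite(r_inv)) or np.linalg.cond(corr) > 1e12:
        warnings.warn("ill-conditioned correlation matrix: ridge-regularized "
                      "inverse", stacklevel=2)
        r_inv = np.linalg.inv(corr + 1e-8 * np.eye(p))
    weights = r_inv @ rotated
    scores = z @ weights

    fac_cols = [f"FA{k + 1}" for k in range(n_ret)]
    return FactorModel(
        eigenvalues=w,
        n_retained=n_ret,
        loadings=pd.DataFrame(rotated, index=traits, columns=fac_cols),
        communalities=pd.Series(comm, index=traits, name="communality"),
        uniquenesses=pd.Series(1.0 - comm, index=traits, name="uniqueness"),
        scores=pd.DataFrame(scores, index=m.index, columns=fac_cols),
        rotation_converged=conv,
        col_means=pd.Series(means, index=traits),
        col_sds=pd.Series(sds, index=traits),
        corr=pd.DataFrame(corr, index=traits, columns=traits),
        score_weights=weights,
    )


def ideotype_scores(fa: FactorModel) -> pd.Series:
    """Factor scores of the virtual genotype with WAASBY = 100 everywhere."""
    z = (100.0 - fa.col_means.to_numpy()) / fa.col_sds.to_numpy()
    return pd.Series(z @ fa.score_weights, index=fa.scores.columns,
                     name="ideotype")


@dataclass
class MTSIResult:
    table: pd.DataFrame          # GEN, MTSI, RANK, SELECTED
    cutoff: float                # MTSI of the last selected genotype
    selected: list[str]
    intensity: float
    contributions: pd.DataFrame  # genotype x factor, rows sum to 1


def mtsi_scores(
    fa: FactorModel,
    ideotype: pd.Series | None = None,
    intensity: float = 15.0,
) -> MTSIResult:
    """MTSI distances, ranking and the selected set.

    MTSI_i = sqrt(sum_j (F_ij - F_j)^2); the round-half-up of
    intensity/100 * n_gen lowest-distance genotypes (at least one) are
    selected.  A genotype's factor contributions are the squared
    deviations' shares of its squared distance.
    """
    if not 0 < intensity <= 100:
        raise ValueError("intensity must be in (0, 100]")
    if ideotype is None:
        ideotype = ideotype_scores(fa)
    dev = fa.scores.to_numpy() - ideotype.to_numpy()[None, :]
    d2 = np.sum(dev**2, axis=1)
    mtsi = np.sqrt(d2)
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = np.where(d2[:, None] > 0, dev**2 / np.where(d2 == 0, 1, d2)[:, None],
                           1.0 / dev.shape[1])

    n_gen = len(mtsi)
    order = np.argsort(mtsi, kind="stable")
    if len(np.unique(mtsi)) < n_gen:
        logger.info("tied MTSI values broken by genotype label order")
    ranks = np.empty(n_gen, dtype=int)
    ranks[order] = np.arange(1, n_gen + 1)
    n_sel = max(1, int(np.floor(intensity / 100.0 * n_gen + 0.5)))
    selected_idx = order[:n_sel]
    selected = [fa.scores.index[i] for i in selected_idx]
    cutoff = float(mtsi[order[n_sel - 1]])

    table = pd.DataFrame(
        {
            "MTSI": mtsi,
            "RANK": ranks,
            "SELECTED": np.isin(np.arange(n_gen), selected_idx),
        },
        index=fa.scores.index,
    ).rename_axis("GEN")
    contributions = pd.DataFrame(
        contrib, index=fa.scores.index, columns=fa.scores.columns
    ).rename_axis("GEN")
    return MTSIResult(table=table, cutoff=cutoff, selected=selected,
                      intensity=float(intensity), contributions=contributions)


def selection_gains(
    mean_perf: pd.DataFrame,
    waasby_matrix: pd.DataFrame,
    selected: Sequence[str],
    h2: Mapping[str, float],
) -> pd.DataFrame:
    """Selection differentials and gains per trait on two scales.

    For each trait and each target (BLUP mean performance, WAASBY):
    X0 = population mean, Xs = mean over the selected set,
    SD = Xs - X0, %SD = 100*SD/X0, SG = SD*h2, %SG = %SD*h2.
    """
    if len(selected) == 0:
        raise ValueError("selected set is empty")
    rows = []
    for target, mat in (("mean_performance", mean_perf), ("waasby", waasby_matrix)):
        for t in mat.columns:
            h = float(h2[t])
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"heritability for {t!r} outside [0, 1]")
            x0 = float(mat[t].mean())
            xs = float(mat.loc[list(selected), t].mean())
            sd = xs - x0
            sd_pct = 100.0 * sd / x0 if x0 != 0 else np.nan
            rows.append(
                {
                    "TRAIT": t,
                    "TARGET": target,
                    "X0": x0,
                    "XS": xs,
                    "SD": sd,
                    "SD_PCT": sd_pct,
                    "SG": sd * h,
                    "SG_PCT": sd_pct * h if x0 != 0 else np.nan,
                    "H2": h,
                }
            )
    return pd.DataFrame(rows)
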