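"""WAASB/WAASBY stability indices from the SVD of the BLUP GEI matrix.

The double-centered genotype x environment matrix of interaction BLUPs is
decomposed into interaction principal component axes (IPCA).  WAASB is the
weighted average of a genotype's (or environment's) absolute IPCA scores,
weighted by the proportion of interaction variance each axis explains;
lower WAASB means more stable.  WAASBY blends rescaled mean performance
(rG) with rescaled WAASB (rW) using user weights theta_Y / theta_S, giving
a 0-100 superiority index where the ideotype scores 100.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import FittedMETModel, genotypic_values

__all__ = [
    "IPCADecomposition",
    "gei_svd",
    "waasb_scores",
    "rescale_0_100",
    "waasby",
    "quadrant_classify",
    "stability_table",
    "rank_across_weights",
]

logger = logging.getLogger(__name__)


@dataclass
class IPCADecomposition:
    """SVD of a GEI matrix with symmetric sqrt(lambda) score scaling."""

    singular_values: np.ndarray          # descending
    gen_scores: pd.DataFrame             # genotype x axis, u_k * sqrt(lambda_k)
    env_scores: pd.DataFrame             # environment x axis, v_k * sqrt(lambda_k)
    explained: np.ndarray                # EP_k = lambda_k^2 / sum lambda^2
    n_axes: int

    def reconstruct(self) -> pd.DataFrame:
        """Sum over axes of genotype-score x environment-score."""
        return pd.DataFrame(
            self.gen_scores.to_numpy() @ self.env_scores.to_numpy().T,
            index=self.gen_scores.index,
            columns=self.env_scores.index,
        )


def gei_svd(ge: pd.DataFrame | np.ndarray) -> IPCADecomposition:
    """Decompose a (double-centered) GEI matrix into IPCA axes.

    Scores use the symmetric scaling (singular vector times sqrt of the
    singular value) for both margins; each axis's sign is fixed so the
    largest-magnitude genotype score is positive.  An all-zero matrix is a
    valid degenerate input and yields zero axes.
    """
    if isinstance(ge, pd.DataFrame):
        gen_idx, env_idx = list(ge.index), list(ge.columns)
        m = ge.to_numpy(dtype=float)
    else:
        m = np.asarray(ge, dtype=float)
        gen_idx = [f"G{i + 1}" for i in range(m.shape[0])]
        env_idx = [f"E{j + 1}" for j in range(m.shape[1])]
    if m.ndim != 2 or min(m.shape) < 2:
        raise ValueError("GEI matrix must be at least 2 x 2")
    if not np.all(np.isfinite(m)):
        raise ValueError("GEI matrix must be finite")

    max_axes = min(m.shape[0] - 1, m.shape[1] - 1)
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    tol = max(m.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep = min(max_axes, int(np.sum(s > tol)))
    if keep == 0:
        warnings.warn("all-zero GEI matrix: no interaction axes", stacklevel=2)
        return IPCADecomposition(
            singular_values=np.zeros(0),
            gen_scores=pd.DataFrame(index=gen_idx),
            env_scores=pd.DataFrame(index=env_idx),
            explained=np.zeros(0),
            n_axes=0,
        )
    u, s, v = u[:, :keep], s[:keep], vt[:keep].T
    # deterministic sign: largest |genotype score| positive per axis
    for k in range(keep):
        i = np.argmax(np.abs(u[:, k]))
        if u[i, k] < 0:
            u[:, k] = -u[:, k]
            v[:, k] = -v[:, k]
    root = np.sqrt(s)
    cols = [f"IPCA{k + 1}" for k in range(keep)]
    return IPCADecomposition(
        singular_values=s,
        gen_scores=pd.DataFrame(u * root, index=gen_idx, columns=cols),
        env_scores=pd.DataFrame(v * root, index=env_idx, columns=cols),
        explained=s**2 / np.sum(s**2),
        n_axes=keep,
    )


def waasb_scores(
    decomp: IPCADecomposition,
    n_axes: int | str = "all",
    margin: str = "gen",
) -> pd.Series:
    """Weighted average of absolute IPCA scores.

    WAASB_i = sum_k |IPCA_ik| * EP_k / sum_k EP_k over the first ``n_axes``
    axes (default: all available).  ``margin`` selects genotype or
    environment scores; the computation is identical.
    """
    scores = decomp.gen_scores if margin == "gen" else decomp.env_scores
    if decomp.n_axes == 0:
        warnings.warn("no interaction axes: WAASB is zero for every entry",
                      stacklevel=2)
        return pd.Series(0.0, index=scores.index, name="WAASB")
    k = decomp.n_axes if n_axes == "all" else int(n_axes)
    if not 1 <= k <= decomp.n_axes:
        raise ValueError(f"n_axes must be in [1, {decomp.n_axes}] or 'all'")
    ep = decomp.explained[:k]
    w = np.abs(scores.to_numpy()[:, :k]) @ ep / ep.sum()
    return pd.Series(w, index=scores.index, name="WAASB")


def rescale_0_100(values, direction: str = "higher") -> pd.Series:
    """Linear 0-100 rescale; ``direction`` says which end deserves 100."""
    s = pd.Series(values, dtype=float)
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    lo, hi = float(s.min()), float(s.max())
    if hi == lo:
        warnings.warn("constant vector: rescaled values set to 50", stacklevel=2)
        return pd.Series(50.0, index=s.index)
    out = 100.0 * (s - lo) / (hi - lo)
    if direction == "lower":
        out = 100.0 - out
    return out


def waasby(
    mean_perf,
    waasb,
    theta_y: float = 50.0,
    theta_s: float = 50.0,
    direction: str = "higher",
) -> pd.Series:
    """Superiority index blending rescaled performance and stability.

    WAASBY_i = (rG_i * theta_Y + rW_i * theta_S) / (theta_Y + theta_S),
    where rG rescales mean performance in the trait's desirable direction
    and rW always rescales WAASB lower-better.
    """
    if theta_y < 0 or theta_s < 0 or theta_y + theta_s <= 0:
        raise ValueError("weights must be non-negative with a positive sum")
    rg = rescale_0_100(mean_perf, direction)
    rw = rescale_0_100(waasb, "lower")
    out = (rg * theta_y + rw.to_numpy() * theta_s) / (theta_y + theta_s)
    out.name = "WAASBY"
    return out


def quadrant_classify(mean_perf, waasb) -> pd.Series:
    """Quadrant labels of the performance x WAASB biplot.

    Dividers sit at the unweighted means.  I: below-mean performance and
    above-mean WAASB (unstable, low); II: above/above (productive but
    unstable); III: below/below (stable but low); IV: above-mean
    performance and below-mean WAASB (the desirable corner).  Values equal
    to a divider count as the desirable side.
    """
    perf = pd.Series(mean_perf, dtype=float)
    w = pd.Series(waasb, dtype=float)
    high_perf = perf >= perf.mean()
    stable = w.to_numpy() <= w.mean()
    labels = np.where(
        high_perf, np.where(stable, "IV", "II"), np.where(stable, "III", "I")
    )
    return pd.Series(labels, index=perf.index, name="QUADRANT")


def stability_table(
    model: FittedMETModel,
    n_axes: int | str = "all",
    theta_y: float = 50.0,
    theta_s: float = 50.0,
    direction: str = "higher",
) -> pd.DataFrame:
    """Per-genotype stability summary for one fitted trait.

    Columns: MEAN (BLUP-based predicted mean), WAASB, rG, rW, WAASBY and
    the biplot QUADRANT.
    """
    gv = genotypic_values(model)
    mean_perf = gv.mean(axis=1)
    decomp = gei_svd(model.ge)
    w = waasb_scores(decomp, n_axes=n_axes)
    rg = rescale_0_100(mean_perf, direction)
    rw = rescale_0_100(w, "lower")
    y = (rg * theta_y + rw * theta_s) / (theta_y + theta_s)
    return pd.DataFrame(
        {
            "MEAN": mean_perf,
            "WAASB": w,
            "rG": rg,
            "rW": rw,
            "WAASBY": y,
            "QUADRANT": quadrant_classify(mean_perf, w),
        }
    ).rename_axis("GEN")


def rank_across_weights(
    mean_perf,
    waasb,
    grid_step: int = 5,
    direction: str = "higher",
) -> pd.DataFrame:
    """Genotype ranks (1 = best) across the stability-weight grid.

    For each theta_S in {0, step, ..., 100} genotypes are ranked by WAASBY
    computed with theta_Y = 100 - theta_S, descending; ties keep the input
    label order.
    """
    if grid_step <= 0 or 100 % grid_step != 0:
        raise ValueError("grid_step must divide 100")
    perf = pd.Series(mean_perf, dtype=float)
    cols = {}
    for ts in range(0, 101, grid_step):
        y = waasby(perf, waasb, theta_y=100.0 - ts, theta_s=float(ts),
                   direction=direction)
        order = np.argsort(-y.to_numpy(), kind="stable")
        ranks = np.empty(len(y), dtype=int)
        ranks[order] = np.arange(1, len(y) + 1)
        if len(np.unique(np.round(y.to_numpy(), 12))) < len(y):
            logger.info("WAASBY ties at theta_S=%s broken by label order", ts)
        cols[ts] = ranks
    return pd.DataFrame(cols, index=perf.index).rename_axis("GEN")
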