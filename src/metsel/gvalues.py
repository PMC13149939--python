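"""Harmonic-mean / relative-performance genotypic-value indices.

Given the genotypic values GV_ij = u_j + g_i + ge_ij of a genotype-random
fit, three selection indices summarize performance, stability and
adaptability on the trait's own scale:

* HMGV_i   = E / sum_j 1/GV_ij               (harmonic mean; penalizes
  genotypes whose value collapses in any environment),
* RPGV_i   = (1/E) sum_j GV_ij / u_j         (mean relative performance),
* HMRPGV_i = E / sum_j u_j / GV_ij           (harmonic mean of the relative
  performances; performance + stability + adaptability in one number).

The dimensionless indices times the overall mean put them back in trait
units.  All three require strictly positive genotypic values; traits with
legitimate near-zero values should be shifted by the caller first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "hmgv",
    "rpgv",
    "hmrpgv",
    "scale_by_mean",
    "percent_gain",
    "genotypic_value_table",
]


def _check_positive_gv(gv: pd.DataFrame) -> None:
    bad = gv.le(0.0)
    if bad.to_numpy().any():
        cells = [(i, j) for i, j in zip(*np.nonzero(bad.to_numpy()))]
        named = [(gv.index[i], gv.columns[j]) for i, j in cells[:10]]
        raise ValueError(
            f"harmonic-mean indices need GV > 0; offending cells: {named}"
            + ("..." if len(cells) > 10 else "")
        )


def hmgv(gv: pd.DataFrame) -> pd.Series:
    """Harmonic mean of genotypic values per genotype (trait units)."""
    _check_positive_gv(gv)
    e = gv.shape[1]
    out = e / (1.0 / gv).sum(axis=1)
    out.name = "HMGV"
    return out


def rpgv(gv: pd.DataFrame, env_means: pd.Series) -> pd.Series:
    """Mean relative performance of genotypic values (dimensionless)."""
    u = env_means.reindex(gv.columns)
    if u.le(0.0).any():
        raise ValueError("environment means must be positive")
    out = (gv / u).mean(axis=1)
    out.name = "RPGV"
    return out


def hmrpgv(gv: pd.DataFrame, env_means: pd.Series) -> pd.Series:
    """Harmonic mean of the relative performances GV_ij / u_j."""
    _check_positive_gv(gv)
    u = env_means.reindex(gv.columns)
    if u.le(0.0).any():
        raise ValueError("environment means must be positive")
    e = gv.shape[1]
    out = e / (u / gv).sum(axis=1)
    out.name = "HMRPGV"
    return out


def scale_by_mean(index: pd.Series, mu: float) -> pd.Series:
    """Express a dimensionless index in trait units (index times mu)."""
    if mu <= 0:
        raise ValueError("overall mean must be positive")
    return index * float(mu)


def percent_gain(values, reference: float | None = None) -> float | pd.Series:
    """Percent gain of index values.

    For a dimensionless relative index, ``percent_gain(v)`` is
    100 * (v - 1); for trait-unit values against a reference mean,
    ``percent_gain(v, reference)`` is 100 * (mean(v) / reference - 1).
    """
    if reference is None:
        v = np.asarray(values, dtype=float)
        out = 100.0 * (v - 1.0)
        if np.ndim(values) == 0:
            return float(out)
        return pd.Series(out, index=getattr(values, "index", None))
    if reference <= 0:
        raise ValueError("reference mean must be positive")
    return float(100.0 * (np.mean(np.asarray(values, dtype=float)) / reference - 1.0))


def genotypic_value_table(
    gv: pd.DataFrame, env_means: pd.Series, mu: float | None = None
) -> pd.DataFrame:
    """Per-genotype index table ranked by HMRPGV (rank 1 = best).

    ``mu`` defaults to the grand mean of the fitted environment means,
    which equals the grand mean of the genotypic values because genotype
    and interaction BLUPs average to zero.
    """
    if mu is None:
        mu = float(env_means.mean())
    h = hmgv(gv)
    r = rpgv(gv, env_means)
    hr = hmrpgv(gv, env_means)
    order = np.argsort(-hr.to_numpy(), kind="stable")
    ranks = np.empty(len(hr), dtype=int)
    ranks[order] = np.arange(1, len(hr) + 1)
    tab = pd.DataFrame(
        {
            "HMGV": h,
            "RPGV": r,
            "RPGV_MU": scale_by_mean(r, mu),
            "HMRPGV": hr,
            "HMRPGV_MU": scale_by_mean(hr, mu),
            "RANK": ranks,
        }
    ).rename_axis("GEN")
    tab.attrs["mu"] = mu
    tab.attrs["n_env"] = gv.shape[1]
    return tab
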