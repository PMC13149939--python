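"""REML/BLUP engine for the combined multi-environment trial model.

The model for one trait is

    y_ijk = mu + E_j + B_k(j) + G_i + GE_ij + eps_ijk,

with environment, block-within-environment and genotype-by-environment
effects always random, and the genotype either random (the parameterization
behind BLUP-based stability and genotypic-value indices) or fixed (the
parameterization behind the significance report).

Restricted maximum likelihood is computed for the general variance-component
model V = sigma2_e * I + sum_c sigma2_c Z_c Z_c'.  Because the random terms
are crossed, everything is evaluated through Gram matrices and the Woodbury
identity: with Z the concatenated incidence matrix (q columns, q << n for a
trial), one restricted-likelihood-and-gradient evaluation costs O(q^3).
The restricted likelihood is maximized with L-BFGS-B under non-negativity
bounds using the analytic gradient; the profile is re-optimized with a
component pinned at zero whenever the unconstrained path would go negative
(the bound simply stays active).  BLUPs solve the mixed-model equations at
the REML estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .simulate import METDataset

__all__ = [
    "DesignError",
    "ModelSpec",
    "VarianceComponents",
    "FittedMETModel",
    "LRTResult",
    "fit_met",
    "lrt_random_term",
    "anova_genotype",
    "genotypic_values",
    "heritability",
]

logger = logging.getLogger(__name__)

# convergence of the restricted-likelihood maximization
_REML_FTOL = 1e-14
_REML_GTOL = 1e-10
_REML_MAXITER = 500
_ACTIVE_TOL = 1e-12  # variance (on the standardized scale) treated as zero


class DesignError(ValueError):
    """Raised when the data cannot support the requested model."""


@dataclass
class ModelSpec:
    """Which trait to fit and how the genotype margin enters the model."""

    trait: str
    genotype_role: str = "random"

    def __post_init__(self) -> None:
        if self.genotype_role not in ("random", "fixed"):
            raise ValueError("genotype_role must be 'random' or 'fixed'")


@dataclass
class VarianceComponents:
    sigma2_env: float
    sigma2_block_env: float
    sigma2_gei: float
    sigma2_resid: float
    sigma2_gen: float | None = None  # absent when genotype is fixed

    def as_dict(self) -> dict[str, float]:
        out = {
            "sigma2_env": self.sigma2_env,
            "sigma2_block_env": self.sigma2_block_env,
        }
        if self.sigma2_gen is not None:
            out["sigma2_gen"] = self.sigma2_gen
        out["sigma2_gei"] = self.sigma2_gei
        out["sigma2_resid"] = self.sigma2_resid
        return out

    @property
    def sigma2_phen(self) -> float:
        return float(sum(self.as_dict().values()))

    def phen_shares(self) -> dict[str, float]:
        """Fraction of the phenotypic variance carried by each component."""
        total = self.sigma2_phen
        if total <= 0:
            raise ValueError("total variance is zero; shares undefined")
        return {k: v / total for k, v in self.as_dict().items()}


@dataclass
class LRTResult:
    term: str
    chi2: float
    df: int
    p_value: float
    loglik_full: float
    loglik_reduced: float


@dataclass
class FittedMETModel:
    """REML fit: variance components, BLUPs and derived quantities."""

    spec: ModelSpec
    mu_hat: float
    env_means: pd.Series          # u_j = mu_hat + BLUP(E_j)
    g: pd.Series                  # genotype BLUPs (random) or estimates (fixed)
    ge: pd.DataFrame              # genotype x environment interaction BLUPs
    block_effects: pd.Series      # block-within-environment BLUPs
    components: VarianceComponents
    reml_loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    n_env: int
    n_gen: int
    n_blocks: int
    fixed_effects: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    fixed_cov: np.ndarray | None = None

    @property
    def gen_levels(self) -> list[str]:
        return list(self.g.index)

    @property
    def env_levels(self) -> list[str]:
        return list(self.env_means.index)

    def predicted_genotype_means(self) -> pd.Series:
        """BLUP-based mean performance: mean_j (u_j + g_i + ge_ij)."""
        gv = genotypic_values(self)
        return gv.mean(axis=1)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    z = np.zeros((codes.size, n_levels))
    z[np.arange(codes.size), codes] = 1.0
    return z


def _trait_frame(data: METDataset | pd.DataFrame, trait: str) -> pd.DataFrame:
    if isinstance(data, METDataset):
        return data.trait_frame(trait)
    sub = data[data["TRAIT"] == trait]
    if sub.empty:
        raise KeyError(f"trait {trait!r} not present")
    return sub.reset_index(drop=True)


class _Design:
    """Factor codes and incidence matrices for one trait's observations."""

    def __init__(self, df: pd.DataFrame):
        self.env_levels = list(pd.unique(df["ENV"]))
        self.gen_levels = list(pd.unique(df["GEN"]))
        self.block_levels = list(pd.unique(df["BLOCK"]))
        if len(self.env_levels) < 2 or len(self.gen_levels) < 2 \
                or len(self.block_levels) < 2:
            raise DesignError("every factor needs at least 2 levels")
        env_pergen = df.groupby("GEN", sort=False)["ENV"].nunique()
        if (env_pergen < 2).any():
            bad = env_pergen.index[env_pergen < 2].tolist()
            raise DesignError(f"genotypes observed in <2 environments: {bad}")
        self.e = len(self.env_levels)
        self.g = len(self.gen_levels)
        self.b = len(self.block_levels)
        self.je = pd.Categorical(df["ENV"], categories=self.env_levels).codes.astype(int)
        self.ig = pd.Categorical(df["GEN"], categories=self.gen_levels).codes.astype(int)
        self.kb = pd.Categorical(df["BLOCK"], categories=self.block_levels).codes.astype(int)
        self.y = df["VALUE"].to_numpy(dtype=float)
        self.n = self.y.size

    def z_env(self) -> np.ndarray:
        return _indicator(self.je, self.e)

    def z_block_env(self) -> np.ndarray:
        return _indicator(self.je * self.b + self.kb, self.e * self.b)

    def z_gen(self) -> np.ndarray:
        return _indicator(self.ig, self.g)

    def z_gei(self) -> np.ndarray:
        return _indicator(self.ig * self.e + self.je, self.g * self.e)

    def x_intercept(self) -> np.ndarray:
        return np.ones((self.n, 1))

    def x_genotype_fixed(self) -> np.ndarray:
        # treatment coding: intercept + g-1 genotype dummies
        return np.hstack([np.ones((self.n, 1)), _indicator(self.ig, self.g)[:, 1:]])

    def is_balanced(self) -> bool:
        counts = np.zeros((self.e, self.g, self.b), dtype=int)
        np.add.at(counts, (self.je, self.ig, self.kb), 1)
        return bool(np.all(counts == 1))


# ---------------------------------------------------------------------------
# restricted likelihood via Gram matrices
# ---------------------------------------------------------------------------

class _REMLProblem:
    def __init__(self, y: np.ndarray, X: np.ndarray, Zs: Sequence[np.ndarray],
                 names: Sequence[str]):
        self.n, self.p = X.shape
        self.names = list(names)
        Z = np.hstack(Zs) if Zs else np.zeros((self.n, 0))
        self.X, self.Z, self.y = X, Z, y
        sizes = [z.shape[1] for z in Zs]
        self.slices: list[slice] = []
        off = 0
        for s in sizes:
            self.slices.append(slice(off, off + s))
            off += s
        self.q = off
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self._const = -0.5 * (self.n - self.p) * np.log(2.0 * np.pi)

    # -- core evaluation -----------------------------------------------------

    def _core(self, theta: np.ndarray) -> dict:
        v, s2e = theta[:-1], float(theta[-1])
        act_cols = np.zeros(self.q, dtype=bool)
        d = np.empty(self.q)
        for vc, sl in zip(v, self.slices):
            if vc > _ACTIVE_TOL:
                act_cols[sl] = True
                d[sl] = vc
        a = np.flatnonzero(act_cols)
        da = d[a]
        ZtZ_aa = self.ZtZ[np.ix_(a, a)]
        if a.size:
            M = ZtZ_aa / s2e + np.diag(1.0 / da)
            cho = cho_factor(M, lower=True)
            logdet_M = 2.0 * np.sum(np.log(np.diag(cho[0])))

            def K(B: np.ndarray) -> np.ndarray:
                return cho_solve(cho, B)
        else:
            logdet_M = 0.0

            def K(B: np.ndarray) -> np.ndarray:
                return np.zeros_like(B)

        ZtZ_aq = self.ZtZ[a, :]          # active x all
        ZtX_a = self.ZtX[a, :]
        Zty_a = self.Zty[a]

        KZtZ = K(ZtZ_aq)
        KZtX = K(ZtX_a)
        KZty = K(Zty_a)

        ZtVinvZ = (self.ZtZ - ZtZ_aq.T @ KZtZ / s2e) / s2e
        ZtVinvX = (self.ZtX - ZtZ_aq.T @ KZtX / s2e) / s2e
        ZtVinvy = (self.Zty - ZtZ_aq.T @ KZty / s2e) / s2e
        XtVinvX = (self.XtX - ZtX_a.T @ KZtX / s2e) / s2e
        XtVinvy = (self.Xty - ZtX_a.T @ KZty / s2e) / s2e
        ytVinvy = (self.yty - Zty_a @ KZty / s2e) / s2e

        cho_x = cho_factor(XtVinvX, lower=True)
        logdet_X = 2.0 * np.sum(np.log(np.diag(cho_x[0])))
        beta = cho_solve(cho_x, XtVinvy)
        yPy = float(ytVinvy - XtVinvy @ beta)
        logdet_V = self.n * np.log(s2e) + logdet_M + float(np.sum(np.log(da)))
        loglik = -0.5 * (logdet_V + logdet_X + yPy) + self._const
        return dict(
            v=v, s2e=s2e, a=a, da=da, K=K, cho_x=cho_x, beta=beta,
            ZtZ_aa=ZtZ_aa, ZtZ_aq=ZtZ_aq, ZtX_a=ZtX_a, Zty_a=Zty_a,
            KZtZ=KZtZ, KZtX=KZtX, KZty=KZty,
            ZtVinvZ=ZtVinvZ, ZtVinvX=ZtVinvX, ZtVinvy=ZtVinvy,
            XtVinvX=XtVinvX, XtVinvy=XtVinvy, ytVinvy=ytVinvy,
            yPy=yPy, loglik=loglik,
        )

    def loglik(self, theta: np.ndarray) -> float:
        return self._core(theta)["loglik"]

    def _gram_vinv2(self, c: dict, AtB, ZtA, ZtB) -> np.ndarray:
        """(V^-1 A)' (V^-1 B) from Gram blocks (ZtA/ZtB on active rows)."""
        s2e, K = c["s2e"], c["K"]
        KZtB = K(ZtB)
        KZtA = K(ZtA)
        t2 = ZtA.T @ KZtB
        t3 = KZtA.T @ c["ZtZ_aa"] @ KZtB
        return (AtB - 2.0 * t2 / s2e + t3 / s2e**2) / s2e**2

    def neg_loglik_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        c = self._core(theta)
        s2e = c["s2e"]
        XtVinvX_inv_XtVinvZ = cho_solve(c["cho_x"], c["ZtVinvX"].T)
        ZtPZ = c["ZtVinvZ"] - c["ZtVinvX"] @ XtVinvX_inv_XtVinvZ
        ZtPy = c["ZtVinvy"] - c["ZtVinvX"] @ c["beta"]

        grad = np.empty(len(self.slices) + 1)
        for ci, sl in enumerate(self.slices):
            tr = float(np.trace(ZtPZ[sl, sl]))
            ss = float(ZtPy[sl] @ ZtPy[sl])
            grad[ci] = 0.5 * (tr - ss)  # d(-loglik)/d v_c

        # residual component
        tr_vinv = (self.n - float(np.trace(c["K"](c["ZtZ_aa"]))) / s2e) / s2e
        XV2X = self._gram_vinv2(c, self.XtX, c["ZtX_a"], c["ZtX_a"])
        XV2y = self._gram_vinv2(c, self.Xty[:, None], c["ZtX_a"],
                                c["Zty_a"][:, None]).ravel()
        yV2y = float(self._gram_vinv2(c, np.array([[self.yty]]), c["Zty_a"][:, None],
                                      c["Zty_a"][:, None])[0, 0])
        beta = c["beta"]
        tr_P = tr_vinv - float(np.trace(cho_solve(c["cho_x"], XV2X)))
        Py2 = yV2y - 2.0 * float(beta @ XV2y) + float(beta @ XV2X @ beta)
        grad[-1] = 0.5 * (tr_P - Py2)
        return -c["loglik"], grad

    def solve(self, starts: Sequence[np.ndarray]) -> optimize.OptimizeResult:
        f_starts = sorted(
            [(self.neg_loglik_grad(s)[0], tuple(s)) for s in starts]
        )
        bounds = [(0.0, None)] * len(self.slices) + [(1e-10, None)]
        lb = np.array([b[0] for b in bounds])

        def _pg(res) -> float:
            g = np.asarray(res.jac, dtype=float).copy()
            g[(res.x <= lb + 1e-12) & (g > 0)] = 0.0
            return float(np.max(np.abs(g)))

        # try the best start first; on a stalled line search, restart (which
        # resets the Hessian approximation) and then fall back to the other
        # start points
        x0s = [np.array(s) for _, s in f_starts]
        x0s = [x0s[0]] + x0s
        results = []
        for i, x0 in enumerate(x0s):
            if i == 1:  # restart from wherever the first attempt stopped
                x0 = results[0].x
            res = optimize.minimize(
                self.neg_loglik_grad, x0, jac=True, method="L-BFGS-B",
                bounds=bounds,
                options=dict(maxiter=_REML_MAXITER, ftol=_REML_FTOL,
                             gtol=_REML_GTOL, maxfun=5 * _REML_MAXITER),
            )
            results.append(res)
            if res.success or _pg(res) < 1e-6:
                break
        res = min(results, key=lambda r: r.fun)
        # L-BFGS-B line searches can fail at machine precision; call the fit
        # converged whenever the projected gradient (standardized scale) is
        # negligible
        res.converged = bool(res.success or _pg(res) < 1e-5)
        return res

    def blups(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (beta_hat, random-effect BLUPs u, cov of beta_hat).

        Solved through the augmented least-squares form of the mixed-model
        equations (QR-based), which stays accurate when the residual
        variance is orders of magnitude below the other components.
        """
        c = self._core(theta)
        v, s2e = theta[:-1], float(theta[-1])
        act_cols = np.zeros(self.q, dtype=bool)
        d = np.empty(self.q)
        for vc, sl in zip(v, self.slices):
            if vc > _ACTIVE_TOL:
                act_cols[sl] = True
                d[sl] = vc
        a = np.flatnonzero(act_cols)
        Za = self.Z[:, a]
        # minimize ||y - X b - Za ua||^2 + s2e * ua' D^-1 ua
        top = np.hstack([self.X, Za])
        bottom = np.hstack([
            np.zeros((a.size, self.p)),
            np.diag(np.sqrt(s2e / d[a])),
        ])
        A = np.vstack([top, bottom])
        b = np.concatenate([self.y, np.zeros(a.size)])
        sol = np.linalg.lstsq(A, b, rcond=None)[0]
        beta = sol[: self.p]
        u = np.zeros(self.q)
        u[a] = sol[self.p:]
        cov_beta = cho_solve(c["cho_x"], np.eye(self.p))
        return beta, u, cov_beta


# ---------------------------------------------------------------------------
# balanced method-of-moments start values
# ---------------------------------------------------------------------------

def _balanced_moments(des: _Design) -> dict[str, float] | None:
    """Expected-mean-square estimators on a balanced layout (else None)."""
    if not des.is_balanced():
        return None
    e, g, b, y = des.e, des.g, des.b, des.y
    cell = np.zeros((e, g))
    np.add.at(cell, (des.je, des.ig), y)
    cell /= b
    blk = np.zeros((e, b))
    np.add.at(blk, (des.je, des.kb), y)
    blk /= g
    env_m = cell.mean(axis=1)
    gen_m = cell.mean(axis=0)
    grand = y.mean()

    ss_env = g * b * np.sum((env_m - grand) ** 2)
    ss_blk = g * np.sum((blk - env_m[:, None]) ** 2)
    ss_gen = e * b * np.sum((gen_m - grand) ** 2)
    ss_gei = b * np.sum((cell - env_m[:, None] - gen_m[None, :] + grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_res = ss_tot - ss_env - ss_blk - ss_gen - ss_gei

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


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------

def _build_problem(des: _Design, genotype_role: str):
    if genotype_role == "random":
        X = des.x_intercept()
        Zs = [des.z_env(), des.z_block_env(), des.z_gen(), des.z_gei()]
        names = ["env", "block_env", "gen", "gei"]
    else:
        X = des.x_genotype_fixed()
        Zs = [des.z_env(), des.z_block_env(), des.z_gei()]
        names = ["env", "block_env", "gei"]
    return X, Zs, names


def _fit_reml(des: _Design, genotype_role: str):
    X, Zs, names = _build_problem(des, genotype_role)
    scale = float(np.std(des.y))
    if scale <= 0:
        scale = 1.0
    ys = des.y / scale
    prob = _REMLProblem(ys, X, Zs, names)

    n_comp = len(names)
    vtot = float(np.var(ys))
    vtot = vtot if vtot > 0 else 1.0
    starts = [np.full(n_comp + 1, vtot / (n_comp + 1))]
    mom = _balanced_moments(des)
    if mom is not None:
        order = names + ["resid"]
        s = np.array([mom[k] / scale**2 for k in order])
        s = np.clip(s, [0.0] * n_comp + [1e-10], None)
        starts.append(s)

    res = prob.solve(starts)
    theta = np.asarray(res.x, dtype=float)
    theta[theta < _ACTIVE_TOL] = 0.0
    clipped = [names[i] for i in range(n_comp) if theta[i] == 0.0]
    if clipped:
        logger.info("variance components at the zero boundary: %s", clipped)
    if not res.converged:
        logger.warning("REML did not converge: %s", res.message)
    beta, u, cov_beta = prob.blups(theta)
    # back to the data scale
    theta_data = theta * scale**2
    loglik = -res.fun - (prob.n - prob.p) * np.log(scale)
    return prob, names, theta_data, beta * scale, u * scale, \
        cov_beta * scale**2, loglik, res


def fit_met(
    data: METDataset | pd.DataFrame,
    spec: ModelSpec,
    env_mean_mode: str = "blup",
) -> FittedMETModel:
    """Fit the combined MET model for one trait by REML.

    Returns variance components, the restricted log-likelihood, and the
    BLUPs of every random term; with genotype random these feed the
    stability and genotypic-value indices downstream.  ``env_mean_mode``
    chooses how the environment means u_j are reported: ``"blup"``
    (mu_hat + shrunken environment effect, the default) or ``"empirical"``
    (observed per-environment means, mainly for unbalanced data).
    """
    if env_mean_mode not in ("blup", "empirical"):
        raise ValueError("env_mean_mode must be 'blup' or 'empirical'")
    df = _trait_frame(data, spec.trait)
    des = _Design(df)
    prob, names, theta, beta, u, cov_beta, loglik, res = _fit_reml(
        des, spec.genotype_role
    )

    comp_map = dict(zip(names, theta[:-1]))
    components = VarianceComponents(
        sigma2_env=comp_map["env"],
        sigma2_block_env=comp_map["block_env"],
        sigma2_gei=comp_map["gei"],
        sigma2_resid=theta[-1],
        sigma2_gen=comp_map.get("gen"),
    )

    sl = dict(zip(names, prob.slices))
    env_blup = u[sl["env"]]
    blk_blup = u[sl["block_env"]]
    gei_blup = u[sl["gei"]].reshape(des.g, des.e)

    # Re-express the BLUPs in the sum-to-zero parameterization: the raw
    # interaction BLUPs carry nonzero margins (main-effect information the
    # mixed model attributes partly to the GE prior); moving those margins
    # into g_i and u_j leaves every genotypic value u_j + g_i + ge_ij
    # unchanged and makes the GE matrix exactly double-centered, which is
    # what the AMMI-style SVD downstream decomposes.
    gm = gei_blup.mean(axis=1)
    em = gei_blup.mean(axis=0)
    mm = gei_blup.mean()
    gei_blup = gei_blup - gm[:, None] - em[None, :] + mm
    env_blup = env_blup + em

    mu_hat = float(beta[0])
    if spec.genotype_role == "random":
        g_eff = pd.Series(u[sl["gen"]] + gm - mm, index=des.gen_levels, name="g")
        fixed = pd.Series({"mu": mu_hat})
    else:
        # treatment coding: effects of levels 2..g relative to level 1,
        # re-expressed as deviations from the genotype mean so g sums to 0
        raw = np.concatenate([[0.0], beta[1:]])
        g_eff = pd.Series(raw - raw.mean() + gm - mm, index=des.gen_levels, name="g")
        mu_hat = mu_hat + raw.mean()
        fixed = pd.Series(beta, index=["mu"] + [f"GEN[{l}]" for l in des.gen_levels[1:]])

    if env_mean_mode == "empirical":
        env_means = df.groupby("ENV", sort=False)["VALUE"].mean().reindex(
            des.env_levels).rename("u_j")
    else:
        env_means = pd.Series(mu_hat + env_blup, index=des.env_levels,
                              name="u_j")
    block_idx = pd.MultiIndex.from_product(
        [des.env_levels, des.block_levels], names=["ENV", "BLOCK"]
    )
    return FittedMETModel(
        spec=spec,
        mu_hat=mu_hat,
        env_means=env_means,
        g=g_eff,
        ge=pd.DataFrame(gei_blup, index=des.gen_levels, columns=des.env_levels),
        block_effects=pd.Series(blk_blup, index=block_idx, name="b_kj"),
        components=components,
        reml_loglik=loglik,
        converged=bool(res.converged),
        n_iter=int(res.nit),
        n_obs=des.n,
        n_env=des.e,
        n_gen=des.g,
        n_blocks=des.b,
        fixed_effects=fixed,
        fixed_cov=cov_beta,
    )


_TERM_TO_NAME = {"ENV": "env", "BLOCK": "block_env", "GEN": "gen", "GEI": "gei"}


def lrt_random_term(
    data: METDataset | pd.DataFrame,
    spec: ModelSpec,
    term: str,
    boundary_correction: bool = False,
) -> LRTResult:
    """Likelihood-ratio test for one random term (ENV, BLOCK, GEN or GEI).

    Both fits use REML with the same fixed structure; the statistic is
    2*(l_full - l_reduced) clipped at zero and referred to chi2 with 1 df.
    Because the null value sigma2 = 0 sits on the boundary of the parameter
    space, the chi2_1 reference is conservative; ``boundary_correction=True``
    uses the 50:50 mixture of a point mass at zero and chi2_1 instead, which
    is the calibrated null distribution.
    """
    name = _TERM_TO_NAME.get(term.upper())
    if name is None:
        raise ValueError(f"unknown term {term!r}; use ENV, BLOCK, GEN or GEI")
    if name == "gen" and spec.genotype_role != "random":
        raise ValueError("GEN is not a random term when genotype_role='fixed'")

    df = _trait_frame(data, spec.trait)
    des = _Design(df)
    X, Zs, names = _build_problem(des, spec.genotype_role)
    if name not in names:
        raise ValueError(f"term {term!r} not in the model")

    scale = float(np.std(des.y)) or 1.0
    ys = des.y / scale

    def _max_loglik(keep: list[int]) -> float:
        zs = [Zs[i] for i in keep]
        nm = [names[i] for i in keep]
        prob = _REMLProblem(ys, X, zs, nm)
        vtot = float(np.var(ys)) or 1.0
        starts = [np.full(len(zs) + 1, vtot / (len(zs) + 2))]
        res = prob.solve(starts)
        return -res.fun

    full = _max_loglik(list(range(len(Zs))))
    reduced = _max_loglik([i for i, nm in enumerate(names) if nm != name])
    chi2 = max(0.0, 2.0 * (full - reduced))
    p = float(stats.chi2.sf(chi2, df=1))
    if boundary_correction:
        p = 0.5 * p if chi2 > 0 else 1.0
    return LRTResult(term=term.upper(), chi2=chi2, df=1, p_value=p,
                     loglik_full=full, loglik_reduced=reduced)


def anova_genotype(
    data: METDataset | pd.DataFrame,
    spec: ModelSpec,
    per_environment: bool = False,
) -> pd.DataFrame:
    """F-test of the fixed genotype effect.

    Combined analysis: Wald-type F at the REML variance estimates with
    denominator df from the containment method, (g-1)(e-1), since the
    genotype contrasts are contained in the random GEI term.  With
    ``per_environment=True`` each environment gets the classical fixed-
    effects RCBD ANOVA (y ~ block + genotype) instead.
    """
    if spec.genotype_role != "fixed":
        raise ValueError("anova_genotype requires genotype_role='fixed'")
    df = _trait_frame(data, spec.trait)

    if per_environment:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rows = []
        for env, sub in df.groupby("ENV", sort=False):
            fit = smf.ols("VALUE ~ C(BLOCK) + C(GEN)", data=sub).fit()
            tab = sm.stats.anova_lm(fit, typ=2)
            row = tab.loc["C(GEN)"]
            rows.append(
                {
                    "ENV": env,
                    "term": "GEN",
                    "num_df": int(row["df"]),
                    "den_df": int(tab.loc["Residual", "df"]),
                    "F": float(row["F"]),
                    "p_value": float(row["PR(>F)"]),
                }
            )
        return pd.DataFrame(rows)

    des = _Design(df)
    prob, names, theta, beta, u, cov_beta, loglik, res = _fit_reml(des, "fixed")
    L = np.zeros((des.g - 1, beta.size))
    L[:, 1:] = np.eye(des.g - 1)
    lb = L @ beta
    lcov = L @ cov_beta @ L.T
    fstat = float(lb @ np.linalg.solve(lcov, lb)) / (des.g - 1)
    num_df = des.g - 1
    den_df = (des.g - 1) * (des.e - 1)
    return pd.DataFrame(
        [
            {
                "term": "GEN",
                "num_df": num_df,
                "den_df": den_df,
                "F": fstat,
                "p_value": float(stats.f.sf(fstat, num_df, den_df)),
            }
        ]
    )


def genotypic_values(model: FittedMETModel) -> pd.DataFrame:
    """Genotypic values GV_ij = u_j + g_i + ge_ij (complete, BLUP-filled)."""
    if model.spec.genotype_role != "random":
        raise ValueError(
            "genotypic values need the genotype-random fit; refit with "
            "ModelSpec(genotype_role='random')"
        )
    u = model.env_means.to_numpy()
    g = model.g.to_numpy()
    return pd.DataFrame(
        u[None, :] + g[:, None] + model.ge.to_numpy(),
        index=model.gen_levels,
        columns=model.env_levels,
    )


def heritability(model: FittedMETModel, basis: str = "mean") -> float:
    """Broad-sense heritability of the trait.

    ``basis='mean'`` (default): on the genotype-mean basis,
    h2 = s2_g / (s2_g + s2_gei/e + s2_resid/(e*r)); ``basis='plot'``:
    plot-level share s2_g / s2_phen.
    """
    comp = model.components
    if comp.sigma2_gen is None:
        raise ValueError("heritability needs the genotype-random fit")
    if basis == "mean":
        denom = (
            comp.sigma2_gen
            + comp.sigma2_gei / model.n_env
            + comp.sigma2_resid / (model.n_env * model.n_blocks)
        )
    elif basis == "plot":
        denom = comp.sigma2_phen
    else:
        raise ValueError("basis must be 'mean' or 'plot'")
    if denom <= 0:
        raise ValueError("total variance is zero; heritability undefined")
    return float(comp.sigma2_gen / denom)
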