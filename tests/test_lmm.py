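"""Tests of the REML/BLUP engine: component estimation, tests, BLUPs."""

import dataclasses
import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from conftest import anova_components_oracle
from metsel.lmm import (DesignError, FittedMETModel, ModelSpec,
                        VarianceComponents, anova_genotype, fit_met,
                        genotypic_values, heritability, lrt_random_term)
from metsel.simulate import SimulationConfig, simulate_met


def _components_dict(model) -> dict[str, float]:
    c = model.components
    return {"env": c.sigma2_env, "block_env": c.sigma2_block_env,
            "gen": c.sigma2_gen, "gei": c.sigma2_gei, "resid": c.sigma2_resid}


class TestREMLFit:
    def test_matches_balanced_anova_oracle(self, small_dataset, fitted_model):
        oracle = anova_components_oracle(small_dataset.trait_frame("VALUE"))
        assert all(v > 0 for v in oracle.values()), "oracle not interior"
        est = _components_dict(fitted_model)
        for k, truth in oracle.items():
            assert est[k] == pytest.approx(truth, rel=1e-5), k

    def test_matches_lme4_on_crossed_model(self):
        # independent cross-check: same model fitted by lme4 through Rscript
        cfg = SimulationConfig(
            n_gen=10, n_env=4, n_blocks=3, grand_mean=20.0, sigma2_env=2.0,
            sigma2_block_env=0.5, sigma2_gen=1.5, sigma2_gei=1.0,
            sigma2_resid=1.0, gei_structure="iid", seed=7,
        )
        ds = simulate_met(cfg)
        model = fit_met(ds, ModelSpec(trait="VALUE"))
        script = """
        suppressMessages(library(lme4))
        d <- read.csv(commandArgs(TRUE)[1])
        fit <- lmer(VALUE ~ 1 + (1|ENV) + (1|BLOCK:ENV) + (1|GEN) + (1|GEN:ENV),
                    data=d, REML=TRUE,
                    control=lmerControl(optimizer="bobyqa",
                                        optCtrl=list(rhobeg=0.2, rhoend=2e-9)))
        vc <- as.data.frame(VarCorr(fit))
        cat(jsonlite::toJSON(list(grp=vc$grp, vcov=vc$vcov,
                                  loglik=as.numeric(logLik(fit))), digits=12))
        """
        import tempfile, os
        with tempfile.TemporaryDirectory() as td:
            csv = os.path.join(td, "d.csv")
            ds.to_csv(csv)
            rfile = os.path.join(td, "fit.R")
            with open(rfile, "w") as fh:
                fh.write(script)
            proc = subprocess.run(["Rscript", rfile, csv], capture_output=True,
                                  text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        out = json.loads(proc.stdout)
        vc = dict(zip(out["grp"], out["vcov"]))
        est = _components_dict(model)
        mapping = {"env": "ENV", "block_env": "BLOCK:ENV", "gen": "GEN",
                   "gei": "GEN:ENV", "resid": "Residual"}
        for mine, theirs in mapping.items():
            assert est[mine] == pytest.approx(vc[theirs], rel=1e-4), mine
        ll = out["loglik"][0] if isinstance(out["loglik"], list) else out["loglik"]
        assert model.reml_loglik == pytest.approx(ll, abs=1e-6)

    def test_noise_free_degenerate_fit(self):
        # environment and genotype effects only: the residual estimate must
        # collapse and the fitted environment means must match the truth
        cfg = SimulationConfig(
            n_gen=12, n_env=5, n_blocks=3, grand_mean=10.0, sigma2_env=2.0,
            sigma2_block_env=0.0, sigma2_gen=1.0, sigma2_gei=0.0, gei_rank=0,
            sigma2_resid=1e-14, seed=8,
        )
        ds = simulate_met(cfg)
        model = fit_met(ds, ModelSpec(trait="VALUE"))
        assert model.components.sigma2_resid <= 1e-6
        # u_j equals the (noise-free) empirical environment mean, which is
        # the generating mean mu + E_j shifted by the non-identifiable
        # realized mean genotype effect
        emp = ds.trait_frame("VALUE").groupby("ENV", sort=False)["VALUE"].mean()
        assert np.allclose(model.env_means.to_numpy(), emp.to_numpy(), atol=1e-6)
        truth_u = cfg.grand_mean[0] + ds.truth.env_effects[:, 0]
        dev = model.env_means.to_numpy() - truth_u
        assert np.std(dev) < 1e-6

    def test_blup_shrinkage_towards_mean(self, small_dataset, fitted_model):
        df = small_dataset.trait_frame("VALUE")
        raw_dev = df.groupby("GEN", sort=False)["VALUE"].mean() - df["VALUE"].mean()
        assert (fitted_model.g.abs() <= raw_dev.abs() + 1e-9).all()

    def test_ge_blup_matrix_is_double_centered(self, fitted_model):
        assert np.abs(fitted_model.ge.sum(axis=0)).max() < 1e-6
        assert np.abs(fitted_model.ge.sum(axis=1)).max() < 1e-6

    def test_relabeling_permutes_outputs(self, small_dataset):
        df = small_dataset.trait_frame("VALUE").copy()
        ren = {f"G{i+1}": f"X{(i+5) % 18 + 1}" for i in range(18)}
        df2 = df.assign(GEN=df["GEN"].map(ren))
        m1 = fit_met(df.assign(TRAIT="VALUE"), ModelSpec(trait="VALUE"))
        m2 = fit_met(df2.assign(TRAIT="VALUE"), ModelSpec(trait="VALUE"))
        g2 = m2.g.rename(index={v: k for k, v in ren.items()})
        assert np.allclose(m1.g.sort_index(), g2.sort_index(), atol=1e-8)

    def test_unbalanced_data_fits_and_predicts_all_cells(self, small_dataset):
        rng = np.random.default_rng(0)
        df = small_dataset.trait_frame("VALUE")
        keep = rng.random(len(df)) > 0.08  # ~8 % missing plots
        model = fit_met(df[keep], ModelSpec(trait="VALUE"))
        assert model.converged
        gv = genotypic_values(model)
        assert gv.shape == (18, 6)
        assert np.isfinite(gv.to_numpy()).all()

    def test_empirical_env_mean_mode(self, small_dataset):
        m = fit_met(small_dataset, ModelSpec(trait="VALUE"),
                    env_mean_mode="empirical")
        emp = small_dataset.trait_frame("VALUE").groupby(
            "ENV", sort=False)["VALUE"].mean()
        assert np.allclose(m.env_means, emp)

    def test_design_errors(self, small_dataset):
        df = small_dataset.trait_frame("VALUE")
        one_env = df[df["ENV"] == "E1"]
        with pytest.raises(DesignError):
            fit_met(one_env, ModelSpec(trait="VALUE"))

    def test_phenotypic_shares_sum_to_one(self, fitted_model):
        shares = fitted_model.components.phen_shares()
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-10)
        total = sum(fitted_model.components.as_dict().values())
        assert fitted_model.components.sigma2_phen == pytest.approx(total)


class TestLRT:
    def test_equal_logliks_give_zero_chi2(self):
        from metsel.lmm import LRTResult
        from scipy import stats

        chi2 = max(0.0, 2.0 * (-100.0 - (-100.0)))
        assert chi2 == 0.0
        assert stats.chi2.sf(chi2, 1) == pytest.approx(1.0)

    def test_null_gei_gives_large_p_values(self):
        ps = []
        for s in range(12):
            cfg = SimulationConfig(
                n_gen=18, n_env=6, n_blocks=3, grand_mean=10.0, sigma2_env=1.0,
                sigma2_block_env=0.5, sigma2_gen=1.0, sigma2_gei=0.0,
                gei_rank=0, sigma2_resid=1.0, seed=300 + s,
            )
            r = lrt_random_term(simulate_met(cfg), ModelSpec(trait="VALUE"), "GEI")
            ps.append(r.p_value)
        assert np.median(ps) > 0.3

    def test_strong_environment_effect_detected(self):
        rejected = 0
        for s in range(20):
            cfg = SimulationConfig(
                n_gen=12, n_env=6, n_blocks=3, grand_mean=10.0, sigma2_env=5.0,
                sigma2_block_env=0.2, sigma2_gen=1.0, sigma2_gei=0.2,
                sigma2_resid=1.0, gei_structure="iid", seed=400 + s,
            )
            r = lrt_random_term(simulate_met(cfg), ModelSpec(trait="VALUE"), "ENV")
            rejected += r.p_value < 0.01
        assert rejected >= 19

    def test_unknown_term_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            lrt_random_term(small_dataset, ModelSpec(trait="VALUE"), "YEAR")


class TestAnovaGenotype:
    def test_single_environment_matches_textbook_rcbd(self):
        rng = np.random.default_rng(6)
        g, b = 8, 4
        gen = np.repeat([f"G{i}" for i in range(g)], b)
        blk = np.tile([f"B{k}" for k in range(b)], g)
        y = (rng.normal(0, 1, g)[np.repeat(np.arange(g), b)]
             + rng.normal(0, 0.5, b)[np.tile(np.arange(b), g)]
             + rng.normal(0, 0.7, g * b) + 10)
        df = pd.DataFrame({"ENV": "E1", "GEN": gen, "BLOCK": blk,
                           "TRAIT": "T", "VALUE": y})
        tab = anova_genotype(df, ModelSpec(trait="T", genotype_role="fixed"),
                             per_environment=True)
        # textbook oracle from raw sums of squares
        grand = y.mean()
        gm = df.groupby("GEN")["VALUE"].mean()
        bm = df.groupby("BLOCK")["VALUE"].mean()
        ss_g = b * ((gm - grand) ** 2).sum()
        ss_b = g * ((bm - grand) ** 2).sum()
        ss_tot = ((y - grand) ** 2).sum()
        ss_e = ss_tot - ss_g - ss_b
        f_oracle = (ss_g / (g - 1)) / (ss_e / ((g - 1) * (b - 1)))
        assert tab["F"].iloc[0] == pytest.approx(f_oracle, abs=1e-8)

    def test_combined_detects_strong_genotype_effect(self):
        cfg = SimulationConfig(
            n_gen=12, n_env=4, n_blocks=3, grand_mean=10.0, sigma2_env=1.0,
            sigma2_block_env=0.2, sigma2_gen=4.0, sigma2_gei=0.2,
            sigma2_resid=1.0, gei_structure="iid", seed=9,
        )
        tab = anova_genotype(simulate_met(cfg),
                             ModelSpec(trait="VALUE", genotype_role="fixed"))
        assert tab["num_df"].iloc[0] == 11
        assert tab["den_df"].iloc[0] == 33
        assert tab["p_value"].iloc[0] < 1e-4

    def test_requires_fixed_role(self, small_dataset):
        with pytest.raises(ValueError):
            anova_genotype(small_dataset, ModelSpec(trait="VALUE"))


class TestGenotypicValues:
    def test_hand_case(self):
        model = _toy_model(
            u=[10.0, 20.0], g=[1.0, -1.0],
            ge=[[0.5, -0.5], [-0.5, 0.5]],
        )
        gv = genotypic_values(model)
        # brute-force cellwise evaluation of u_j + g_i + ge_ij
        expected = np.array([[10 + 1 + 0.5, 20 + 1 - 0.5],
                             [10 - 1 - 0.5, 20 - 1 + 0.5]])
        assert np.allclose(gv.to_numpy(), expected)

    def test_column_means_equal_env_means_plus_mean_g(self, fitted_model):
        gv = genotypic_values(fitted_model)
        expected = fitted_model.env_means + fitted_model.g.mean()
        assert np.allclose(gv.mean(axis=0), expected, atol=1e-10)

    def test_fixed_fit_rejected(self, small_dataset):
        m = fit_met(small_dataset, ModelSpec(trait="VALUE", genotype_role="fixed"))
        with pytest.raises(ValueError, match="random"):
            genotypic_values(m)


class TestHeritability:
    @pytest.mark.parametrize(
        "s2g,s2i,s2e,expected",
        [(0.0, 1.0, 1.0, 0.0), (1.0, 0.0, 0.0, 1.0),
         (1.0, 1.0, 1.0, 1.0 / (1 + 1 / 6 + 1 / 18))],
    )
    def test_mean_basis_formula(self, s2g, s2i, s2e, expected):
        model = _toy_model(u=[10.0] * 6, g=[0.0] * 18,
                           ge=np.zeros((18, 6)),
                           comps=dict(sigma2_env=1.0, sigma2_block_env=0.5,
                                      sigma2_gen=s2g, sigma2_gei=s2i,
                                      sigma2_resid=s2e))
        assert heritability(model) == pytest.approx(expected, abs=1e-4)


def _toy_model(u, g, ge, comps=None) -> FittedMETModel:
    u = pd.Series(u, index=[f"E{j+1}" for j in range(len(u))])
    g = pd.Series(g, index=[f"G{i+1}" for i in range(len(g))])
    ge = pd.DataFrame(np.asarray(ge, dtype=float), index=g.index, columns=u.index)
    comps = comps or dict(sigma2_env=1.0, sigma2_block_env=0.5, sigma2_gen=1.0,
                          sigma2_gei=0.5, sigma2_resid=1.0)
    return FittedMETModel(
        spec=ModelSpec(trait="T"), mu_hat=float(np.mean(u)), env_means=u, g=g,
        ge=ge, block_effects=pd.Series(dtype=float),
        components=VarianceComponents(**comps), reml_loglik=0.0, converged=True,
        n_iter=1, n_obs=len(u) * len(g) * 3, n_env=len(u), n_gen=len(g),
        n_blocks=3,
    )
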