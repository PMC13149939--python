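"""File I/O, pipeline configuration, and the end-to-end analysis pipeline.

The canonical on-disk form of a trial is a long-format CSV with header
ENV,GEN,BLOCK,TRAIT,VALUE; wide files (one column per trait after the three
design columns) are melted on read.  ``run_pipeline`` chains the stages —
REML fits, likelihood-ratio and ANOVA reports, the GEI decomposition,
WAASB/WAASBY stability tables, the MTSI with selection gains, and the
genotypic-value indices — and writes every table plus a JSON manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gvalues as gv_mod
from . import lmm, mtsi as mtsi_mod, waasb as waasb_mod
from .simulate import METDataset, SimulationConfig, rice_trial_config, simulate_met

__all__ = [
    "PipelineConfig",
    "read_met_csv",
    "write_met_csv",
    "load_simulation_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_LONG_COLS = ["ENV", "GEN", "BLOCK", "TRAIT", "VALUE"]


def read_met_csv(path) -> METDataset:
    """Read a trial CSV; long format is canonical, wide is auto-melted."""
    df = pd.read_csv(path)
    df.columns = [str(c).upper() for c in df.columns]
    design = ["ENV", "GEN", "BLOCK"]
    missing = [c for c in design if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if "TRAIT" in df.columns and "VALUE" in df.columns:
        long_df = df[_LONG_COLS].copy()
    else:
        trait_cols = [c for c in df.columns if c not in design]
        if not trait_cols:
            raise ValueError("no trait columns found")
        long_df = df.melt(id_vars=design, value_vars=trait_cols,
                          var_name="TRAIT", value_name="VALUE")
    vals = pd.to_numeric(long_df["VALUE"], errors="coerce")
    if vals.isna().any():
        bad = (long_df.index[vals.isna()] + 2).tolist()[:10]
        raise ValueError(f"non-numeric VALUE entries at lines {bad}")
    long_df["VALUE"] = vals
    return METDataset(data=long_df.reset_index(drop=True))


def write_met_csv(dataset: METDataset, path) -> None:
    dataset.to_csv(path)


def load_simulation_config(path) -> SimulationConfig:
    """Build a SimulationConfig from a YAML file mirroring its field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "gen_corr" in raw and raw["gen_corr"] is not None:
        raw["gen_corr"] = np.asarray(raw["gen_corr"], dtype=float)
    return SimulationConfig(**raw)


@dataclass
class PipelineConfig:
    """Everything the full pipeline needs.

    Either ``input_path`` (a trial CSV) or ``simulation`` (a generator
    config) provides the data.  ``directions`` maps each analyzed trait to
    'higher' or 'lower'; traits default to the dataset's trait list.
    """

    input_path: str | None = None
    simulation: SimulationConfig | None = None
    traits: list[str] | None = None
    directions: dict[str, str] = dc_field(default_factory=dict)
    yield_trait: str | None = None
    theta_y: float = 50.0
    theta_s: float = 50.0
    n_axes: int | str = "all"
    intensity: float = 15.0
    outdir: str = "metsel_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.intensity <= 100:
            raise ValueError("intensity must be in (0, 100]")


def _load_data(config: PipelineConfig) -> METDataset:
    if config.input_path is not None:
        return read_met_csv(config.input_path)
    sim = config.simulation or rice_trial_config(seed=config.seed)
    if config.simulation is None and config.seed is not None:
        sim.seed = config.seed
    return simulate_met(sim)


def _resolve_directions(config: PipelineConfig, traits: list[str],
                        data: METDataset) -> dict[str, str]:
    directions = dict(config.directions)
    if not directions and config.simulation is None and config.input_path is None:
        sim = rice_trial_config()
        directions = dict(zip(sim.trait_names, sim.trait_directions))
    elif not directions and config.simulation is not None:
        directions = dict(zip(config.simulation.trait_names,
                              config.simulation.trait_directions))
    for t in traits:
        directions.setdefault(t, "higher")
        if directions[t] not in ("higher", "lower"):
            raise ValueError(f"unknown direction {directions[t]!r} for trait {t!r}")
    return directions


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full stability-selection pipeline and write all outputs.

    Returns the manifest (also written to ``manifest.json``): the list of
    output files, the settings used, and decisions taken along the way
    (variance components clipped at zero, tie-breaks, parameterizations).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "settings": {
            "theta_y": config.theta_y,
            "theta_s": config.theta_s,
            "n_axes": str(config.n_axes),
            "intensity": config.intensity,
            "seed": config.seed,
        },
        "outputs": [],
        "notes": [],
        "status": "incomplete",
    }

    def emit(name: str, obj) -> None:
        path = outdir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path)
        else:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2, default=_json_default)
        manifest["outputs"].append(name)

    try:
        data = _load_data(config)
        traits = config.traits or data.traits
        directions = _resolve_directions(config, traits, data)
        unknown = [t for t in traits if t not in data.traits]
        if unknown:
            raise ValueError(f"traits not in dataset: {unknown}")
        if data.truth is not None:
            emit("dataset.csv", data.data.set_index("ENV"))

        fits: dict[str, lmm.FittedMETModel] = {}
        stab: dict[str, pd.DataFrame] = {}
        comp_rows, test_rows = [], []
        for t in traits:
            spec = lmm.ModelSpec(trait=t, genotype_role="random")
            model = lmm.fit_met(data, spec)
            fits[t] = model
            if not model.converged:
                manifest["notes"].append(f"REML not converged for trait {t}")
            comp = model.components.as_dict()
            shares = model.components.phen_shares()
            row = {"TRAIT": t, **comp, "sigma2_phen": model.components.sigma2_phen}
            row.update({f"share_{k}": v for k, v in shares.items()})
            comp_rows.append(row)

            for term in ("ENV", "GEI"):
                r = lmm.lrt_random_term(data, spec, term)
                test_rows.append({"TRAIT": t, "TEST": f"LRT_{term}",
                                  "STAT": r.chi2, "DF": r.df, "P": r.p_value})
            an = lmm.anova_genotype(
                data, lmm.ModelSpec(trait=t, genotype_role="fixed"))
            test_rows.append({"TRAIT": t, "TEST": "ANOVA_GEN_F",
                              "STAT": float(an["F"].iloc[0]),
                              "DF": int(an["num_df"].iloc[0]),
                              "P": float(an["p_value"].iloc[0])})

            stab[t] = waasb_mod.stability_table(
                model, n_axes=config.n_axes, theta_y=config.theta_y,
                theta_s=config.theta_s, direction=directions[t])
            emit(f"stability_{t}.csv", stab[t])

        emit("variance_components.csv", pd.DataFrame(comp_rows).set_index("TRAIT"))
        emit("significance_tests.csv", pd.DataFrame(test_rows).set_index("TRAIT"))
        manifest["notes"].append(
            "indices use the genotype-random fit; the significance report "
            "uses the genotype-fixed fit")

        yield_trait = config.yield_trait or ("GY" if "GY" in traits else traits[-1])
        ymodel = fits[yield_trait]
        decomp = waasb_mod.gei_svd(ymodel.ge)
        emit("ipca_decomposition.json", {
            "trait": yield_trait,
            "singular_values": decomp.singular_values.tolist(),
            "explained_pct": (100 * decomp.explained).tolist(),
            "gen_scores": decomp.gen_scores.round(10).to_dict(),
            "env_scores": decomp.env_scores.round(10).to_dict(),
        })
        env_waasb = waasb_mod.waasb_scores(decomp, n_axes=config.n_axes,
                                           margin="env")
        emit("environment_waasb.csv", pd.DataFrame({
            "MEAN": data.trait_frame(yield_trait).groupby(
                "ENV", sort=False)["VALUE"].mean(),
            "WAASB": env_waasb,
            "QUADRANT": waasb_mod.quadrant_classify(ymodel.env_means, env_waasb),
        }).rename_axis("ENV"))
        emit("weight_grid_ranks.csv", waasb_mod.rank_across_weights(
            stab[yield_trait]["MEAN"], stab[yield_trait]["WAASB"],
            direction=directions[yield_trait]))

        h2 = {t: lmm.heritability(fits[t]) for t in traits}
        emit("model_dump.json", {
            t: {
                "mu_hat": fits[t].mu_hat,
                "env_means": fits[t].env_means.to_dict(),
                "g": fits[t].g.to_dict(),
                "components": fits[t].components.as_dict(),
                "reml_loglik": fits[t].reml_loglik,
                "heritability_mean_basis": h2[t],
                "converged": fits[t].converged,
            }
            for t in traits
        })

        if len(traits) >= 2:
            index_m = mtsi_mod.build_index_matrix(
                stab, directions, theta_y=config.theta_y, theta_s=config.theta_s)
            fa = mtsi_mod.factor_analysis(index_m)
            if not fa.rotation_converged:
                manifest["notes"].append("varimax rotation hit iteration cap")
            emit("fa_eigenvalues.csv", pd.DataFrame({
                "EIGENVALUE": fa.eigenvalues,
                "EXPLAINED_PCT": 100 * fa.eigenvalues / fa.eigenvalues.sum(),
                "CUMULATIVE_PCT": 100 * np.cumsum(fa.eigenvalues)
                / fa.eigenvalues.sum(),
            }, index=pd.RangeIndex(1, len(fa.eigenvalues) + 1, name="PC")))
            emit("fa_loadings.csv",
                 fa.loadings.assign(COMMUNALITY=fa.communalities).rename_axis("TRAIT"))
            ideo = mtsi_mod.ideotype_scores(fa)
            res = mtsi_mod.mtsi_scores(fa, ideo, intensity=config.intensity)
            emit("mtsi_ranking.csv", res.table)
            emit("mtsi_factor_contributions.csv", res.contributions)
            mean_perf = pd.DataFrame({t: stab[t]["MEAN"] for t in traits})
            gains = mtsi_mod.selection_gains(mean_perf, index_m, res.selected, h2)
            emit("selection_gains.csv", gains.set_index("TRAIT"))
            manifest["mtsi_selected"] = list(res.selected)
            manifest["mtsi_cutoff"] = res.cutoff

        gvmat = lmm.genotypic_values(ymodel)
        if (gvmat.to_numpy() > 0).all():
            gtab = gv_mod.genotypic_value_table(gvmat, ymodel.env_means)
            emit("genotypic_values.csv", gtab)
            emit("genotypic_values_meta.json",
                 {"trait": yield_trait, "mu": gtab.attrs["mu"],
                  "n_env": gtab.attrs["n_env"]})
        else:
            manifest["notes"].append(
                f"non-positive genotypic values for {yield_trait}: harmonic "
                "indices skipped (shift the trait explicitly to enable them)")

        manifest["status"] = "success"
    except Exception as exc:  # partial outputs stay; manifest marks the failure
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=_json_default)
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
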