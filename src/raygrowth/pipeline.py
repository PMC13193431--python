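"""End-to-end age-and-growth pipeline.

Chains the stages in analysis order — synthetic data (or a user ageing
table) → reading precision → edge periodicity → DW–VR regression and
ANCOVA pooling → BPH back-calculation → Bayesian growth fits per family and
sex → model comparison → sex contrasts → longevity — and writes a report
bundle of CSV/JSON tables plus a machine-readable run manifest (seed,
config hash, package version). A stage failure halts only the stages that
depend on it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .backcalc import ancova_sex, back_calculate_all, fit_dw_vr, summarize_by_age
from .growth import (MCMCSettings, build_growth_input, compare_models,
                     fit_growth_bayes, sex_difference)
from .io import RunConfig, write_ageing_csv
from .lifehistory import comparative_stats, longevity_report
from .periodicity import aggregate_edges, select_edge_model
from .precision import adjudicate_reads, age_bias, precision_report
from .simulate import SimulationConfig, simulate_double_reads, simulate_population

logger = logging.getLogger(__name__)


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return None if np.isnan(o) else float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns {stage: result/path} report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"failures": {}}
    manifest = {"seed": config.seed, "config_hash": config.config_hash(),
                "version": __version__, "config": asdict(config)}

    # --- input: simulate or load -------------------------------------------
    df = None
    if "simulate" in config.stages or config.input_csv is None:
        sim_cfg = SimulationConfig(n_fish=config.n_fish, seed=config.seed)
        ds = simulate_double_reads(simulate_population(sim_cfg))
        df = ds.data
        write_ageing_csv(df, outdir / "specimens.csv")
        report["simulate"] = str(outdir / "specimens.csv")
    else:
        from .io import read_ageing_csv
        df, quarantine = read_ageing_csv(config.input_csv)
        if len(quarantine):
            quarantine.to_csv(outdir / "quarantine.csv", index=False)
        report["input"] = config.input_csv

    # accepted age per fish (read-3 adjudication when available)
    aged = adjudicate_reads(df) if "read2" in df.columns else df.assign(
        age=df["read1"])

    # --- precision ----------------------------------------------------------
    if "precision" in config.stages and "read2" in df.columns:
        try:
            rep = precision_report(df[["read1", "read2"]])
            _dump(rep.to_dict(), outdir / "precision.json")
            age_bias(df[["read1", "read2"]]).to_csv(
                outdir / "age_bias.csv", index=False)
            report["precision"] = rep.to_dict()
        except Exception as e:  # independent stage: record and continue
            logger.exception("precision stage failed")
            report["failures"]["precision"] = str(e)

    # --- edge periodicity ---------------------------------------------------
    if "edges" in config.stages:
        try:
            table = aggregate_edges(df)
            comp = select_edge_model(table)
            table.to_frame().to_csv(outdir / "edge_monthly.csv", index=False)
            comp.table.to_csv(outdir / "edge_comparison.csv", index=False)
            _dump({"best": comp.best,
                   "fits": {h: f.params for h, f in comp.fits.items()}},
                  outdir / "edge_models.json")
            report["edges"] = comp.best
        except Exception as e:
            logger.exception("edge stage failed")
            report["failures"]["edges"] = str(e)

    # --- back-calculation (required by growth) ------------------------------
    pairs = None
    if "backcalc" in config.stages:
        try:
            fit = fit_dw_vr(df)
            anc = ancova_sex(df, alpha=config.alpha)
            _dump({"a": fit.a, "b": fit.b, "r2": fit.r2, "n": fit.n,
                   "residual_sd": fit.residual_sd}, outdir / "dw_vr.json")
            _dump(asdict(anc), outdir / "ancova.json")
            pairs = back_calculate_all(aged, fit)
            pairs.to_csv(outdir / "backcalc_pairs.csv", index=False)
            summarize_by_age(pairs, aged).to_csv(
                outdir / "age_summary.csv", index=False)
            report["backcalc"] = {"a": fit.a, "b": fit.b, "r2": fit.r2,
                                  "pooled": anc.pooled}
        except Exception as e:
            logger.exception("back-calculation stage failed")
            report["failures"]["backcalc"] = str(e)

    # --- growth fits, comparison, contrasts ---------------------------------
    fits_by_sex: dict[str, dict] = {}
    if "growth" in config.stages and pairs is not None:
        settings = MCMCSettings(n_chains=config.n_chains,
                                n_warmup=config.n_warmup,
                                n_samples=config.n_samples)
        post_rows, contrast_rows = [], []
        comp_frames: dict[str, pd.DataFrame] = {}
        for sex in sorted(pairs["sex"].unique()):
            t, dw = build_growth_input(pairs, sex)
            fits = {}
            for fam in config.families:
                try:
                    fr = fit_growth_bayes(t, dw, fam, settings=settings,
                                          seed=config.seed, sex=sex)
                    fits[fam] = fr
                    s = fr.posterior.summary()
                    s.insert(0, "sex", sex)
                    s.insert(1, "family", fam)
                    post_rows.append(s)
                except Exception as e:
                    logger.exception("growth fit failed: %s %s", sex, fam)
                    report["failures"][f"growth:{sex}:{fam}"] = str(e)
            fits_by_sex[sex] = fits
            if len(fits) >= 2:
                comp_frames[sex] = compare_models(list(fits.values()))
        if post_rows:
            pd.concat(post_rows, ignore_index=True).to_csv(
                outdir / "growth_posteriors.csv", index=False)
        if comp_frames:
            comp_all = pd.concat(comp_frames.values(), ignore_index=True)
            comp_all.to_csv(outdir / "model_comparison.csv", index=False)
            report["growth"] = {sex: c.loc[0, "family"]
                                for sex, c in comp_frames.items()}
        if {"F", "M"} <= set(fits_by_sex):
            for fam in config.families:
                if fam in fits_by_sex["F"] and fam in fits_by_sex["M"]:
                    for c in sex_difference(fits_by_sex["F"][fam],
                                            fits_by_sex["M"][fam],
                                            level=config.contrast_level,
                                            seed=config.seed):
                        contrast_rows.append({"family": fam, **asdict(c),
                                              "significant": c.significant})
            if contrast_rows:
                pd.DataFrame(contrast_rows).to_csv(
                    outdir / "sex_contrasts.csv", index=False)

    # --- longevity -----------------------------------------------------------
    if "longevity" in config.stages and fits_by_sex:
        try:
            k_by_sex, obs_max = {}, {}
            for sex, fits in fits_by_sex.items():
                if "logistic" in fits:
                    k_by_sex[sex] = fits["logistic"].posterior.mean("k")
                    obs_max[sex] = float(aged.loc[aged["sex"] == sex, "age"].max())
            if k_by_sex:
                res = [r.to_dict() for r in longevity_report(k_by_sex, obs_max)]
                _dump(res, outdir / "longevity.json")
                report["longevity"] = res
        except Exception as e:
            logger.exception("longevity stage failed")
            report["failures"]["longevity"] = str(e)

    # --- cross-species comparison -------------------------------------------
    if "comparative" in config.stages:
        try:
            cs = comparative_stats()
            _dump(cs.to_dict(), outdir / "comparative.json")
            report["comparative"] = cs.to_dict()
        except Exception as e:
            logger.exception("comparative stage failed")
            report["failures"]["comparative"] = str(e)

    _dump(manifest, outdir / "manifest.json")
    report["manifest"] = str(outdir / "manifest.json")
    return report
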