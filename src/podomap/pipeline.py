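"""End-to-end pipeline: simulate → extract → background → sdm → geostat →
burden → report, with a hash manifest for reproducibility.

Each stage reads its inputs from, and writes its outputs to, the run
directory, so stages are independently re-runnable.  The manifest records
per stage the SHA-256 of every input and output file, the derived stage
seed and the wall time; identical config + seed ⇒ identical hashes for
the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import background as bg
from . import burden as bd
from . import geostat as gs
from . import rasterops as ro
from . import sdm
from . import surveys as sv
from . import synthdata as syn
from .config import PipelineConfig, stage_rng, stage_seed
from .raster import RasterStack, read_ascii_grid

__all__ = ["run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "background", "sdm", "geostat", "burden", "report")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _world_config(cfg: PipelineConfig) -> syn.SyntheticWorldConfig:
    return syn.SyntheticWorldConfig(
        grid_shape=cfg.grid_shape,
        cell_size=cfg.cell_size,
        n_covariates=cfg.n_covariates,
        covariate_ranges=cfg.covariate_ranges,
        beta=cfg.beta,
        sigma2=cfg.sigma2,
        phi=cfg.phi,
        tau2=cfg.tau2,
        n_communities=cfg.n_communities,
        oversample_region=cfg.oversample_region,
        oversample_fraction=cfg.oversample_fraction,
        n_per_community_range=cfg.n_per_community_range,
        suitability_floor=cfg.suitability_floor,
        seed=stage_seed(cfg.seed, "simulate"),
        north=cfg.grid_shape[0] * cfg.cell_size,
    )


# ------------------------------------------------------------------- stages
def _stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    wc = _world_config(cfg)
    stack = syn.generate_covariates(wc)
    truth = syn.generate_truth(stack, wc)
    surveys = syn.simulate_surveys(truth, wc)
    pop = syn.generate_population(wc, total_population=cfg.total_population)
    admin = syn.generate_admin(wc)

    stack.write_dir(out / "covariates")
    truth.prevalence.write_ascii(out / "truth_prevalence.asc")
    truth.suitability.write_ascii(out / "truth_suitability.asc")
    sv.save_surveys(surveys, out / "surveys.csv")
    pop.write_ascii(out / "population.asc")
    bd.write_admin_geojson(admin, out / "admin.geojson")
    return {
        "outputs": [
            "covariates", "truth_prevalence.asc", "truth_suitability.asc",
            "surveys.csv", "population.asc", "admin.geojson",
        ]
    }


def _stage_extract(cfg: PipelineConfig, out: Path) -> dict:
    stack = RasterStack.read_dir(out / "covariates")
    surveys = sv.load_surveys(out / "surveys.csv")
    features = ro.extract_features(stack, surveys)
    features.to_csv(out / "features.csv", index=False)
    meta = {
        "covariates": features.attrs["covariates"],
        "n_dropped_outside": features.attrs["n_dropped_outside"],
        "n_dropped_nodata": features.attrs["n_dropped_nodata"],
    }
    (out / "features_meta.json").write_text(json.dumps(meta, indent=2))
    log.info(
        "extract: %d communities, %d zero-case (%.1f%%), %d dropped",
        len(features),
        int((features["n_cases"] == 0).sum()),
        100.0 * (features["n_cases"] == 0).mean(),
        meta["n_dropped_outside"] + meta["n_dropped_nodata"],
    )
    return {"inputs": ["covariates", "surveys.csv"],
            "outputs": ["features.csv", "features_meta.json"]}


def _stage_background(cfg: PipelineConfig, out: Path) -> dict:
    stack = RasterStack.read_dir(out / "covariates")
    features = pd.read_csv(out / "features.csv")
    covs = json.loads((out / "features_meta.json").read_text())["covariates"]
    rng = stage_rng(cfg.seed, "background")

    occ = features.loc[features["label"] == 1, ["x_km", "y_km"]].to_numpy()
    bias = bg.build_bias_surface(occ, stack.grid, bandwidth=cfg.kde_bandwidth)
    bias.grid.write_ascii(out / "bias.asc")

    xmin, ymin, xmax, ymax = cfg.oversample_region
    x = features["x_km"].to_numpy()
    y = features["y_km"].to_numpy()
    in_region = (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)
    thinned = bg.subsample_positives(features, in_region, cfg.positive_fraction, rng)

    pts = bg.sample_background(bias, cfg.n_background, rng)
    bg_surveys = pd.DataFrame(
        {
            "community_id": [f"bg{i:04d}" for i in range(len(pts))],
            "x_km": pts[:, 0],
            "y_km": pts[:, 1],
            "n_screened": 0,
            "n_cases": 0,
        }
    )
    bg_features = ro.extract_features(stack, bg_surveys)
    weighted = bg.assign_weights(
        thinned[thinned["label"] == 1],
        thinned[thinned["label"] == 0],
        bg_features,
    )
    weighted.to_csv(out / "weighted.csv", index=False)
    log.info(
        "background: %d presences, %d absences, %d background points "
        "(non-presence weight %.4f)",
        int((weighted["record"] == "presence").sum()),
        int((weighted["record"] == "absence").sum()),
        int((weighted["record"] == "background").sum()),
        float(weighted.loc[weighted["record"] != "presence", "weight"].iloc[0]),
    )
    return {"inputs": ["features.csv", "covariates"],
            "outputs": ["bias.asc", "weighted.csv"]}


def _stage_sdm(cfg: PipelineConfig, out: Path) -> dict:
    stack = RasterStack.read_dir(out / "covariates")
    weighted = pd.read_csv(out / "weighted.csv")
    covs = json.loads((out / "features_meta.json").read_text())["covariates"]
    result = sdm.run_ensemble(
        weighted,
        stack,
        covs,
        n_reps=cfg.n_reps,
        train_frac=cfg.train_frac,
        auc_min=cfg.auc_min,
        tss_min=cfg.tss_min,
        seed=stage_seed(cfg.seed, "sdm"),
        algorithms=cfg.algorithms,
        brt_max_trees=cfg.brt_max_trees,
        rf_trees=cfg.rf_trees,
    )
    result.mean_suitability.write_ascii(out / "suitability_mean.asc")
    result.ci_low.write_ascii(out / "suitability_lo.asc")
    result.ci_high.write_ascii(out / "suitability_hi.asc")
    result.limits.write_ascii(out / "limits.asc")
    result.metrics_table().to_csv(out / "sdm_runs.csv", index=False)
    (out / "threshold.json").write_text(
        json.dumps(
            {
                "threshold": result.threshold,
                **result.threshold_stats,
                "rep_thresholds": result.rep_thresholds.tolist(),
            },
            indent=2,
        )
    )
    # partial dependence of one full-data fit per algorithm
    X = weighted[covs].to_numpy(float)
    yv = weighted["label"].to_numpy(int)
    w = weighted["weight"].to_numpy(float)
    pd_seed = stage_seed(cfg.seed, "sdm-pd")
    learners = {}
    if "brt" in cfg.algorithms:
        learners["brt"] = sdm.fit_brt(X, yv, w, max_trees=cfg.brt_max_trees, seed=pd_seed)
    if "rf" in cfg.algorithms:
        learners["rf"] = sdm.fit_rf(X, yv, w, n_trees=cfg.rf_trees, seed=pd_seed)
    for j, cov in enumerate(covs):
        vals = np.linspace(X[:, j].min(), X[:, j].max(), 50)
        table = {"value": vals}
        for name, learner in learners.items():
            table[name] = sdm.partial_dependence(learner, X, j, vals)
        pd.DataFrame(table).to_csv(out / f"partial_dependence_{cov}.csv", index=False)
    contrib = pd.DataFrame(
        {"covariate": covs}
        | {name: sdm.variable_contribution(l) for name, l in learners.items()}
    )
    contrib.to_csv(out / "variable_contribution.csv", index=False)
    return {"inputs": ["weighted.csv", "covariates"],
            "outputs": ["suitability_mean.asc", "limits.asc", "sdm_runs.csv",
                        "threshold.json", "variable_contribution.csv"]}


def _stage_geostat(cfg: PipelineConfig, out: Path) -> dict:
    stack = RasterStack.read_dir(out / "covariates")
    features = pd.read_csv(out / "features.csv")
    covs = json.loads((out / "features_meta.json").read_text())["covariates"]
    limits = read_ascii_grid(out / "limits.asc")
    model = gs.fit(
        features,
        covs,
        method=cfg.geostat_method,
        n_mc=cfg.geostat_mc,
        seed=stage_seed(cfg.seed, "geostat"),
    )
    pred = gs.predict(
        model,
        stack,
        limits,
        threshold=cfg.exceedance_threshold,
        n_samples=cfg.n_samples,
        seed=stage_seed(cfg.seed, "geostat-predict"),
    )
    pred.mean.write_ascii(out / "prevalence_mean.asc")
    pred.ci_low.write_ascii(out / "prevalence_lo.asc")
    pred.ci_high.write_ascii(out / "prevalence_hi.asc")
    pred.exceedance.write_ascii(out / "exceedance.asc")
    pred.se.write_ascii(out / "prevalence_se.asc")
    if model.se is not None:
        model.se.to_csv(out / "geostat_params.csv", index=False)
    report = gs.variogram_validation(
        model, n_mc=max(100, cfg.geostat_mc), seed=stage_seed(cfg.seed, "variogram")
    )
    report.to_csv(out / "variogram.csv")
    _plot_variogram(report, out / "variogram.png")
    (out / "geostat_fit.json").write_text(
        json.dumps(
            {
                "params": model.params(),
                "loglik": model.loglik,
                "method": model.method,
                "variogram_pass": report.passed,
                "variogram_fraction_inside": report.fraction_inside,
            },
            indent=2,
        )
    )
    return {"inputs": ["features.csv", "covariates", "limits.asc"],
            "outputs": ["prevalence_mean.asc", "exceedance.asc",
                        "geostat_params.csv", "variogram.csv", "geostat_fit.json"]}


def _plot_variogram(report: gs.VariogramReport, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    v = report.vario
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.fill_between(v["dist"], v["env_lo"], v["env_hi"], alpha=0.3,
                    label="95% Monte-Carlo envelope")
    ax.plot(v["dist"], v["gamma"], "o-", label="empirical")
    ax.set_xlabel("distance (km)")
    ax.set_ylabel("semivariance")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _stage_burden(cfg: PipelineConfig, out: Path) -> dict:
    pop = read_ascii_grid(out / "population.asc")
    limits = read_ascii_grid(out / "limits.asc")
    mean = read_ascii_grid(out / "prevalence_mean.asc")
    lo = read_ascii_grid(out / "prevalence_lo.asc")
    hi = read_ascii_grid(out / "prevalence_hi.asc")
    admin = bd.read_admin_geojson(out / "admin.geojson")

    adults = bd.adult_population(pop, cfg.adult_fraction)
    par = bd.population_at_risk(adults, limits)
    cases = {
        "cases_mean": mean.copy_with(mean.data * adults.data),
        "cases_low": lo.copy_with(lo.data * adults.data),
        "cases_high": hi.copy_with(hi.data * adults.data),
    }
    table = bd.aggregate(
        {"population_at_risk": par, **cases, "adults": adults}, admin
    )
    table.to_csv(out / "burden.csv", index=False)
    summary = bd.summarize_endemicity(table)
    (out / "endemicity.json").write_text(json.dumps(summary, indent=2))
    return {"inputs": ["population.asc", "limits.asc", "prevalence_mean.asc",
                       "admin.geojson"],
            "outputs": ["burden.csv", "endemicity.json"]}


def _stage_report(cfg: PipelineConfig, out: Path) -> dict:
    surveys = sv.load_surveys(out / "surveys.csv")
    summary = sv.summarize_surveys(surveys).as_dict()
    burden_table = pd.read_csv(out / "burden.csv")
    report = {
        "survey_summary": summary,
        "burden_total_cases": float(burden_table["cases_mean"].sum()),
        "population_at_risk": float(burden_table["population_at_risk"].sum()),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    log.info(
        "report: %d communities, %d zero-case clusters (%.1f%%), "
        "prevalence %.2f%%",
        summary["n_clusters"], summary["zero_case_clusters"],
        summary["zero_case_share_pct"], summary["prevalence_pct"],
    )
    return {"inputs": ["surveys.csv", "burden.csv"], "outputs": ["report.json"]}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "extract": _stage_extract,
    "background": _stage_background,
    "sdm": _stage_sdm,
    "geostat": _stage_geostat,
    "burden": _stage_burden,
    "report": _stage_report,
}


def _hash_entry(out: Path, rel: str) -> dict:
    p = out / rel
    if p.is_dir():
        return {f: _sha256(p / f) for f in sorted(x.name for x in p.iterdir())}
    if p.suffix == ".png":  # binary artefact, hash only
        return {rel: _sha256(p)}
    return {rel: _sha256(p)}


def run_pipeline(
    cfg: PipelineConfig, stages: tuple[str, ...] = STAGES
) -> dict:
    """Run the requested stages in order, fail fast, write the manifest.

    Returns the manifest dict.  On stage failure the manifest (including
    the failure record) is still written before the exception propagates.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.as_dict(), "stages": {}}
    manifest_path = out / "manifest.json"
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.perf_counter()
        log.info("stage %s: start (seed %d)", stage, stage_seed(cfg.seed, stage))
        try:
            io_info = _STAGE_FUNCS[stage](cfg, out)
        except Exception as exc:
            manifest["stages"][stage] = {
                "status": "failed", "error": f"{type(exc).__name__}: {exc}",
                "seed": stage_seed(cfg.seed, stage),
            }
            manifest_path.write_text(json.dumps(manifest, indent=2))
            raise
        entry = {
            "status": "ok",
            "seed": stage_seed(cfg.seed, stage),
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "inputs": {},
            "outputs": {},
        }
        for rel in io_info.get("inputs", []):
            entry["inputs"].update(_hash_entry(out, rel))
        for rel in io_info.get("outputs", []):
            entry["outputs"].update(_hash_entry(out, rel))
        manifest["stages"][stage] = entry
        manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
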