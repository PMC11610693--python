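"""End-to-end orchestration: simulate → rate sums → covariates → fit → validate → hindcast.

Each stage writes its artifacts under the configured output directory and is
recorded in a run manifest (stage name, status, outputs with SHA-256 hashes,
wall time).  All randomness derives from the single top-level seed through
:class:`numpy.random.SeedSequence` spawning, so rerunning a config
reproduces every numeric output.

Real (externally simulated) microclimate can replace the emulator by setting
``sites_csv`` and ``microclimate_csv`` in the config, in which case the
simulate stage is skipped; likewise ``observations_csv`` replaces the
synthetic observation draw.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from . import evaluation, germination, hindcast, synth
from .config import RunConfig, effective_config_dict
from .sdm import fit_abundance, fit_presence, model_diagnostics, partial_effects, predict

logger = logging.getLogger(__name__)

STAGES = ("simulate", "rate_sums", "covariates", "fit", "validate", "hindcast")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, seed: int):
        self.entries = []
        self.seed = seed

    def record(self, stage: str, status: str, outputs, t0: float) -> None:
        self.entries.append(
            {
                "stage": stage,
                "status": status,
                "outputs": {str(p.name): _sha256(p) for p in outputs},
                "wall_time_s": round(time.monotonic() - t0, 3),
            }
        )

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "stages": self.entries}, fh, indent=2)


def stage_seeds(seed: int) -> dict:
    """Deterministic per-stage integer seeds derived from the global seed."""
    ss = np.random.SeedSequence(seed)
    names = ("sites", "microclimate", "observations", "split")
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(names, children)
    }


def run_pipeline(config: RunConfig, output_dir=None) -> dict:
    """Execute all stages; returns the manifest mapping.

    Any stage failure is re-raised with the failing stage named.
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = _Manifest(config.seed)

    with open(out / "config_effective.json", "w") as fh:
        json.dump(effective_config_dict(config), fh, indent=2)

    state: dict = {}
    for stage in STAGES:
        t0 = time.monotonic()
        try:
            status, outputs = _STAGE_FUNCS[stage](config, seeds, out, state)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        manifest.record(stage, status, outputs, t0)
        logger.info("stage %s: %s (%.1fs)", stage, status, time.monotonic() - t0)
    manifest.write(out / "manifest.json")
    with open(out / "manifest.json") as fh:
        return json.load(fh)


def _stage_simulate(config, seeds, out, state):
    if config.sites_csv is not None:
        state["sites"] = synth.read_sites_csv(config.sites_csv)
        if config.microclimate_csv is not None:
            return "skipped", []
    else:
        state["sites"] = synth.generate_sites(
            config.n_sites, config.n_watersheds, seeds["sites"], config.sites
        )
    path = out / "sites.csv"
    synth.write_sites_csv(state["sites"], path)
    return "completed", [path]


def _stage_rate_sums(config, seeds, out, state):
    ref0, ref1 = config.reference_period
    sites = state["sites"]
    monthly_parts = []
    if config.microclimate_csv is not None:
        series = germination.read_microclimate_csv(config.microclimate_csv)
        monthly = germination.monthly_rate_sums(series, config.rate_curve)
    else:
        ss = np.random.SeedSequence(seeds["microclimate"]).spawn(len(sites))
        mc_paths = []
        for i, (_, site) in enumerate(sites.iterrows()):
            site_seed = int(ss[i].generate_state(1)[0] % (2**31 - 1))
            series = synth.simulate_microclimate(
                site, ref0 - 1, ref1, site_seed, config.microclimate
            )
            if config.write_microclimate:
                p = out / f"microclimate_{site['site_id']}.csv"
                series.to_csv(p, index=False)
                mc_paths.append(p)
            monthly_parts.append(germination.monthly_rate_sums(series, config.rate_curve))
        monthly = pd.concat(monthly_parts, ignore_index=True)
    seasonal = germination.seasonal_rate_sums(monthly, range(ref0, ref1 + 1))
    monthly_path, seasonal_path = out / "monthly_rate_sums.csv", out / "seasonal_rate_sums.csv"
    monthly.to_csv(monthly_path, index=False)
    seasonal.to_csv(seasonal_path, index=False)
    state["seasonal"] = seasonal
    return "completed", [monthly_path, seasonal_path]


def _stage_covariates(config, seeds, out, state):
    sites = state["sites"]
    seasonal = state["seasonal"]
    watershed_map = dict(zip(sites["site_id"], sites["watershed_id"]))

    # Blocked split first: scaling constants are frozen on training sites only.
    obs_site_years = _observation_site_years(config, sites, seeds)
    obs_frame = pd.DataFrame(obs_site_years, columns=["site_id", "obs_year"])
    split = evaluation.split_by_watershed(
        obs_frame, watershed_map, config.split.test_fraction, seeds["split"]
    )
    train_sites = [s for s, w in watershed_map.items() if w in split.train_watersheds]
    constants = cov.compute_constants(
        seasonal, spatial_sites=train_sites, provenance="training watersheds"
    )
    all_cov, _ = cov.build_covariates(seasonal, constants=constants)
    state.update(split=split, constants=constants, covariates=all_cov, watershed_map=watershed_map)

    if config.observations_csv is not None:
        observations = pd.read_csv(config.observations_csv)
        observations["presence"] = (
            observations["cover_percent"] > synth.PRESENCE_COVER_THRESHOLD
        )
    else:
        obs_cov = all_cov.merge(obs_frame, on=["site_id", "obs_year"], how="inner")
        observations = synth.simulate_observations(
            obs_cov, config.truth, seeds["observations"]
        )
    state["observations"] = observations

    cov_path = out / "covariates.csv"
    cov.write_covariates_csv(all_cov, cov_path)
    const_path = out / "scaling_constants.yaml"
    constants.to_yaml(const_path)
    split_path = out / "split.csv"
    split.to_frame().to_csv(split_path, index=False)
    obs_path = out / "observations.csv"
    observations.to_csv(obs_path, index=False)
    return "completed", [cov_path, const_path, split_path, obs_path]


def _observation_site_years(config, sites, seeds):
    obs0, obs1 = config.observation_years
    rng = np.random.default_rng(seeds["observations"])
    pool = [(s, y) for s in sites["site_id"] for y in range(obs0, obs1 + 1)]
    n = min(config.n_observations, len(pool))
    chosen = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(chosen)]


def _merged_training_frame(state):
    obs = state["observations"]
    merged = obs.merge(state["covariates"], on=["site_id", "obs_year"], how="left")
    ws = merged["site_id"].map(state["watershed_map"])
    merged["partition"] = np.where(
        ws.isin(state["split"].test_watersheds), "test", "train"
    )
    return merged


def _stage_fit(config, seeds, out, state):
    merged = _merged_training_frame(state)
    train = merged[merged["partition"] == "train"]
    presence_model = fit_presence(train, train["presence"], config.gam)
    abundance_model = fit_abundance(train, train["cover_percent"], config.gam)
    state.update(presence_model=presence_model, abundance_model=abundance_model, merged=merged)

    outputs = []
    for name, model in (("presence", presence_model), ("abundance", abundance_model)):
        p = out / f"{name}_model.json"
        model.to_json(p)
        outputs.append(p)
    pe_rows = []
    for name, model in (("presence", presence_model), ("abundance", abundance_model)):
        for curve in partial_effects(model):
            pe_rows.append(
                pd.DataFrame(
                    {
                        "model": name,
                        "term": curve.term,
                        "x": curve.grid,
                        "effect": curve.effect,
                        "se": curve.se,
                    }
                )
            )
    pe_path = out / "partial_effects.csv"
    pd.concat(pe_rows, ignore_index=True).to_csv(pe_path, index=False)
    outputs.append(pe_path)

    diag = {
        "presence": model_diagnostics(presence_model, train, train["presence"].astype(float)),
        "abundance": model_diagnostics(abundance_model, train, train["cover_percent"]),
    }
    diag_path = out / "diagnostics.json"
    with open(diag_path, "w") as fh:
        json.dump(diag, fh, indent=2, sort_keys=True)
    outputs.append(diag_path)
    return "completed", outputs


def _stage_validate(config, seeds, out, state):
    merged = state["merged"]
    test = merged[merged["partition"] == "test"]
    pres = predict(state["presence_model"], test, threshold=config.gam.threshold)
    abun = predict(state["abundance_model"], test)
    report = evaluation.classification_metrics(test["presence"], pres["label"])
    try:
        report.r_squared = evaluation.r_squared(test["cover_percent"], abun["cover_pred"])
    except ValueError as err:
        logger.warning("cover R^2 undefined on test set: %s", err)
    preds = pres.assign(
        cover_pred=abun["cover_pred"].to_numpy(),
        cover_pred_clamped=abun["cover_pred_clamped"].to_numpy(),
    )
    pred_path = out / "predictions_test.csv"
    preds.to_csv(pred_path, index=False)
    evaluation.write_metrics(report, out / "metrics.json", out / "metrics.txt")
    state["metrics"] = report
    return "completed", [pred_path, out / "metrics.json", out / "metrics.txt"]


def _stage_hindcast(config, seeds, out, state):
    strata = hindcast.stratify_sites(state["sites"])
    hc0, hc1 = config.hindcast_window
    window_cov = state["covariates"]
    window_cov = window_cov[
        (window_cov["obs_year"] >= hc0) & (window_cov["obs_year"] <= hc1)
    ]
    occ = hindcast.annual_occupancy(
        state["presence_model"],
        window_cov,
        strata,
        threshold=config.hindcast.threshold,
        by=config.hindcast.strata,
    )
    trends = hindcast.trend_estimate(occ)
    strata_path, occ_path, trend_path = (
        out / "strata.csv",
        out / "occupancy.csv",
        out / "trends.csv",
    )
    strata.to_csv(strata_path, index=False)
    occ.to_csv(occ_path, index=False)
    trends.to_csv(trend_path, index=False)
    return "completed", [strata_path, occ_path, trend_path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "rate_sums": _stage_rate_sums,
    "covariates": _stage_covariates,
    "fit": _stage_fit,
    "validate": _stage_validate,
    "hindcast": _stage_hindcast,
}
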