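"""End-to-end driver: simulate/load → covariates → encode → fit → predict.

``run_pipeline`` executes the whole analysis under a validated
:class:`~budburst.io.RunConfig` and writes every intermediate table, the
per-transition selection tables, the prediction tables (crossing DOYs
with the covariate values reached there), budbreak durations, heating
requirements, and a markdown report.  A JSON run log records the seed,
package version, and record counts; repeated runs with the same config
are byte-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .covariates import build_covariate_table, gap_fill
from .io import (RunConfig, read_phenology_csv, read_weather_csv,
                 write_phenology_csv, write_table, write_weather_csv)
from .prediction import budbreak_duration, heating_requirement, predict_crossings
from .selection import coef_significant, two_phase_selection
from .synthetic import default_scenario
from .transitions import (TRANSITIONS, build_transition_datasets, merge_stages,
                          validate_trajectories)

logger = logging.getLogger(__name__)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a bundle of in-memory results.

    See the module docstring for the files written under
    ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "transitions").mkdir(exist_ok=True)
    (out / "selection").mkdir(exist_ok=True)
    log: dict = {"seed": config.seed, "version": __version__, "counts": {}}

    # ---- data ------------------------------------------------------------
    if config.synthetic is not None:
        scenario = default_scenario(config.seed, **config.synthetic)
        weather = scenario.weather
        obs = scenario.observations
        latitudes = scenario.design.latitudes
        covariates, frost_models = scenario.covariates, scenario.frost_models
        standardizer = scenario.standardizer
        truth_rows = scenario.truth.crossings
        write_table(truth_rows, out / "ground_truth.csv")
        log["synthetic"] = {k: v for k, v in (config.synthetic or {}).items()}
    else:
        weather = read_weather_csv(config.inputs["weather"])
        if "reference_weather" in config.inputs:
            reference = read_weather_csv(config.inputs["reference_weather"])
            if "logger" not in weather.columns:
                weather = weather.assign(logger="logger1")
            weather, gap_models = gap_fill(weather, reference)
            log["gap_fill"] = [vars(m) for m in gap_models]
        obs = merge_stages(read_phenology_csv(config.inputs["phenology"]))
        latitudes = config.latitudes
        covariates, frost_models = build_covariate_table(
            weather, latitudes, pool_years=config.frost_pool_years
        )
        from .synthetic import make_standardizer
        standardizer = make_standardizer(covariates)
        truth_rows = None
    write_weather_csv(weather, out / "weather.csv")
    write_phenology_csv(obs, out / "phenology.csv")
    write_table(covariates, out / "covariates.csv")
    log["counts"]["weather_days"] = int(len(weather))
    log["counts"]["observations"] = int(len(obs))

    # ---- validation and encoding -----------------------------------------
    report = validate_trajectories(obs, mode="lenient")
    if report.violations:
        logger.warning("%d invalid buds dropped", len(report.violations))
    obs_clean = report.clean_obs
    log["counts"]["buds"] = int(report.n_buds)
    log["counts"]["invalid_buds"] = len(report.violations)
    datasets = build_transition_datasets(obs_clean, covariates,
                                         mode=config.encoding_mode)
    for tid, d in datasets.items():
        write_table(d, out / "transitions" / f"{tid.replace('->', '_')}.csv")
        log["counts"][f"records[{tid}]"] = int(len(d))

    # ---- selection ---------------------------------------------------------
    fit_options = {} if config.fit_method == "fast" else {"method": "full"}
    reports = {}
    coef_rows = []
    summary_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tid in TRANSITIONS:
            rep = two_phase_selection(
                datasets[tid], standardizer, transition=tid,
                temperature_pool=config.temperature_pool,
                photoperiod_pool=config.photoperiod_pool,
                group_factor=config.group_factor,
                refit_best=config.refit_best, **fit_options,
            )
            reports[tid] = rep
            tbl = rep.temperature.table.assign(transition=tid, phase="temperature")
            ptb = rep.photoperiod.table.assign(transition=tid, phase="photoperiod")
            write_table(tbl, out / "selection" / f"{tid.replace('->', '_')}_temperature.csv")
            write_table(ptb, out / "selection" / f"{tid.replace('->', '_')}_photoperiod.csv")
            summary_rows.append(rep.summary_row())
            for phase, pres in (("temperature", rep.temperature),
                                ("photoperiod", rep.photoperiod)):
                best = pres.best
                for term in best.params.index:
                    se = float(best.bse[term])
                    coef_rows.append({
                        "transition": tid, "phase": phase,
                        "model_id": best.model_id, "term": term,
                        "estimate": float(best.params[term]), "se": se,
                        "significant": coef_significant(
                            float(best.params[term]), se,
                            config.significance_multiplier)
                        if se > 0 else False,
                    })
    summary = pd.DataFrame(summary_rows)
    write_table(summary, out / "selection_summary.csv")
    write_table(pd.DataFrame(coef_rows), out / "coefficients.csv")

    # ---- prediction --------------------------------------------------------
    groups = sorted(
        obs_clean.groupby(["species", "seed_source"]).groups.keys()
    )
    pred_rows = []
    for tid in TRANSITIONS:
        rep = reports[tid]
        for phase, pres in (("temperature", rep.temperature),
                            ("photoperiod", rep.photoperiod)):
            for (site, year), path in covariates.groupby(["site", "year"]):
                for species, seed_source in groups:
                    gl = {"site": site, "species": species,
                          "seed_source": seed_source}
                    cr = predict_crossings(
                        pres.best, path, standardizer, gl,
                        frost_model=frost_models.get(site),
                        threshold=config.threshold, transition=tid,
                    )
                    pred_rows.append({
                        "transition": tid, "phase": phase, "site": site,
                        "year": year, "species": species,
                        "seed_source": seed_source,
                        "model_id": pres.best.model_id,
                        "crossing_doy": cr.crossing_doy,
                        "status": cr.status,
                        "gdd_at_crossing": cr.gdd_at_crossing,
                        "daylength_at_crossing": cr.daylength_at_crossing,
                        "frost_prob_at_crossing": cr.frost_prob_at_crossing,
                    })
    predictions = pd.DataFrame(pred_rows)
    write_table(predictions, out / "predictions.csv")

    # durations and heating requirements from the temperature-phase winners
    dur_rows = []
    temp_pred = predictions[predictions["phase"] == "temperature"]
    for (site, year, species, seed_source), grp in temp_pred.groupby(
            ["site", "year", "species", "seed_source"]):
        first = grp[grp["transition"] == TRANSITIONS[0]]["crossing_doy"]
        last = grp[grp["transition"] == TRANSITIONS[-1]]["crossing_doy"]
        stage5 = grp[grp["transition"] == "4->5"]["crossing_doy"]
        first = None if first.isna().all() else float(first.iloc[0])
        last = None if last.isna().all() else float(last.iloc[0])
        dur, status = budbreak_duration(first, last)
        gdd_path = covariates[(covariates["site"] == site)
                              & (covariates["year"] == year)]
        heat = np.nan
        if len(stage5) and not stage5.isna().all():
            heat = heating_requirement(float(stage5.iloc[0]), gdd_path, "mean")
        dur_rows.append({
            "site": site, "year": year, "species": species,
            "seed_source": seed_source, "onset_doy": first,
            "completion_doy": last, "duration_days": dur, "status": status,
            "heating_requirement_gdd": heat,
        })
    durations = pd.DataFrame(dur_rows)
    write_table(durations, out / "durations.csv")

    # ---- report ------------------------------------------------------------
    _write_report(out / "report.md", summary, predictions, durations)
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return {
        "summary": summary, "predictions": predictions, "durations": durations,
        "reports": reports, "covariates": covariates, "datasets": datasets,
        "standardizer": standardizer, "frost_models": frost_models,
        "truth": truth_rows, "log": log,
    }


def _write_report(path, summary, predictions, durations) -> None:
    lines = ["# Bud-break transition analysis", ""]
    lines.append("## Best models per transition")
    lines.append("")
    lines.append("```\n" + summary.to_string(index=False) + "\n```")
    lines.append("")
    lines.append("## Predicted 0.51-threshold crossings (temperature phase)")
    lines.append("")
    tp = predictions[predictions["phase"] == "temperature"]
    piv = tp.pivot_table(index=["site", "species", "seed_source"],
                         columns="transition", values="crossing_doy",
                         aggfunc="mean")
    lines.append("```\n" + piv.round(1).to_string() + "\n```")
    lines.append("")
    lines.append("## Budbreak duration and heating requirement")
    lines.append("")
    lines.append("```\n" + durations.round(1).to_string(index=False) + "\n```")
    lines.append("")
    Path(path).write_text("\n".join(lines))
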