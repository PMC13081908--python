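"""End-to-end study orchestration: ingest, exclusions, metrics, models.

``run_pipeline`` executes the full analysis from a single config, either on
a directory of event CSVs or on a freshly generated synthetic study, and
returns a bundle of tidy tables: per-session metrics, the sex contrast on
win-stay, per-mouse choice-history regressions, demand-curve fits, the
PCA/classifier phenotyping, power curves, the model sweep, and a run
manifest with per-stage row counts.  A single seed fans out to per-stage
seeds derived by hashing the stage name, so altering one stage never
perturbs another's randomness.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .event_model import Cohort, read_cohort_dir
from .wsls_agent import STUDY_PAIRS, STUDY_W_GRID, estimate_w, model_sweep
from .trial_metrics import (
    STUDY_SCHEDULE, apply_exclusions, combine_pr_metrics, metrics_table,
    parse_trials, pr_runs, win_stay_lose_stay,
)
from .choice_regression import fit_per_mouse, summarize_by_sex
from .demand_model import compare_groups, fit_demand, fits_table, tabulate_demand
from .cohort_analysis import (
    METHODS_FEATURES, RESULTS_FEATURES, build_feature_table, classify_sex,
    pca_with_loadings,
)
from .power_analysis import EffectSpec, analytic_power, empirical_power, required_n
from .synthetic_cohort import generate_study, sample_cohort


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from the run seed and stage name."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    synthetic: bool = True
    input_dir: str | None = None
    out_dir: str | None = None
    seed: int = 0
    n_f: int = 62
    n_m: int = 74
    schedule: tuple = STUDY_SCHEDULE
    min_pellets_per_day: int = 75
    alpha: float = 0.05
    n_resamples: int = 1000
    power_grid: tuple = tuple(range(4, 61, 2))
    regression_lags: int = 5
    cv_folds: int = 5
    feature_set: str = "results4"   # or "methods6"
    run_sweep: bool = True
    sweep_agents: int = 100
    sweep_trials: int = 300
    pr_duration_h: float = 24.0


def _per_mouse_bandit_trials(cohort: Cohort, task: str = "bandit_100_0") -> dict:
    """Pool outcome trials over all days of ``task``, per mouse."""
    out = {}
    for mouse_id in cohort.mouse_table["mouse_id"]:
        frames = [parse_trials(log) for log in cohort.sessions_for(mouse_id, task)]
        if frames:
            pooled = pd.concat(frames, ignore_index=True)
            pooled["index"] = np.arange(len(pooled))
            out[mouse_id] = pooled
    return out


def win_stay_contrast(cohort: Cohort, lapse: float = 0.25,
                      task: str = "bandit_100_0") -> pd.DataFrame:
    """Per-mouse pooled win-stay/lose-stay on a task, plus the estimated w.

    ``w_hat`` inverts the WSLS stay-after-win closed form at the study lapse,
    mapping the parsed stay frequency back to the agent's win-stay scale.
    """
    rows = []
    sexes = dict(zip(cohort.mouse_table["mouse_id"], cohort.mouse_table["sex"]))
    for mouse_id, trials in _per_mouse_bandit_trials(cohort, task).items():
        ws, ls = win_stay_lose_stay(trials)
        acc = float((trials["choice"] == trials["correct_side"]).mean())
        rows.append(
            {
                "mouse_id": mouse_id,
                "sex": sexes[mouse_id],
                "win_stay": ws,
                "lose_stay": ls,
                "accuracy": acc,
                "w_hat": estimate_w(ws, lapse) if np.isfinite(ws) else np.nan,
                "n_trials": len(trials),
            }
        )
    return pd.DataFrame(rows)


def sex_ttest(values: pd.DataFrame, column: str) -> dict:
    """Unpaired two-tailed t-test of a per-mouse metric between sexes."""
    m = values.loc[values["sex"] == "M", column].dropna().to_numpy()
    f = values.loc[values["sex"] == "F", column].dropna().to_numpy()
    t, p = stats.ttest_ind(m, f)
    return {
        "metric": column,
        "mean_M": float(m.mean()),
        "mean_F": float(f.mean()),
        "sd_M": float(m.std(ddof=1)),
        "sd_F": float(f.std(ddof=1)),
        "cohens_d": EffectSpec.from_samples(m, f).cohens_d,
        "t": float(t),
        "p": float(p),
        "n_M": len(m),
        "n_F": len(f),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full study analysis; returns the results bundle."""
    counts = {}
    if config.synthetic:
        specs = sample_cohort(config.n_f, config.n_m, seed=stage_seed(config.seed, "cohort"))
        cohort, ground_truth = generate_study(
            specs, schedule=config.schedule,
            seed=stage_seed(config.seed, "study"),
            pr_duration_h=config.pr_duration_h,
        )
    else:
        if not config.input_dir:
            raise ValueError("input_dir required when synthetic=False")
        cohort = read_cohort_dir(config.input_dir)
        ground_truth = None
    counts["mice_in"] = len(cohort.mouse_table)

    tasks_present = {t for t, _ in config.schedule}
    cohort, exclusions = apply_exclusions(
        cohort, config.min_pellets_per_day, required_schedule=config.schedule
    )
    counts["mice_excluded"] = exclusions["mouse_id"].nunique() if len(exclusions) else 0
    counts["mice_analysed"] = len(cohort.mouse_table)
    if counts["mice_in"] != counts["mice_excluded"] + counts["mice_analysed"]:
        raise RuntimeError("exclusion bookkeeping mismatch")
    if counts["mice_analysed"] == 0:
        raise RuntimeError("no mice left after exclusions")

    results: dict = {"exclusions": exclusions, "ground_truth": ground_truth}
    results["metrics"] = metrics_table(cohort)
    counts["metric_rows"] = len(results["metrics"])

    # --- decision-strategy contrast on the deterministic bandit -------------
    contrast = win_stay_contrast(cohort)
    results["win_stay_by_mouse"] = contrast
    results["win_stay_test"] = pd.DataFrame(
        [sex_ttest(contrast, "win_stay"), sex_ttest(contrast, "accuracy"),
         sex_ttest(contrast, "lose_stay")]
    )

    # --- lag-5 choice-history regression ------------------------------------
    trials_by_mouse = _per_mouse_bandit_trials(cohort)
    sexes = dict(zip(cohort.mouse_table["mouse_id"], cohort.mouse_table["sex"]))
    per_mouse_fits = fit_per_mouse(trials_by_mouse, sexes, K=config.regression_lags)
    results["regression"] = per_mouse_fits
    results["regression_by_sex"] = (
        summarize_by_sex(per_mouse_fits) if len(per_mouse_fits) else pd.DataFrame()
    )

    # --- PR1 demand ----------------------------------------------------------
    if "pr1" in tasks_present:
        pr_by_mouse, demand_fits = {}, {}
        for mouse_id in cohort.mouse_table["mouse_id"]:
            days = [pr_runs(log) for log in cohort.sessions_for(mouse_id, "pr1")]
            if not days:
                continue
            pooled = combine_pr_metrics(days)
            pr_by_mouse[mouse_id] = pooled
            try:
                demand_fits[mouse_id] = fit_demand(tabulate_demand(pooled))
            except ValueError:
                continue
        results["pr_metrics"] = pd.DataFrame(
            [
                {
                    "mouse_id": m.mouse_id, "sex": m.sex, "pellets": m.pellets,
                    "pokes": m.pokes, "accuracy": m.accuracy,
                    "median_breakpoint": m.median_breakpoint, "n_runs": m.n_runs,
                }
                for m in pr_by_mouse.values()
            ]
        )
        results["demand_fits"] = fits_table(demand_fits, sexes)
        clean = results["demand_fits"]
        clean = clean[clean["flags"] == ""]
        results["demand_groups"] = (
            compare_groups(clean) if clean["sex"].nunique() == 2
            and clean.groupby("sex").size().min() >= 2 else pd.DataFrame()
        )
        counts["demand_fits"] = len(results["demand_fits"])

    # --- phenotyping ---------------------------------------------------------
    if {"bandit_100_0", "fr1"} <= tasks_present:
        table = build_feature_table(results["metrics"])
        results["feature_table"] = table.data
        results["cross_task_corr"] = table.cross_task_corr
        pca = pca_with_loadings(table)
        results["pca_loadings"] = pca.loadings
        results["pca_scores"] = pca.scores
        results["pca_explained"] = pd.DataFrame(
            {"component": pca.loadings.columns,
             "explained_variance_ratio": pca.explained_variance_ratio}
        )
        feats = RESULTS_FEATURES if config.feature_set == "results4" else METHODS_FEATURES
        report = classify_sex(
            table, features=feats, n_splits=config.cv_folds,
            seed=stage_seed(config.seed, "classifier"),
        )
        results["classifier_confusion"] = report.confusion
        results["classifier_accuracy"] = report.accuracy
        results["classifier_scheme"] = report.scheme

    # --- power ---------------------------------------------------------------
    ws_m = contrast.loc[contrast["sex"] == "M", "win_stay"].dropna().to_numpy()
    ws_f = contrast.loc[contrast["sex"] == "F", "win_stay"].dropna().to_numpy()
    grid = tuple(n for n in config.power_grid if n <= min(len(ws_m), len(ws_f)))
    if len(grid) >= 2:
        emp = empirical_power(
            ws_m, ws_f, n_grid=grid, n_resamples=config.n_resamples,
            alpha=config.alpha, seed=stage_seed(config.seed, "power"),
        )
        ana = analytic_power(EffectSpec.from_samples(ws_m, ws_f), n_grid=grid,
                             alpha=config.alpha)
        results["power_curves"] = pd.concat([emp.table(), ana.table()], ignore_index=True)
        results["required_n"] = pd.DataFrame(
            [
                {"method": "empirical", "n_80": required_n(emp)[0], "status": required_n(emp)[1]},
                {"method": "analytic", "n_80": required_n(ana)[0], "status": required_n(ana)[1]},
            ]
        )

    # --- model sweep ---------------------------------------------------------
    if config.run_sweep:
        results["sweep"] = model_sweep(
            w_grid=STUDY_W_GRID, pairs=STUDY_PAIRS,
            n_agents=config.sweep_agents, n_trials=config.sweep_trials,
            seed=stage_seed(config.seed, "sweep"),
        )

    results["manifest"] = {
        "config": asdict(config),
        "seed": config.seed,
        "version": __version__,
        "counts": counts,
    }
    if config.out_dir:
        _write_bundle(results, config.out_dir)
    return results


def _write_bundle(results: dict, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(os.path.join(out_dir, f"{name}.csv"),
                       index=name in ("pca_loadings", "classifier_confusion",
                                      "cross_task_corr", "feature_table", "pca_scores"))
    import json

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"not serializable: {type(o)}")

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(results["manifest"], fh, indent=2, default=_default, sort_keys=True)
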