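"""End-to-end orchestration: simulate -> censor -> describe -> fit -> impute -> risk model.

Each stage reads and writes plain CSV in the run's output directory so the
stages stay independently testable and re-runnable; ``manifest.json``
records the seed, the config echo and a SHA-256 hash of every artifact
(no timestamps, so a fixed seed reproduces the manifest byte-for-byte).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import censoring, cohort as cohort_mod, descriptives, imputation, riskmodel, survival
from .config import RunConfig
from .errors import RelapseTrackError

log = logging.getLogger("relapsetrack")


@dataclass
class RunReport:
    """Artifact paths plus headline statistics of one pipeline run."""

    output_dir: str
    paths: dict = field(default_factory=dict)
    headline: dict = field(default_factory=dict)


def _write(df: pd.DataFrame, path: Path, index=False):
    df.to_csv(path, index=index)
    return str(path)


def stage_simulate(config: RunConfig, outdir: Path) -> dict:
    seeds = config.stage_seeds()
    cc = config.cohort
    if cc.seed != seeds["cohort"]:
        cc = cohort_mod.CohortConfig(**{**cc.__dict__, "seed": seeds["cohort"]})
    subjects = cohort_mod.generate_cohort(cc)
    times = cohort_mod.simulate_relapse_times(subjects, cc.relapse_model, seeds["relapse"])
    frame = cohort_mod.cohort_to_frame(subjects)
    paths = {
        "cohort": _write(frame, outdir / "cohort.csv"),
        "true_times": _write(
            pd.DataFrame({"id": frame["id"], "true_day": times}), outdir / "true_times.csv"
        ),
    }
    return {"paths": paths, "n_subjects": len(subjects)}


def stage_censor(config: RunConfig, outdir: Path) -> dict:
    frame = pd.read_csv(outdir / "cohort.csv")
    times = pd.read_csv(outdir / "true_times.csv")["true_day"].to_numpy()
    subjects = cohort_mod.frame_to_cohort(frame)
    outcomes = censoring.censor_cohort(subjects, times, config.schedule, config.study_end_day)
    path = _write(censoring.outcomes_to_frame(outcomes), outdir / "outcomes.csv")
    n_rel = sum(o.status == censoring.RELAPSE for o in outcomes)
    return {"paths": {"outcomes": path}, "n_relapse": n_rel}


def stage_describe(config: RunConfig, outdir: Path) -> dict:
    frame = pd.read_csv(outdir / "cohort.csv")
    outcomes = censoring.frame_to_outcomes(pd.read_csv(outdir / "outcomes.csv"))
    groups = frame["group"].tolist()

    table1 = descriptives.baseline_table(frame)
    table2 = descriptives.relapse_rate_table(outcomes, groups)
    table3 = censoring.tabulate_relapse_windows(outcomes, groups, config.schedule)
    paths = {
        "table1": _write(table1, outdir / "table1.csv"),
        "table2": _write(table2.reset_index(), outdir / "table2.csv"),
        "table3": _write(table3.reset_index(names="window"), outdir / "table3.csv"),
    }
    return {
        "paths": paths,
        "relapse_rate_pct": float(table2.loc["overall", "relapse_pct"]),
        "relapse_chi2": float(table2.attrs.get("chi2", float("nan"))),
    }


def stage_fit(config: RunConfig, outdir: Path) -> dict:
    frame = pd.read_csv(outdir / "cohort.csv")
    outcomes = censoring.frame_to_outcomes(pd.read_csv(outdir / "outcomes.csv"))
    socrates = frame["socrates_total"].to_numpy(dtype=float)
    groups = frame["group"].tolist()
    seeds = config.stage_seeds()
    mcmc = survival.McmcConfig(**{**config.mcmc.__dict__, "seed": seeds["mcmc"]})

    total = survival.fit_interval_weibull(outcomes, socrates, None, config.model, mcmc)
    grouped = survival.fit_interval_weibull(outcomes, socrates, groups, config.model, mcmc)

    table4 = survival.table4_frame(total, grouped)
    rows = {"motivation_effect": survival.motivation_effect(total).as_dict()} if config.model.include_motivation else {}
    effect = pd.DataFrame(rows).T
    paths = {
        "table4": _write(pd.concat([table4, effect]).reset_index(names="quantity"), outdir / "table4.csv"),
    }
    # Persist the grouped fit's latent times for the imputation stage.
    np.savez_compressed(
        outdir / "posterior_grouped.npz",
        shape=grouped.shape, alpha=grouped.alpha, slope=grouped.slope,
        latent=grouped.latent, group_idx=grouped.group_idx,
        motivation=grouped.motivation, region_lo=grouped.region_lo,
        region_hi=grouped.region_hi, group_labels=np.array(grouped.group_labels),
    )
    return {
        "paths": paths,
        "mean_survival_days": float(table4.loc["total", "mean"]),
        "converged": bool(total.converged and grouped.converged),
        "_grouped_draws": grouped,
    }


def _load_grouped(outdir: Path, config: RunConfig) -> survival.PosteriorDraws:
    z = np.load(outdir / "posterior_grouped.npz", allow_pickle=False)
    return survival.PosteriorDraws(
        shape=z["shape"], alpha=z["alpha"], slope=z["slope"], latent=z["latent"],
        group_labels=[str(g) for g in z["group_labels"]], group_idx=z["group_idx"],
        motivation=z["motivation"], region_lo=z["region_lo"], region_hi=z["region_hi"],
        spec=config.model, mcmc=config.mcmc,
    )


def stage_impute(config: RunConfig, outdir: Path, draws=None) -> dict:
    outcomes = censoring.frame_to_outcomes(pd.read_csv(outdir / "outcomes.csv"))
    if draws is None:
        draws = _load_grouped(outdir, config)
    sets = imputation.impute_times(draws, outcomes, m=config.imputation_m)
    report = imputation.imputation_report(sets)
    paths = {"imputations": _write(imputation.imputations_to_frame(sets), outdir / "imputations.csv")}
    (outdir / "imputation_summary.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    paths["imputation_summary"] = str(outdir / "imputation_summary.json")
    return {"paths": paths, **report}


def stage_riskmodel(config: RunConfig, outdir: Path) -> dict:
    frame = pd.read_csv(outdir / "cohort.csv")
    combined = pd.read_csv(outdir / "imputations.csv")["combined"].to_numpy()
    labels = riskmodel.discretize_27(combined, config.tail_fraction)
    results, deltas = riskmodel.run_batched_models(frame, labels)
    paths = {"table5": _write(riskmodel.table5_frame(results), outdir / "table5.csv", index=True)}
    detail = {
        f"model_{i + 1}": {
            "chi2": r.model_chi2, "df": r.df_model, "nagelkerke_r2": r.nagelkerke_r2,
            "minus2loglik": r.minus2loglik, "predicted_pct": r.predicted_pct, "n_used": r.n_used,
            "or": {p: float(r.coef.loc[p, "or"]) for p in r.coef.index},
            "se": {p: float(r.coef.loc[p, "se"]) for p in r.coef.index},
        }
        for i, r in enumerate(results)
    }
    detail["deltas"] = [{"delta_chi2": d, "delta_df": f} for d, f in deltas]
    (outdir / "risk_models.json").write_text(json.dumps(detail, indent=2, sort_keys=True))
    paths["risk_models"] = str(outdir / "risk_models.json")
    final = results[-1]
    group_or = {p: float(final.coef.loc[p, "or"]) for p in final.coef.index if p.startswith("group")}
    return {"paths": paths, "final_predicted_pct": final.predicted_pct, **group_or}


_STAGES = ("simulate", "censor", "describe", "fit", "impute", "riskmodel")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order; idempotent under a fixed seed."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(output_dir=str(outdir))
    grouped = None
    for stage in _STAGES:
        fn = globals()[f"stage_{stage}"]
        log.info("stage %s", stage)
        try:
            info = fn(config, outdir, grouped) if stage == "impute" else fn(config, outdir)
        except RelapseTrackError as exc:
            raise RelapseTrackError(f"stage {stage!r} failed: {exc}") from exc
        if stage == "fit":
            grouped = info.pop("_grouped_draws", None)
        report.paths.update(info.pop("paths", {}))
        report.headline.update({f"{stage}.{k}": v for k, v in info.items() if not k.startswith("_")})

    # report.md regenerates purely from stored artifacts.
    lines = ["# Pipeline run report", "", f"seed: {config.seed}", ""]
    for key in sorted(report.headline):
        val = report.headline[key]
        lines.append(f"- {key}: {val:.4f}" if isinstance(val, float) else f"- {key}: {val}")
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
    report.paths["report"] = str(outdir / "report.md")

    manifest = {
        "seed": config.seed,
        "config": config.raw,
        "artifacts": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in sorted(report.paths.items())
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    report.paths["manifest"] = str(outdir / "manifest.json")
    return report
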