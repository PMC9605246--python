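"""Orchestration: cohort → features → strategies → reports.

Drives the full pipeline from an :class:`~fedstress.io.ExperimentConfig` (the
CLI's engine) and provides the seeded multi-strategy comparison experiment
used to study how individual, centralized and federated learning rank on
heterogeneous cohorts.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .cohort import (
    CohortHeterogeneity,
    SensorRecording,
    default_session_plan,
    generate_cohort,
    scaled_session_plan,
)
from .evaluation import EvaluationReport, compare_strategies, evaluate_strategy
from .features import build_feature_matrix
from .io import (
    ExperimentConfig,
    load_cohort,
    read_feature_matrix,
    read_predictions,
    write_cohort,
    write_feature_matrix,
    write_predictions,
)
from .logistic import TrainConfig
from .strategies import (
    FederatedConfig,
    SplitSpec,
    StrategyResult,
    run_centralized,
    run_federated,
    run_individual,
)

log = logging.getLogger("fedstress")

_RUNNERS = {
    "individual": run_individual,
    "centralized": run_centralized,
    "federated": run_federated,
}


def extract_cohort_features(cohort: Sequence[SensorRecording]) -> dict[int, pd.DataFrame]:
    """Per-participant feature matrices, keyed by participant id."""
    out = {}
    for rec in cohort:
        df = build_feature_matrix(rec)
        log.info(
            "participant %d: %d windows, %d stress", rec.participant_id, len(df), df["label"].sum()
        )
        out[rec.participant_id] = df
    return out


def run_strategies(
    matrices: Mapping[int, pd.DataFrame],
    strategies: Sequence[str],
    split: SplitSpec,
    train: TrainConfig,
    federated: FederatedConfig,
) -> dict[str, StrategyResult]:
    results = {}
    for name in strategies:
        if name == "federated":
            results[name] = run_federated(matrices, split, federated)
        else:
            results[name] = _RUNNERS[name](matrices, split, train)
        log.info("strategy %s: evaluated %d participants", name, len(results[name].predictions))
    return results


def comparison_experiment(
    seeds: Sequence[int],
    n_participants: int = 15,
    session_seconds: float = 360.0,
    atypical_fraction: float = 0.2,
    heterogeneity: CohortHeterogeneity | None = None,
    strategies: Sequence[str] = ("individual", "centralized", "federated"),
    split_mode: str = "stratified_random",
    train: TrainConfig | None = None,
    federated: FederatedConfig | None = None,
) -> pd.DataFrame:
    """Mean test metrics per strategy over independently seeded cohorts.

    For each seed a fresh heterogeneous cohort is generated, features are
    extracted once, and all strategies run against identical per-participant
    splits.  Returns one row per (seed, strategy) with the macro-averaged
    Acc/P/R/F1 at full precision.
    """
    plan = scaled_session_plan(session_seconds)
    train = train or TrainConfig()
    rows = []
    for seed in seeds:
        cohort = generate_cohort(
            n_participants,
            heterogeneity=heterogeneity,
            atypical_fraction=atypical_fraction,
            seed=seed,
            plan=plan,
        )
        matrices = extract_cohort_features(cohort)
        split = SplitSpec(mode=split_mode, seed=seed)
        fed = federated or FederatedConfig(seed=seed)
        results = run_strategies(matrices, strategies, split, train, fed)
        for name, result in results.items():
            report = evaluate_strategy(result)
            rows.append(
                {
                    "seed": seed,
                    "strategy": name,
                    "Acc": report.average.acc,
                    "P": report.average.p,
                    "R": report.average.r,
                    "F1": report.average.f1,
                }
            )
    return pd.DataFrame.from_records(rows)


# --------------------------------------------------------------------------
# Config-driven pipeline stages (used by the CLI)
# --------------------------------------------------------------------------


def _cohort_from_config(cfg: ExperimentConfig) -> list[SensorRecording]:
    c = cfg.cohort
    if "manifest" in c:
        return load_cohort(c["manifest"])
    plan = (
        scaled_session_plan(float(c["session_seconds"]))
        if "session_seconds" in c
        else default_session_plan()
    )
    het = CohortHeterogeneity(**c.get("heterogeneity", {}))
    return generate_cohort(
        int(c.get("n_participants", 15)),
        heterogeneity=het,
        atypical_fraction=float(c.get("atypical_fraction", 0.2)),
        seed=cfg.seed,
        plan=plan,
        noise_scales=c.get("noise_scales"),
    )


def stage_simulate(cfg: ExperimentConfig) -> Path:
    out = Path(cfg.output_dir)
    cohort = _cohort_from_config(cfg)
    manifest = write_cohort(cohort, out / "cohort")
    log.info("simulate: wrote %d participants, seed %d -> %s", len(cohort), cfg.seed, manifest)
    return manifest


def stage_extract(cfg: ExperimentConfig) -> dict[int, Path]:
    out = Path(cfg.output_dir)
    cohort = load_cohort(out / "cohort" / "manifest.json")
    fdir = out / "features"
    fdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for pid, df in extract_cohort_features(cohort).items():
        path = fdir / f"participant_{pid:02d}.csv"
        write_feature_matrix(df, path)
        paths[pid] = path
    return paths


def _load_features(cfg: ExperimentConfig) -> dict[int, pd.DataFrame]:
    fdir = Path(cfg.output_dir) / "features"
    matrices = {}
    for path in sorted(fdir.glob("participant_*.csv")):
        df = read_feature_matrix(path)
        matrices[int(df["participant"].iloc[0])] = df
    if not matrices:
        raise FileNotFoundError(f"no feature matrices under {fdir}; run `extract` first")
    return matrices


def stage_run(cfg: ExperimentConfig) -> dict[str, StrategyResult]:
    out = Path(cfg.output_dir)
    matrices = _load_features(cfg)
    split = SplitSpec(**{"seed": cfg.seed, **cfg.split})
    train = TrainConfig(**{"seed": cfg.seed, **cfg.train})
    federated = FederatedConfig(**{"seed": cfg.seed, **cfg.federated}, train=train)
    results = run_strategies(matrices, cfg.strategies, split, train, federated)
    rdir = out / "runs"
    rdir.mkdir(parents=True, exist_ok=True)
    for name, result in results.items():
        write_predictions(result, rdir / f"predictions_{name}.csv")
        mdir = rdir / f"models_{name}"
        mdir.mkdir(exist_ok=True)
        for key, model in result.models.items():
            model.save(mdir / f"{key}.json")
    return results


def stage_report(cfg: ExperimentConfig) -> list[EvaluationReport]:
    out = Path(cfg.output_dir)
    rdir = out / "runs"
    reports = []
    for name in cfg.strategies:
        path = rdir / f"predictions_{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing {path}; run `run` first")
        reports.append(evaluate_strategy(read_predictions(path, name)))
    repdir = out / "reports"
    repdir.mkdir(parents=True, exist_ok=True)
    import json as _json

    for rep in reports:
        rep.to_dataframe().to_csv(repdir / f"report_{rep.strategy}.csv", index=False)
        (repdir / f"report_{rep.strategy}.json").write_text(_json.dumps(rep.to_json_dict(), indent=2))
    compare_strategies(reports).to_csv(repdir / "comparison.csv", index=False)
    log.info("report: wrote %d strategy reports to %s", len(reports), repdir)
    return reports
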