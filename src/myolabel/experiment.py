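"""End-to-end experiment runner: simulate a cohort, score label quality,
sweep decoders over dataset sizes, and run the cohort statistics."""

from __future__ import annotations

import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import build_training_dataset
from .evaluation import dataset_size_sweep
from .io import RunConfig, write_manifest
from .metrics import label_quality_report
from .nnet import WindowedNetSpec, small_spec
from .schedule import build_schedule
from .simulate import sample_cohort, simulate_participant
from .stats import cohort_stats


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as err:
                raise RuntimeError(f"[stage:{name}] {err}") from err
            print(f"[stage:{name}] {time.perf_counter() - t0:.1f}s", flush=True)
            return out
        return wrapped
    return deco


@_stage("simulate")
def _simulate_cohort(config: RunConfig):
    params = sample_cohort(config.preset, config.cohort_size, seed=config.seed)
    sessions = []
    for i, p in enumerate(params):
        per_participant = []
        for s in range(config.n_sessions):
            sch = build_schedule(config.protocol, config.reps, session_id=f"p{i}_s{s}")
            ps = p if s == 0 else type(p)(**{**asdict_params(p), "seed": p.seed + 1000 * s})
            per_participant.append(simulate_participant(sch, ps))
        sessions.append(per_participant)
    return sessions


def asdict_params(p) -> dict:
    from dataclasses import fields
    return {f.name: getattr(p, f.name) for f in fields(p)}


@_stage("label_metrics")
def _label_metrics(sessions) -> pd.DataFrame:
    rows = []
    for i, per_participant in enumerate(sessions):
        for paradigm in ("mimic", "mirror"):
            rep = label_quality_report(per_participant[0], paradigm)
            rows.append({"participant": f"p{i}", **asdict(rep)})
    return pd.DataFrame(rows)


@_stage("sweep")
def _sweep(sessions, config: RunConfig) -> pd.DataFrame:
    spec = small_spec(config.seed) if config.net == "small" else WindowedNetSpec(seed=config.seed)
    rows = []
    for i, per_participant in enumerate(sessions):
        datasets = {par: build_training_dataset(per_participant, par,
                                                n_electrodes=config.n_electrodes)
                    for par in ("mimic", "mirror")}
        results = dataset_size_sweep(datasets, algorithms=tuple(config.algorithms),
                                     sizes=tuple(config.sizes), k=config.k_folds,
                                     seed=config.seed, participant=f"p{i}", net_spec=spec)
        for r in results:
            for fi, v in enumerate(r.fold_rmse):
                rows.append({"participant": r.participant, "paradigm": r.paradigm,
                             "algorithm": r.algorithm, "n_train_trials": r.n_train_trials,
                             "fold": fi, "rmse": v, "summary_rmse": r.summary_rmse})
    return pd.DataFrame(rows)


@_stage("stats")
def _stats(metrics_df: pd.DataFrame, results_df: pd.DataFrame | None):
    summary = None
    if results_df is not None and len(results_df):
        summary = results_df.drop_duplicates(
            ["participant", "paradigm", "algorithm", "n_train_trials"])
    return cohort_stats(metrics_df, summary)


def run_full_experiment(config: RunConfig) -> dict:
    """Run every stage and write tabular outputs plus a run manifest.

    Returns the in-memory tables: ``metrics``, optionally ``results``, and
    the statistics tables.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sessions = _simulate_cohort(config)
    metrics_df = _label_metrics(sessions)
    metrics_df.to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
    results_df = None
    if config.sizes:
        results_df = _sweep(sessions, config)
        results_df.to_csv(out_dir / "results.tsv", sep="\t", index=False)
    tables = _stats(metrics_df, results_df)
    for name, tbl in tables.items():
        tbl.to_csv(out_dir / f"stats_{name}.tsv", sep="\t", index=False)
    write_manifest(config, out_dir / "manifest.yaml",
                   extra={"participants": [f"p{i}" for i in range(config.cohort_size)]})
    out = {"metrics": metrics_df, "stats": tables}
    if results_df is not None:
        out["results"] = results_df
    return out
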