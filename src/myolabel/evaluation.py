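"""Offline decoder evaluation: shuffled k-fold analysis across training
paradigm, algorithm and training-set size.

Folds are built at trial granularity (a trial is never split between train
and test) and stratified by movement: each fold reserves ``n_train`` trials
per movement for training, drawn equally from each recording session, and
tests on the remainder. Decoder predictions are scored against the
ground-truth kinematics. Folds are shared across paradigms at a fixed
(size, seed) so mimic/mirror comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .dataset import TrainingDataset
from .kalman import fit_kalman, kalman_filter
from .nnet import WindowedNetSpec, build_windows, fit_windowed_net

ALGORITHMS = ("kf", "cnn")


@dataclass
class FoldAssignment:
    train_trials: np.ndarray
    test_trials: np.ndarray


@dataclass
class EvalResult:
    participant: str
    paradigm: str
    algorithm: str
    n_train_trials: int
    fold_rmse: list[float]
    summary_rmse: float
    per_dof_medians: np.ndarray


def make_folds(dataset: TrainingDataset, n_train_trials: int, k: int = 10,
               seed: int = 0) -> list[FoldAssignment]:
    """k shuffled train/test splits, ``n_train_trials`` per movement drawn
    equally (to within one trial) from each session."""
    table = dataset.trial_table()  # trial -> (session, movement)
    by_move: dict[int, dict[int, list[int]]] = {}
    for trial, (sess, move) in table.items():
        by_move.setdefault(move, {}).setdefault(sess, []).append(trial)
    min_avail = min(sum(len(v) for v in sess.values()) for sess in by_move.values())
    if n_train_trials >= min_avail:
        raise ValueError("n_train_trials must be below the trials available per movement")
    rng = np.random.default_rng(seed)
    folds = []
    for f in range(k):
        train: list[int] = []
        test: list[int] = []
        for move in sorted(by_move):
            sessions = sorted(by_move[move])
            base, rem = divmod(n_train_trials, len(sessions))
            for i, s in enumerate(sessions):
                pool = sorted(by_move[move][s])
                rng.shuffle(pool)
                quota = base + (1 if (i + f) % len(sessions) < rem else 0)
                train.extend(pool[:quota])
                test.extend(pool[quota:])
        folds.append(FoldAssignment(train_trials=np.sort(train), test_trials=np.sort(test)))
    return folds


def _subset(dataset: TrainingDataset, rows: np.ndarray) -> TrainingDataset:
    return TrainingDataset(
        features=dataset.features[rows], labels=dataset.labels[rows],
        truth=dataset.truth[rows], trial_index=dataset.trial_index[rows],
        session_index=dataset.session_index[rows],
        movement_index=dataset.movement_index[rows],
        paradigm=dataset.paradigm, rate=dataset.rate,
    )


def _per_dof_error(pred: np.ndarray, truth: np.ndarray, aggregate: str) -> np.ndarray:
    """Per-DOF error summary over time: the median absolute error per time
    point (literal reading of the analysis recipe) or a plain per-DOF RMSE."""
    err = pred - truth
    if aggregate == "rmse":
        return np.sqrt(np.mean(err ** 2, axis=0))
    return np.median(np.abs(err), axis=0)


def _fit_predict(train: TrainingDataset, test: TrainingDataset, algorithm: str,
                 ridge_lambda: float, n_channels: int,
                 net_spec: WindowedNetSpec | None) -> np.ndarray:
    if algorithm == "kf":
        model = fit_kalman(train, ridge_lambda=ridge_lambda,
                           n_channels=min(n_channels, train.features.shape[1]))
        return np.clip(kalman_filter(model, test.features[:, model.channel_subset]), -1, 1)
    if algorithm == "cnn":
        from .nnet import windowed_net_predict  # local import keeps cli light
        model = fit_windowed_net(train, net_spec)
        return windowed_net_predict(model, test.features, test.trial_index).values
    raise ValueError(f"unknown algorithm {algorithm!r}")


def evaluate_condition(dataset: TrainingDataset, algorithm: str, n_train_trials: int,
                       k: int = 10, seed: int = 0, folds: list[FoldAssignment] | None = None,
                       ridge_lambda: float = 1e-3, n_channels: int = 48,
                       net_spec: WindowedNetSpec | None = None,
                       aggregate: str = "median_abs",
                       participant: str = "p0") -> EvalResult:
    """k-fold evaluation of one paradigm x algorithm x size condition.

    Per fold: train on the paradigm labels of the training trials, predict
    the test stream, summarize the per-DOF error against the held-out
    labels of the same paradigm and take the median across the 8 DOFs; the
    condition summary is the median across folds. (An oracle that emits the
    test labels scores exactly zero.)
    """
    if folds is None:
        folds = make_folds(dataset, n_train_trials, k=k, seed=seed)
    fold_vals = []
    per_dof = []
    for fi, fold in enumerate(folds):
        tr = _subset(dataset, dataset.rows_for_trials(fold.train_trials))
        te = _subset(dataset, dataset.rows_for_trials(fold.test_trials))
        spec = net_spec
        if algorithm == "cnn" and spec is not None:
            spec = dc_replace(spec, seed=spec.seed + fi)
        try:
            pred = _fit_predict(tr, te, algorithm, ridge_lambda, n_channels, spec)
        except Exception as err:
            raise RuntimeError(
                f"decoder training failed in fold {fi} "
                f"({dataset.paradigm}/{algorithm}/n={n_train_trials})") from err
        dof_err = _per_dof_error(pred, te.labels, aggregate)
        per_dof.append(dof_err)
        fold_vals.append(float(np.median(dof_err)))
    per_dof = np.asarray(per_dof)
    return EvalResult(
        participant=participant, paradigm=dataset.paradigm, algorithm=algorithm,
        n_train_trials=n_train_trials, fold_rmse=fold_vals,
        summary_rmse=float(np.median(fold_vals)),
        per_dof_medians=np.median(per_dof, axis=0),
    )


DEFAULT_SIZES = tuple(range(10, 60, 5))


def dataset_size_sweep(datasets: dict[str, TrainingDataset], algorithms=ALGORITHMS,
                       sizes=DEFAULT_SIZES, k: int = 10, seed: int = 0,
                       participant: str = "p0", **kwargs) -> list[EvalResult]:
    """Full factorial paradigm x algorithm x size evaluation.

    Folds are constructed once per size from the shared trial structure and
    reused across paradigms and algorithms, so comparisons are paired.
    """
    any_ds = next(iter(datasets.values()))
    results = []
    for size in sizes:
        fold_seed = int(np.random.default_rng([seed, size]).integers(2**31 - 1))
        folds = make_folds(any_ds, size, k=k, seed=fold_seed)
        for paradigm, ds in datasets.items():
            for algo in algorithms:
                results.append(evaluate_condition(
                    ds, algo, size, k=k, folds=folds,
                    participant=participant, **kwargs))
    return results
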