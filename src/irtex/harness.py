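"""Leave-one-patient-out classification harness.

Protocol: each fold holds out one patient; the remaining patients train
the model. For texture (and clinical+texture) inputs every patient
contributes three per-cut feature vectors and the held-out patient's
three slice predictions are reduced to one label by majority vote
(binary labels, three votes — no ties); the clinical-only input is a
single per-patient vector, so no voting is involved. Inside every fold
the features are standardized to zero mean / unit SD on the training
rows only, hyperparameters are tuned by patient-grouped inner 5-fold
cross-validation maximizing Cohen's kappa over the registered grid, and
the tuned model is refit on all training rows. Final metrics compare
the per-patient (voted) labels with the biopsy gold standard. The
patient-level score for the ROC is the mean of the slice probabilities,
for families that emit probabilities.

Boosted ensembles are strictly incremental — the T-tree model is the
first T stages of a larger fit with the same seed — so grids over the
ensemble size are scored from a single fit per inner fold via staged
predictions. This is an exact shortcut, not an approximation (a test
checks equality with brute-force refits).

All randomness descends from one master seed: fold f uses
SeedSequence([master, fold]) so any single fold can be reproduced in
isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .metrics import MetricsReport, cohen_kappa, confusion, evaluate
from .registry import ClassifierSpec, get_classifier_spec

N_INNER_FOLDS = 5


@dataclass(frozen=True)
class SliceDataset:
    """Per-slice feature matrix grouped by patient.

    ``X`` has shape (n_patients, n_slices, n_features) with n_slices 3
    for per-cut texture inputs or 1 for the per-patient clinical vector;
    ``y`` holds one binary label per patient (1 = KRAS+).
    """

    patient_ids: tuple[str, ...]
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        if X.ndim != 3 or X.shape[1] not in (1, 3):
            raise ValueError("X must have shape (n_patients, 1 or 3, n_features)")
        if len(self.patient_ids) != X.shape[0] or y.shape != (X.shape[0],):
            raise ValueError("patient ids, X and y are misaligned")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n_patients(self) -> int:
        return self.X.shape[0]

    @property
    def n_slices(self) -> int:
        return self.X.shape[1]

    @property
    def n_features(self) -> int:
        return self.X.shape[2]


@dataclass(frozen=True)
class PredictionSet:
    """LOPO outputs: slice votes, voted labels, optional mean scores."""

    patient_ids: tuple[str, ...]
    true_labels: np.ndarray
    slice_labels: np.ndarray  # (n_patients, n_slices)
    voted_labels: np.ndarray
    scores: np.ndarray | None
    chosen_params: tuple[Mapping, ...]


def majority_vote(slice_labels: Sequence[int]) -> int:
    """The label occurring at least twice among exactly three votes."""
    labels = np.asarray(slice_labels)
    if labels.shape != (3,):
        raise ValueError(f"expected exactly 3 slice labels, got shape {labels.shape}")
    return int(labels.sum() >= 2)


def _vote_rows(pred: np.ndarray) -> np.ndarray:
    """Per-patient label from an (n_patients, n_slices) prediction block."""
    if pred.shape[1] == 1:
        return pred[:, 0].astype(int)
    return np.array([majority_vote(row) for row in pred])


def standardize_fit_apply(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean/unit-SD transform fit on training rows only.

    Population SD (ddof = 0); features constant on the training rows map
    to 0 everywhere.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training rows to standardize")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    z_train = (train - mean) / safe
    z_test = (test - mean) / safe
    zero = sd == 0
    z_train[:, zero] = 0.0
    z_test[:, zero] = 0.0
    return z_train, z_test


def _flatten(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n_patients, s, F) -> (s*n_patients, F) with labels repeated per slice."""
    n, s, f = X.shape
    return X.reshape(n * s, f), np.repeat(y, s)


def resolve_grid(grid: Mapping, n_samples: int, n_features: int) -> list[dict]:
    """Expand a spec grid into concrete parameter dicts (stable order)."""
    if not grid:
        return [{}]
    keys = list(grid)
    value_lists = []
    for k in keys:
        v = grid[k]
        value_lists.append(list(v(n_samples, n_features)) if callable(v) else list(v))
    return [dict(zip(keys, combo)) for combo in product(*value_lists)]


def _inner_folds(
    n_patients: int, rng: np.random.Generator, n_folds: int = N_INNER_FOLDS
) -> list[np.ndarray]:
    idx = rng.permutation(n_patients)
    return [f for f in np.array_split(idx, n_folds) if f.size > 0]


def _stage_groups(
    candidates: list[dict], staged_param: str | None
) -> list[tuple[dict, list[tuple[int, dict]]]]:
    """Group grid points that differ only in the boosting-size parameter.

    Returns [(fit_params, [(candidate_index, params), ...])] where
    fit_params carries the maximum stage of the group; a group of one is
    simply fit directly.
    """
    if staged_param is None:
        return [(params, [(i, params)]) for i, params in enumerate(candidates)]
    groups: dict[tuple, list[tuple[int, dict]]] = {}
    for i, params in enumerate(candidates):
        key = tuple(sorted((k, v) for k, v in params.items() if k != staged_param))
        groups.setdefault(key, []).append((i, params))
    out = []
    for members in groups.values():
        fit_params = dict(max(members, key=lambda m: m[1][staged_param])[1])
        out.append((fit_params, members))
    return out


def _predict_candidates(
    spec: ClassifierSpec,
    fit_params: dict,
    members: list[tuple[int, dict]],
    rs: int,
    z_train: np.ndarray,
    y_train: np.ndarray,
    z_test: np.ndarray,
) -> dict[int, np.ndarray]:
    """Fit once and emit test predictions for every member grid point."""
    model = spec.make(fit_params, rs)
    model.fit(z_train, y_train)
    if spec.staged_param is None or len(members) == 1 or not hasattr(model, "staged_predict"):
        pred = np.asarray(model.predict(z_test))
        return {i: pred for i, _ in members}
    wanted = {params[spec.staged_param]: i for i, params in members}
    out: dict[int, np.ndarray] = {}
    for stage, pred in enumerate(model.staged_predict(z_test), start=1):
        if stage in wanted:
            out[wanted[stage]] = np.asarray(pred)
    # ensemble may have stopped early; remaining members equal the last stage
    for t, i in wanted.items():
        if i not in out:
            out[i] = np.asarray(model.predict(z_test))
    return out


def tune_hyperparams(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    rng: np.random.Generator,
) -> dict:
    """Grid search by patient-grouped inner 5-fold CV maximizing kappa.

    ``X`` is (n_patients, s, F). Each inner fold holds out whole
    patients, votes their slices and pools the voted predictions over
    folds; the grid point with the highest pooled kappa wins, ties going
    to the earliest (least complex) grid entry. A single-point grid is
    returned immediately without inner CV.
    """
    n, s, f = X.shape
    candidates = resolve_grid(spec.grid, n_samples=s * n, n_features=f)
    if len(candidates) == 1:
        return candidates[0]
    folds = _inner_folds(n, rng)
    rs = int(rng.integers(2**31 - 1))
    votes = np.empty((len(candidates), n), dtype=int)
    evaluated = np.zeros(n, dtype=bool)
    for fold in folds:
        train_idx = np.setdiff1d(np.arange(n), fold)
        if len(np.unique(y[train_idx])) < 2:
            warnings.warn("inner fold with single-class training set skipped")
            continue
        X_tr, y_tr = _flatten(X[train_idx], y[train_idx])
        X_te, _ = _flatten(X[fold], y[fold])
        z_train, z_test = standardize_fit_apply(X_tr, X_te)
        for fit_params, members in _stage_groups(candidates, spec.staged_param):
            preds = _predict_candidates(spec, fit_params, members, rs,
                                        z_train, y_tr, z_test)
            for ci, pred in preds.items():
                votes[ci, fold] = _vote_rows(pred.reshape(-1, s))
        evaluated[fold] = True
    if not evaluated.any():
        raise ValueError("all inner folds degenerate: cannot tune")
    best_params, best_kappa = None, -np.inf
    for ci, params in enumerate(candidates):
        kappa = cohen_kappa(confusion(y[evaluated], votes[ci, evaluated]))
        if kappa > best_kappa + 1e-12:
            best_kappa, best_params = kappa, params
    return best_params


def lopo_cv(
    dataset: SliceDataset,
    spec: ClassifierSpec | str,
    seed: int = 0,
) -> tuple[PredictionSet, MetricsReport]:
    """Leave-one-patient-out cross-validation with per-slice voting.

    The held-out patient's slices never touch standardization, tuning or
    fitting. Deterministic given (dataset, spec, seed).
    """
    if isinstance(spec, str):
        spec = get_classifier_spec(spec)
    X, y = dataset.X, dataset.y
    n, s = dataset.n_patients, dataset.n_slices
    if min(np.sum(y == 1), np.sum(y == 0)) < 2:
        raise ValueError("need at least two patients per class for LOPO")
    slice_labels = np.empty((n, s), dtype=int)
    voted = np.empty(n, dtype=int)
    scores = np.full(n, np.nan) if spec.supports_proba else None
    chosen: list[dict] = []
    for fold in range(n):
        ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, fold])
        rng = np.random.default_rng(ss)
        train_idx = np.setdiff1d(np.arange(n), [fold])
        params = tune_hyperparams(X[train_idx], y[train_idx], spec, rng)
        chosen.append(params)
        X_tr, y_tr = _flatten(X[train_idx], y[train_idx])
        z_train, z_test = standardize_fit_apply(X_tr, X[fold])
        rs = int(rng.integers(2**31 - 1))
        model = spec.make(params, rs)
        model.fit(z_train, y_tr)
        pred = np.asarray(model.predict(z_test))
        slice_labels[fold] = pred
        voted[fold] = _vote_rows(pred.reshape(1, s))[0]
        if scores is not None:
            proba = model.predict_proba(z_test)
            pos_col = int(np.where(model.classes_ == 1)[0][0])
            scores[fold] = float(proba[:, pos_col].mean())
    predictions = PredictionSet(
        patient_ids=dataset.patient_ids,
        true_labels=y.copy(),
        slice_labels=slice_labels,
        voted_labels=voted,
        scores=None if scores is None else scores,
        chosen_params=tuple(chosen),
    )
    report = evaluate(y, voted, scores=scores)
    return predictions, report
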