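"""Experiment design for comparing screening classifiers.

The design crosses four train/test splits (test fraction r_d ∈ {0.2, 0.3,
0.4, 0.5}), two cross-validation depths (K ∈ {5, 10}) and the two assessment
schemes into 16 evaluation conditions. In each condition every algorithm is
evaluated twice: *trained* (untuned default hyperparameters) and *retrained*
(grid-search-tuned), giving 32 result sets per algorithm. Accuracies are
compared against the baseline accuracy — the majority-class rate mode(N)/N —
below which a model is flagged unsatisfactory.

All randomness derives from one master seed: condition ``i`` uses
``master_seed + i`` (mod 2³¹) for its split, fold shuffle and model seeds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.preprocessing import MinMaxScaler

from .backends import (
    ALGORITHMS,
    HyperparameterGrid,
    ModelSpec,
    build_and_fit,
    grids,
)
from .core import SCHEMES, SURROGATES, Scheme, assess_frame

logger = logging.getLogger(__name__)

R_D_LEVELS: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5)
K_LEVELS: tuple[int, ...] = (5, 10)

TRAINED = "trained"
RETRAINED = "retrained"


@dataclass(frozen=True)
class SplitSpec:
    """Test fraction r_d = n_test / n_total and the shuffle seed."""

    r_d: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.r_d < 1.0:
            raise ValueError("r_d must lie strictly between 0 and 1")


@dataclass(frozen=True)
class EvaluationCondition:
    r_d: float
    k: int
    scheme_name: str

    @property
    def scheme(self) -> Scheme:
        return SCHEMES[self.scheme_name]

    @property
    def id(self) -> str:
        return f"{self.scheme_name}_rd{self.r_d:g}_k{self.k}"


@dataclass(frozen=True)
class AccuracyReport:
    """Baseline accuracy mode(N)/N of a label vector."""

    baseline: float
    n: int
    mode_count: int


@dataclass
class ModelResult:
    condition: EvaluationCondition
    algorithm: str
    stage: str
    cv_accuracy: float
    test_accuracy: float
    spec: ModelSpec
    baseline: float
    below_baseline: bool
    model: object | None = field(default=None, repr=False)
    scaler: object | None = field(default=None, repr=False)


def full_design(
    schemes: Sequence[str] = ("scheme1", "scheme2"),
    r_d_levels: Sequence[float] = R_D_LEVELS,
    k_levels: Sequence[int] = K_LEVELS,
) -> list[EvaluationCondition]:
    """The 4 × 2 × 2 = 16 evaluation conditions, in deterministic order."""
    return [
        EvaluationCondition(r_d=r_d, k=k, scheme_name=scheme)
        for scheme in schemes
        for r_d in r_d_levels
        for k in k_levels
    ]


def minmax_normalize(train_features, other_features=None):
    """Fit a per-column [0, 1] min-max map on the training data only.

    Returns ``(train_scaled, other_scaled, scaler)``; ``other_scaled`` is
    transformed with the *training* map and may fall outside [0, 1] — it is
    deliberately not clipped. A zero-range column maps to 0 with a warning.
    """
    X_train = np.asarray(train_features, dtype=float)
    scaler = MinMaxScaler(clip=False)
    train_scaled = scaler.fit_transform(X_train)
    if np.any(scaler.data_range_ == 0):
        cols = np.flatnonzero(scaler.data_range_ == 0).tolist()
        warnings.warn(
            f"zero-range training column(s) {cols} mapped to 0", stacklevel=2
        )
    other_scaled = None
    if other_features is not None:
        other_scaled = scaler.transform(np.asarray(other_features, dtype=float))
    return train_scaled, other_scaled, scaler


def split(features, labels, spec: SplitSpec):
    """Seeded random partition into training and testing sets.

    ``|test| = round(r_d · N)``. If the training portion ends up single-class
    the split is retried with an incremented sub-seed (at most 100 times).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = len(y)
    if n < 10:
        raise ValueError("dataset too small to split (need at least 10 records)")
    n_test = int(np.floor(spec.r_d * n + 0.5))
    if not 0 < n_test < n:
        raise ValueError(f"r_d={spec.r_d} leaves an empty train or test set")
    for attempt in range(100):
        rng = np.random.default_rng((spec.seed + attempt) % (2**31))
        order = rng.permutation(n)
        test_idx, train_idx = order[:n_test], order[n_test:]
        if len(np.unique(y[train_idx])) > 1:
            return X[train_idx], X[test_idx], y[train_idx], y[test_idx]
    raise ValueError("could not produce a two-class training set in 100 attempts")


def _fold_indices(n: int, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    kf = KFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    return list(kf.split(np.arange(n)))


def kfold_cv(
    spec: ModelSpec,
    features,
    labels,
    k: int = 5,
    seed: int = 0,
    folds: list | None = None,
) -> float:
    """Mean held-out accuracy over K seeded folds of the training set.

    Fold sizes differ by at most one and every record is held out exactly
    once. A fold whose training portion is single-class is skipped with a
    warning and K is effectively reduced.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(y) < k:
        raise ValueError("training set smaller than the number of folds")
    if folds is None:
        folds = _fold_indices(len(y), k, seed)
    accuracies = []
    for train_idx, val_idx in folds:
        if len(np.unique(y[train_idx])) < 2:
            warnings.warn("single-class fold skipped; effective K reduced", stacklevel=2)
            continue
        model = build_and_fit(spec, X[train_idx], y[train_idx], seed=seed)
        accuracies.append(float(model.score(X[val_idx], y[val_idx])))
    if not accuracies:
        raise ValueError("every fold was single-class; cannot cross-validate")
    return float(np.mean(accuracies))


def grid_search(
    algorithm: str,
    grid: HyperparameterGrid,
    features,
    labels,
    k: int = 5,
    seed: int = 0,
    folds: list | None = None,
    return_all: bool = False,
):
    """Exhaustive search maximizing K-fold accuracy.

    Ties resolve to the earliest grid point (strictly-greater comparison in
    the grid's deterministic enumeration order). With ``return_all`` the
    per-spec CV accuracies are returned as a third element so callers can
    reuse evaluations.
    """
    specs = list(grid)
    if not specs:
        raise ValueError(f"empty grid for {algorithm}")
    if folds is None:
        folds = _fold_indices(len(np.asarray(labels)), k, seed)
    best_spec, best_cv = None, -np.inf
    evaluations: list[tuple[ModelSpec, float]] = []
    failures = []
    for spec in specs:
        try:
            cv = kfold_cv(spec, features, labels, k=k, seed=seed, folds=folds)
        except Exception as exc:  # noqa: BLE001 - report all failing grid points
            failures.append((spec, exc))
            continue
        evaluations.append((spec, cv))
        if cv > best_cv:
            best_spec, best_cv = spec, cv
    if best_spec is None:
        detail = "; ".join(f"{s.hyperparameters}: {e}" for s, e in failures[:5])
        raise RuntimeError(f"all {len(specs)} grid points failed for {algorithm}: {detail}")
    if return_all:
        return best_spec, best_cv, evaluations
    return best_spec, best_cv


def baseline_accuracy(labels) -> AccuracyReport:
    """Majority-class accuracy mode(N)/N — the no-model reference."""
    y = np.asarray(labels)
    if len(y) == 0:
        raise ValueError("empty label vector")
    _, counts = np.unique(y, return_counts=True)
    mode_count = int(counts.max())
    return AccuracyReport(baseline=mode_count / len(y), n=len(y), mode_count=mode_count)


def run_evaluation(
    frame: pd.DataFrame,
    conditions: Iterable[EvaluationCondition] | None = None,
    algorithms: Sequence[str] = ALGORITHMS,
    grid_set: Mapping[str, HyperparameterGrid] | None = None,
    master_seed: int = 0,
    keep_models: bool = False,
) -> list[ModelResult]:
    """Run the full trained/retrained comparison over the given conditions.

    For each condition: label by its scheme, split, min-max normalize on the
    training part, then fit each algorithm with its untuned default spec
    (*trained*) and with the grid-search winner (*retrained*), scoring both
    on the held-out test set. Fold indices are computed once per condition and
    shared across algorithms and grid points.
    """
    conditions = list(conditions) if conditions is not None else full_design()
    if not conditions:
        raise ValueError("need at least one evaluation condition")
    if not algorithms:
        raise ValueError("need at least one algorithm")
    unknown = [a for a in algorithms if a not in ALGORITHMS]
    if unknown:
        raise ValueError(f"unknown algorithm(s) {unknown}")
    if grid_set is None:
        grid_set = grids(reduced=True)

    base_seed = int(master_seed) % (2**31)
    results: list[ModelResult] = []
    for i, condition in enumerate(conditions):
        seed = (base_seed + i) % (2**31)
        labels = assess_frame(frame, condition.scheme).to_numpy()
        features = frame[list(SURROGATES)]
        report = baseline_accuracy(labels)
        logger.info(
            "condition %s: n=%d baseline=%.3f", condition.id, report.n, report.baseline
        )
        X_tr, X_te, y_tr, y_te = split(features, labels, SplitSpec(condition.r_d, seed))
        X_tr, X_te, scaler = minmax_normalize(X_tr, X_te)
        folds = _fold_indices(len(y_tr), condition.k, seed)

        for algorithm in algorithms:
            grid = grid_set[algorithm]
            default_spec = grid.default_spec()
            best_spec, best_cv, evaluations = grid_search(
                algorithm, grid, X_tr, y_tr, k=condition.k, seed=seed, folds=folds,
                return_all=True,
            )
            # The default spec usually sits in the grid; reuse its evaluation.
            default_cv = next((cv for s, cv in evaluations if s == default_spec), None)
            stages = {TRAINED: (default_spec, default_cv), RETRAINED: (best_spec, best_cv)}
            for stage, (spec, cv) in stages.items():
                if cv is None:
                    cv = kfold_cv(spec, X_tr, y_tr, k=condition.k, seed=seed, folds=folds)
                model = build_and_fit(spec, X_tr, y_tr, seed=seed)
                test_accuracy = float(model.score(X_te, y_te))
                below = test_accuracy < report.baseline
                if below:
                    logger.info(
                        "condition %s: %s/%s below baseline (%.3f < %.3f)",
                        condition.id, algorithm, stage, test_accuracy, report.baseline,
                    )
                results.append(
                    ModelResult(
                        condition=condition,
                        algorithm=algorithm,
                        stage=stage,
                        cv_accuracy=float(cv),
                        test_accuracy=test_accuracy,
                        spec=spec,
                        baseline=report.baseline,
                        below_baseline=below,
                        model=model if keep_models else None,
                        scaler=scaler if keep_models else None,
                    )
                )
    return results


def results_frame(results: Sequence[ModelResult]) -> pd.DataFrame:
    """Flatten results into a tidy table (one row per model × stage × condition)."""
    rows = []
    for r in results:
        rows.append(
            {
                "condition": r.condition.id,
                "scheme": r.condition.scheme_name,
                "r_d": r.condition.r_d,
                "k": r.condition.k,
                "algorithm": r.algorithm,
                "stage": r.stage,
                "cv_accuracy": r.cv_accuracy,
                "test_accuracy": r.test_accuracy,
                "baseline": r.baseline,
                "below_baseline": r.below_baseline,
                "hyperparameters": repr(dict(r.spec.hyperparameters)),
            }
        )
    return pd.DataFrame(rows)


def tally_best(results: Sequence[ModelResult]) -> pd.DataFrame:
    """Count, per algorithm, the (condition, stage) cells it wins.

    The winner of a cell is the algorithm with the highest test accuracy; on
    an exact tie every tied algorithm is credited. Returns counts and the
    mean test accuracy of each algorithm's winning cells, per stage and
    combined.
    """
    if not results:
        raise ValueError("no results to tally")
    cells: dict[tuple[str, str], list[ModelResult]] = {}
    for r in results:
        cells.setdefault((r.condition.id, r.stage), []).append(r)
    seen = [a for a in ALGORITHMS if any(r.algorithm == a for r in results)]
    wins: dict[str, dict[str, list[float]]] = {
        a: {TRAINED: [], RETRAINED: []} for a in seen
    }
    for (_, stage), cell in cells.items():
        top = max(r.test_accuracy for r in cell)
        for r in cell:
            if r.test_accuracy == top:
                wins[r.algorithm][stage].append(r.test_accuracy)
    rows = []
    for algorithm in seen:
        trained, retrained = wins[algorithm][TRAINED], wins[algorithm][RETRAINED]
        both = trained + retrained
        rows.append(
            {
                "algorithm": algorithm,
                "trained_count": len(trained),
                "trained_mean_accuracy": float(np.mean(trained)) if trained else np.nan,
                "retrained_count": len(retrained),
                "retrained_mean_accuracy": float(np.mean(retrained)) if retrained else np.nan,
                "combined_count": len(both),
                "combined_mean_accuracy": float(np.mean(both)) if both else np.nan,
            }
        )
    return pd.DataFrame(rows)
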