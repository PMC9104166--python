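"""Uniform adapter over the nine screening classifiers.

Each algorithm is identified by a short name and configured through a
:class:`ModelSpec`; :func:`build_and_fit` turns a spec into a fitted
scikit-learn estimator exposing the usual ``predict``/``score`` contract.
Hyperparameter search spaces ship as a YAML file (``data/grids.yaml``) and
enumerate deterministically, which the evaluation harness relies on for
reproducible tie-breaks.

A note on the regularization factor C: for the SVM and logistic backends C is
passed straight through to scikit-learn's ``C``, i.e. the *inverse*
regularization strength — larger C permits a closer fit to the training data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterator, Mapping

import numpy as np
import yaml
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

ALGORITHMS: tuple[str, ...] = (
    "svm_linear",
    "svm_poly",
    "svm_rbf",
    "svm_sigmoid",
    "knn",
    "logistic",
    "decision_tree",
    "random_forest",
    "mlp",
)

_VALID_PARAMS: dict[str, frozenset[str]] = {
    "svm_linear": frozenset({"C"}),
    "svm_poly": frozenset({"C", "degree", "coef0"}),
    "svm_rbf": frozenset({"C"}),
    "svm_sigmoid": frozenset({"C", "coef0"}),
    "knn": frozenset({"n_neighbors", "weights"}),
    "logistic": frozenset({"C"}),
    "decision_tree": frozenset(
        {"max_depth", "min_samples_split", "min_samples_leaf", "criterion"}
    ),
    "random_forest": frozenset(
        {"n_estimators", "max_depth", "min_samples_split", "min_samples_leaf", "criterion"}
    ),
    "mlp": frozenset({"neurons", "hidden_ratio", "activation", "solver", "learning_rate"}),
}


@dataclass(frozen=True)
class ModelSpec:
    """One point in an algorithm's hyperparameter space."""

    algorithm: str
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        unknown = set(self.hyperparameters) - _VALID_PARAMS[self.algorithm]
        if unknown:
            raise ValueError(
                f"{self.algorithm}: unknown hyperparameter(s) {sorted(unknown)}"
            )


class HyperparameterGrid:
    """Ordered cross-product of hyperparameter values for one algorithm.

    Iteration order is the cross-product of the dimensions in declaration
    order, last dimension fastest, and is identical on every enumeration.
    """

    def __init__(self, algorithm: str, dimensions: Mapping[str, list]):
        self.algorithm = algorithm
        self.dimensions = {
            name: [self._freeze(v) for v in values] for name, values in dimensions.items()
        }
        ModelSpec(algorithm, {name: vals[0] for name, vals in self.dimensions.items()})

    @staticmethod
    def _freeze(value):
        return tuple(value) if isinstance(value, list) else value

    def __len__(self) -> int:
        out = 1
        for values in self.dimensions.values():
            out *= len(values)
        return out

    def __iter__(self) -> Iterator[ModelSpec]:
        names = list(self.dimensions)
        for combo in itertools.product(*(self.dimensions[n] for n in names)):
            yield ModelSpec(self.algorithm, dict(zip(names, combo)))

    def default_spec(self) -> ModelSpec:
        """Untuned default: the midpoint element of every dimension."""
        return ModelSpec(
            self.algorithm,
            {name: values[len(values) // 2] for name, values in self.dimensions.items()},
        )


def _load_grid_file() -> dict:
    text = resources.files("iaqscreen").joinpath("data/grids.yaml").read_text()
    return yaml.safe_load(text)


def grids(reduced: bool = True, overrides: Mapping | None = None) -> dict[str, HyperparameterGrid]:
    """Load the shipped grids (``reduced`` by default), optionally overridden.

    ``overrides`` maps algorithm name to a {dimension: [values]} mapping that
    replaces the shipped definition for that algorithm.
    """
    raw = _load_grid_file()["reduced" if reduced else "full"]
    if overrides:
        raw = {**raw, **{k: dict(v) for k, v in overrides.items()}}
    return {name: HyperparameterGrid(name, dims) for name, dims in raw.items()}


def allocate_neurons(total: int, ratio: tuple[int, ...]) -> tuple[int, ...]:
    """Split ``total`` neurons over hidden layers proportionally to ``ratio``.

    Each layer gets the floor of its proportional share; any remainder goes to
    the first layer. Deterministic, and every layer must end up non-empty.
    """
    ratio = tuple(int(r) for r in ratio)
    if not ratio or any(r <= 0 for r in ratio):
        raise ValueError("ratio must be a non-empty tuple of positive integers")
    if total < len(ratio):
        raise ValueError(f"cannot spread {total} neurons over {len(ratio)} layers")
    denom = sum(ratio)
    sizes = [int(total * r // denom) for r in ratio]
    sizes[0] += total - sum(sizes)
    if any(s < 1 for s in sizes):
        raise ValueError(f"allocation {sizes} leaves an empty layer")
    return tuple(sizes)


def mlp_architecture_table(limit: int = 60) -> list[ModelSpec]:
    """Deterministic enumeration of MLP configurations.

    A reconstruction of a 60-row architecture table from the deterministic
    cross-product of the full MLP grid (totals × layer ratios × activations ×
    solvers × learning-rate schedules), truncated to ``limit`` in grid order.
    """
    grid = grids(reduced=False)["mlp"]
    return list(itertools.islice(iter(grid), limit))


def _check_training_labels(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError(
            "training labels contain a single class; a screening classifier "
            "cannot be fitted on a degenerate sample"
        )


def build_model(spec: ModelSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator for a spec (unfitted)."""
    p = dict(spec.hyperparameters)
    algorithm = spec.algorithm
    if algorithm == "svm_linear":
        return SVC(kernel="linear", C=p.get("C", 1.0))
    if algorithm == "svm_poly":
        return SVC(
            kernel="poly",
            C=p.get("C", 1.0),
            degree=p.get("degree", 3),
            coef0=p.get("coef0", 0.0),
        )
    if algorithm == "svm_rbf":
        return SVC(kernel="rbf", C=p.get("C", 1.0))
    if algorithm == "svm_sigmoid":
        return SVC(kernel="sigmoid", C=p.get("C", 1.0), coef0=p.get("coef0", 0.0))
    if algorithm == "knn":
        return KNeighborsClassifier(
            n_neighbors=p.get("n_neighbors", 5), weights=p.get("weights", "uniform")
        )
    if algorithm == "logistic":
        return LogisticRegression(C=p.get("C", 1.0), max_iter=5000)
    if algorithm == "decision_tree":
        return DecisionTreeClassifier(
            max_depth=p.get("max_depth"),
            min_samples_split=p.get("min_samples_split", 2),
            min_samples_leaf=p.get("min_samples_leaf", 1),
            criterion=p.get("criterion", "gini"),
            random_state=seed,
        )
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 100),
            max_depth=p.get("max_depth"),
            min_samples_split=p.get("min_samples_split", 2),
            min_samples_leaf=p.get("min_samples_leaf", 1),
            criterion=p.get("criterion", "gini"),
            random_state=seed,
        )
    if algorithm == "mlp":
        layers = allocate_neurons(p.get("neurons", 100), tuple(p.get("hidden_ratio", (1,))))
        return MLPClassifier(
            hidden_layer_sizes=layers,
            activation=p.get("activation", "relu"),
            solver=p.get("solver", "lbfgs"),
            learning_rate=p.get("learning_rate", "constant"),
            max_iter=2000,
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")  # pragma: no cover


def build_and_fit(spec: ModelSpec, features, labels, seed: int = 0):
    """Fit the estimator for ``spec`` on [0,1]-scaled features and binary labels.

    Deterministic given ``spec`` and ``seed``; refuses single-class labels.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    _check_training_labels(y)
    model = build_model(spec, seed=seed)
    model.fit(X, y)
    return model
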