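"""Wrapper feature selection: binarized optimizer positions scored by a
KNN-error fitness, plus the repeated-experiment protocol.

A continuous position in [0,1]^D is thresholded (strictly > 0.5) into a
binary feature mask.  A mask's fitness combines the misclassification
rate E of a k-nearest-neighbor classifier (k = 5, Euclidean) trained on
the selected columns with a parsimony penalty:

    fitness = alpha * E + (1 - alpha) * S / D,        alpha = 0.99

where S is the number of selected features and D the total.  The empty
mask is assigned the maximal fitness 1.0 without fitting a classifier.
E is measured on the run's stratified 20% hold-out partition by default;
an internal cross-validation mode on the 80% training partition is
available to decouple selection from the reported test split.

A selection run draws a stratified 80/20 split, runs a population
optimizer (P = 10, T = 50 by default) over the relaxed mask space, and
reports the best mask together with its hold-out accuracy, precision,
recall and F1 under a reporting classifier (KNN k = 5, or random forest
with 100 trees).  The repeated protocol executes R = 25 such runs with
fresh per-run splits; comparisons across algorithms reuse the same split
seeds so that runs form paired blocks for Friedman ranking.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier

from . import optimizers
from .evaluation import MetricSet, aggregate_run_metrics, classification_metrics

__all__ = [
    "FitnessConfig",
    "SelectionRun",
    "ExperimentReport",
    "binarize_position",
    "subset_fitness",
    "MaskedKNNError",
    "select_features",
    "run_repeated_experiment",
    "compare_algorithms",
]


@dataclass(frozen=True)
class FitnessConfig:
    """Wrapper-fitness parameters.

    ``alpha`` weights the error term (size penalty weight is 1 − alpha);
    ``literal_weights`` switches to the variant in which both terms carry
    weight alpha.  ``cv_folds`` (optional) evaluates E by stratified
    cross-validation inside the training partition instead of on the
    hold-out split.
    """

    alpha: float = 0.99
    threshold: float = 0.5
    k: int = 5
    empty_mask_fitness: float = 1.0
    literal_weights: bool = False
    cv_folds: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not (0 < self.threshold < 1):
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")

    def combine(self, error: float, n_selected: int, n_features: int) -> float:
        size_weight = self.alpha if self.literal_weights else 1.0 - self.alpha
        return self.alpha * error + size_weight * (n_selected / n_features)


def binarize_position(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary mask: bit d = 1 iff position_d > threshold (strict)."""
    return np.asarray(position) > threshold


class MaskedKNNError:
    """Fast exact KNN misclassification rate under a feature mask.

    Precomputes per-feature squared differences between evaluation and
    training samples once, so each mask costs one matrix-vector product
    plus a top-k partition — the same Euclidean k-NN majority vote as
    ``KNeighborsClassifier``, orders of magnitude cheaper per call for
    wrapper loops.  k must be odd so binary votes cannot tie.
    """

    def __init__(self, X_train, y_train, X_eval, y_eval, k: int = 5):
        X_train = np.asarray(X_train, dtype=np.float64)
        X_eval = np.asarray(X_eval, dtype=np.float64)
        self.y_train = np.asarray(y_train, dtype=np.int64)
        self.y_eval = np.asarray(y_eval, dtype=np.int64)
        if X_eval.shape[0] == 0:
            raise ValueError("evaluation partition is empty")
        if len(np.unique(self.y_train)) < 2:
            raise ValueError("training partition must contain both classes")
        self.k = min(k, X_train.shape[0])
        self.n_eval = X_eval.shape[0]
        # (n_eval * n_train, D) table of per-feature squared differences
        self._diff2 = ((X_eval[:, None, :] - X_train[None, :, :]) ** 2).reshape(
            -1, X_train.shape[1]
        )

    def predict(self, mask: np.ndarray) -> np.ndarray:
        d2 = (self._diff2 @ np.asarray(mask, dtype=np.float64)).reshape(self.n_eval, -1)
        idx = np.argpartition(d2, self.k - 1, axis=1)[:, : self.k]
        votes = self.y_train[idx].sum(axis=1)
        return (2 * votes > self.k).astype(np.int64)

    def error(self, mask: np.ndarray) -> float:
        return float(np.mean(self.predict(mask) != self.y_eval))


def subset_fitness(
    mask: np.ndarray,
    X_train,
    y_train,
    X_eval,
    y_eval,
    cfg: FitnessConfig = FitnessConfig(),
) -> float:
    """Reference fitness of one mask via scikit-learn's KNN.

    Fits ``KNeighborsClassifier(n_neighbors=k)`` on the selected training
    columns, measures the misclassification rate on the evaluation
    partition and combines it with the size penalty.  The empty mask skips
    the fit and returns ``empty_mask_fitness``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return cfg.empty_mask_fitness
    X_train = np.asarray(X_train, dtype=np.float64)
    X_eval = np.asarray(X_eval, dtype=np.float64)
    if X_eval.shape[0] == 0:
        raise ValueError("evaluation partition is empty")
    if len(np.unique(np.asarray(y_train))) < 2:
        raise ValueError("training partition must contain both classes")
    clf = KNeighborsClassifier(n_neighbors=min(cfg.k, X_train.shape[0]), algorithm="brute")
    clf.fit(X_train[:, mask], y_train)
    error = float(np.mean(clf.predict(X_eval[:, mask]) != np.asarray(y_eval)))
    return cfg.combine(error, int(mask.sum()), mask.size)


@dataclass
class SelectionRun:
    algorithm: str
    seed: int
    split_seed: int
    mask: np.ndarray
    n_selected: int
    n_features: int
    best_fitness: float
    trace: np.ndarray
    metrics: MetricSet
    elapsed: float
    n_test: int
    train_index: np.ndarray
    test_index: np.ndarray


@dataclass
class ExperimentReport:
    algorithm: str
    runs: list
    aggregates: dict
    config: dict


def _split_xy(data: pd.DataFrame):
    feature_cols = [c for c in data.columns if c != "label"]
    X = data[feature_cols].to_numpy(dtype=np.float64)
    y = data["label"].to_numpy(dtype=np.int64)
    if len(np.unique(y)) != 2:
        raise ValueError("feature matrix must contain exactly two classes")
    return X, y, feature_cols


def _make_objective(X_tr, y_tr, X_te, y_te, cfg: FitnessConfig, split_seed: int):
    """Objective closure over the relaxed mask space."""
    D = X_tr.shape[1]
    if cfg.cv_folds:
        skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=split_seed)
        scorers = [
            MaskedKNNError(X_tr[tr], y_tr[tr], X_tr[va], y_tr[va], cfg.k)
            for tr, va in skf.split(X_tr, y_tr)
        ]
    else:
        scorers = [MaskedKNNError(X_tr, y_tr, X_te, y_te, cfg.k)]

    def objective(position: np.ndarray) -> float:
        mask = binarize_position(position, cfg.threshold)
        S = int(mask.sum())
        if S == 0:
            return cfg.empty_mask_fitness
        error = float(np.mean([s.error(mask) for s in scorers]))
        return cfg.combine(error, S, D)

    return objective


def _reporting_classifier(name: str, cfg: FitnessConfig, rf_trees: int, seed: int):
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=cfg.k)
    if name == "rf":
        return RandomForestClassifier(n_estimators=rf_trees, random_state=seed)
    raise ValueError(f"unknown reporting classifier {name!r}; use 'knn' or 'rf'")


def select_features(
    data: pd.DataFrame,
    algorithm: str = "shosca",
    fitness_cfg: FitnessConfig = FitnessConfig(),
    P: int = 10,
    T: int = 50,
    seed: int = 0,
    split_seed: int | None = None,
    sho_cfg: optimizers.SHOConfig | None = None,
    sca_cfg: optimizers.SCAConfig | None = None,
    classifier: str = "knn",
    rf_trees: int = 100,
) -> SelectionRun:
    """One wrapper-selection run on a labeled feature matrix.

    Draws a stratified 80/20 split seeded by ``split_seed`` (defaults to
    ``seed``), optimizes the relaxed mask with the named algorithm, and
    evaluates the final mask's hold-out metrics under the reporting
    classifier.  One agent of the initial population is pinned at 0.75 in
    every coordinate, so the full-feature mask is always part of the
    search and the returned fitness can never exceed the full-mask
    fitness on the same split.
    """
    t0 = time.perf_counter()
    X, y, _ = _split_xy(data)
    counts = np.bincount(y)
    if counts.min() < 10:
        raise ValueError(f"need >= 10 samples per class for a stratified 80/20 split, got {counts}")
    if split_seed is None:
        split_seed = seed
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=0.2, stratify=y, random_state=split_seed
    )
    X_tr, y_tr = X[train_idx], y[train_idx]
    X_te, y_te = X[test_idx], y[test_idx]
    D = X.shape[1]
    objective = _make_objective(X_tr, y_tr, X_te, y_te, fitness_cfg, split_seed)
    rng = np.random.default_rng(seed)
    init = optimizers.initialize_population(P, D, rng)
    init[0, :] = 0.75  # full-feature mask is always reachable
    result = optimizers.optimize(
        algorithm, objective, P=P, dim=D, T=T, sho_cfg=sho_cfg, sca_cfg=sca_cfg,
        rng=rng, init_positions=init,
    )
    mask = binarize_position(result.best_position, fitness_cfg.threshold)
    if mask.any():
        clf = _reporting_classifier(classifier, fitness_cfg, rf_trees, seed)
        clf.fit(X_tr[:, mask], y_tr)
        y_pred = clf.predict(X_te[:, mask])
    else:  # degenerate: optimizer never left the empty mask
        y_pred = np.zeros_like(y_te)
    metrics = classification_metrics(y_te, y_pred)
    return SelectionRun(
        algorithm=algorithm,
        seed=seed,
        split_seed=split_seed,
        mask=mask,
        n_selected=int(mask.sum()),
        n_features=D,
        best_fitness=float(result.best_fitness),
        trace=result.trace,
        metrics=metrics,
        elapsed=time.perf_counter() - t0,
        n_test=len(y_te),
        train_index=train_idx,
        test_index=test_idx,
    )


def run_repeated_experiment(
    data: pd.DataFrame,
    algorithm: str = "shosca",
    fitness_cfg: FitnessConfig = FitnessConfig(),
    P: int = 10,
    T: int = 50,
    runs: int = 25,
    base_seed: int = 0,
    sho_cfg: optimizers.SHOConfig | None = None,
    sca_cfg: optimizers.SCAConfig | None = None,
    classifier: str = "knn",
    rf_trees: int = 100,
) -> ExperimentReport:
    """R independent selection runs with fresh per-run stratified splits.

    Run r uses split seed ``base_seed + r`` and optimizer seed derived from
    ``(base_seed, r)``, so two algorithms launched with the same
    ``base_seed`` see identical splits run-for-run (paired blocks).
    """
    if runs < 2:
        raise ValueError(f"need >= 2 runs, got {runs}")
    out = []
    for r in range(runs):
        opt_seed = int(np.random.SeedSequence([base_seed, r]).generate_state(1)[0] % (2**31))
        out.append(
            select_features(
                data,
                algorithm=algorithm,
                fitness_cfg=fitness_cfg,
                P=P,
                T=T,
                seed=opt_seed,
                split_seed=base_seed + r,
                sho_cfg=sho_cfg,
                sca_cfg=sca_cfg,
                classifier=classifier,
                rf_trees=rf_trees,
            )
        )
    config = {
        "algorithm": algorithm,
        "P": P,
        "T": T,
        "runs": runs,
        "base_seed": base_seed,
        "alpha": fitness_cfg.alpha,
        "threshold": fitness_cfg.threshold,
        "k": fitness_cfg.k,
        "classifier": classifier,
        "rf_trees": rf_trees,
    }
    return ExperimentReport(algorithm, out, aggregate_run_metrics(out), config)


#: metric name -> (attribute getter, lower_is_better) for Friedman blocks
_FRIEDMAN_METRICS = {
    "feat_size": (lambda r: r.n_selected, True),
    "accuracy": (lambda r: r.metrics.accuracy, False),
    "precision": (lambda r: r.metrics.precision, False),
    "recall": (lambda r: r.metrics.recall, False),
    "f1": (lambda r: r.metrics.f1, False),
    "cpu_time": (lambda r: r.elapsed, True),
    "fitness": (lambda r: r.best_fitness, True),
}


def compare_algorithms(
    data: pd.DataFrame,
    algorithms: list[str],
    runs: int = 25,
    base_seed: int = 0,
    **kwargs,
) -> tuple[list[ExperimentReport], dict]:
    """Aligned repeated experiments plus per-metric Friedman ranking.

    All algorithms share per-run split seeds (paired blocks).  Returns the
    per-algorithm reports and a dict of FriedmanResult per metric.
    """
    from .evaluation import friedman_ranks

    if len(algorithms) < 2:
        raise ValueError("need at least two algorithms to compare")
    reports = [
        run_repeated_experiment(data, algorithm=alg, runs=runs, base_seed=base_seed, **kwargs)
        for alg in algorithms
    ]
    friedman = {}
    for metric, (getter, lower) in _FRIEDMAN_METRICS.items():
        table = np.column_stack([[getter(r) for r in rep.runs] for rep in reports])
        friedman[metric] = friedman_ranks(table, algorithms, lower_is_better=lower)
    return reports, friedman
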