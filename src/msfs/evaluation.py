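"""Classification metrics, repeated-run aggregates, Friedman ranking and
report export.

The positive class throughout is the MS/lesioned label (1): precision and
recall are single-class quantities unless ``macro=True`` is requested.
Aggregates over a repeated experiment follow the usual conventions for
stochastic optimizers: mean accuracy pooled over runs and test samples,
mean/best/worst of the per-run best fitness, sample standard deviation
(divisor R−1), and the average selected-subset size both as a raw feature
count and as a fraction of D.

The Friedman test ranks algorithms within each block (run), averages the
ranks and forms the tie-corrected chi-square statistic

    χ² = [12/(R·k·(k+1)) · Σ_j S_j² − 3R(k+1)] / (1 − ΣT/(R·k·(k²−1)))

with S_j the rank sum of algorithm j and T = Σ(t³−t) over tie groups,
referred to a chi-square distribution with k−1 degrees of freedom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "FriedmanResult",
    "confusion_counts",
    "classification_metrics",
    "aggregate_run_metrics",
    "friedman_ranks",
    "export_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float
    precision_degenerate: bool = False  # no positive predictions
    recall_degenerate: bool = False  # no positive labels


def confusion_counts(y_true, y_pred, positive: int = 1) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("empty prediction vector")
    tp = int(np.sum((y_pred == positive) & (y_true == positive)))
    fp = int(np.sum((y_pred == positive) & (y_true != positive)))
    fn = int(np.sum((y_pred != positive) & (y_true == positive)))
    tn = int(np.sum((y_pred != positive) & (y_true != positive)))
    return ConfusionCounts(tp, fp, fn, tn)


def _prf(c: ConfusionCounts) -> tuple[float, float, float, bool, bool]:
    p_deg = (c.tp + c.fp) == 0
    r_deg = (c.tp + c.fn) == 0
    precision = 0.0 if p_deg else c.tp / (c.tp + c.fp)
    recall = 0.0 if r_deg else c.tp / (c.tp + c.fn)
    f1 = 0.0 if (precision + recall) == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1, p_deg, r_deg


def classification_metrics(
    y_true, y_pred, positive: int = 1, macro: bool = False
) -> MetricSet:
    """Accuracy, precision, recall and F1 with the MS class (1) as positive.

    Precision (recall) is returned as 0 and flagged when no positive
    predictions (labels) exist.  ``macro=True`` averages precision/recall/F1
    over both classes instead.
    """
    c = confusion_counts(y_true, y_pred, positive)
    accuracy = (c.tp + c.tn) / c.total
    if macro:
        pos = _prf(c)
        neg = _prf(ConfusionCounts(tp=c.tn, fp=c.fn, fn=c.fp, tn=c.tp))
        precision = (pos[0] + neg[0]) / 2
        recall = (pos[1] + neg[1]) / 2
        f1 = (pos[2] + neg[2]) / 2
        return MetricSet(accuracy, precision, recall, f1, pos[3] or neg[3], pos[4] or neg[4])
    precision, recall, f1, p_deg, r_deg = _prf(c)
    return MetricSet(accuracy, precision, recall, f1, p_deg, r_deg)


def aggregate_run_metrics(runs) -> dict:
    """Aggregate a collection of selection runs (>= 2).

    Mean accuracy pools correct predictions over runs and test samples
    (reduces to the mean of per-run accuracies when test sizes are equal);
    fitness aggregates use the per-run best fitness; the selected-size mean
    is reported both as a raw count and as a fraction of D.
    """
    runs = list(runs)
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to aggregate")
    fits = np.array([r.best_fitness for r in runs])
    sizes = np.array([r.n_selected for r in runs], dtype=float)
    D = runs[0].n_features
    test_sizes = np.array([r.n_test for r in runs], dtype=float)
    acc = np.array([r.metrics.accuracy for r in runs])
    return {
        "n_runs": len(runs),
        "feat_size_mean": float(sizes.mean()),
        "feat_ratio_mean": float((sizes / D).mean()),
        "accuracy_mean": float(np.average(acc, weights=test_sizes)),
        "precision_mean": float(np.mean([r.metrics.precision for r in runs])),
        "recall_mean": float(np.mean([r.metrics.recall for r in runs])),
        "f1_mean": float(np.mean([r.metrics.f1 for r in runs])),
        "time_mean": float(np.mean([r.elapsed for r in runs])),
        "fitness_mean": float(fits.mean()),
        "fitness_std": float(fits.std(ddof=1)),
        "fitness_best": float(fits.min()),
        "fitness_worst": float(fits.max()),
    }


@dataclass(frozen=True)
class FriedmanResult:
    algorithms: tuple[str, ...]
    mean_ranks: dict
    chi_square: float
    p_value: float
    blocks: int


def friedman_ranks(
    values: np.ndarray, algorithms: list[str], lower_is_better: bool = False
) -> FriedmanResult:
    """Friedman test on a blocks x algorithms matrix of one metric.

    Rank 1 is best within each block; ties share their mean rank.  The
    statistic uses the tie-corrected chi-square form; a table in which all
    algorithms coincide in every block yields statistic 0 and p = 1.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("values must be a 2-D (blocks x algorithms) matrix")
    R, k = values.shape
    if k < 2 or R < 2:
        raise ValueError(f"need >= 2 algorithms and >= 2 blocks, got shape {values.shape}")
    if len(algorithms) != k:
        raise ValueError("one algorithm name per column required")
    if np.any(~np.isfinite(values)):
        raise ValueError("missing or non-finite cells in the metric matrix")
    signed = values if lower_is_better else -values
    ranks = np.apply_along_axis(rankdata, 1, signed)
    rank_sums = ranks.sum(axis=0)
    numerator = 12.0 / (R * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * R * (k + 1)
    ties = 0.0
    for row in signed:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (R * k * (k**2 - 1))
    if abs(numerator) < 1e-12 or correction <= 0:
        stat = 0.0
    else:
        stat = numerator / correction
    p = float(chi2.sf(stat, k - 1)) if stat > 0 else 1.0
    mean_ranks = {name: float(m) for name, m in zip(algorithms, ranks.mean(axis=0))}
    return FriedmanResult(tuple(algorithms), mean_ranks, float(stat), p, R)


_AGG_COLUMNS = [
    ("FeatSize", "feat_size_mean"),
    ("Acc", "accuracy_mean"),
    ("Prec", "precision_mean"),
    ("Rec", "recall_mean"),
    ("F1Score", "f1_mean"),
    ("CPUTime", "time_mean"),
    ("Avrfit", "fitness_mean"),
    ("Stdfit", "fitness_std"),
    ("Bestfit", "fitness_best"),
    ("Worstfit", "fitness_worst"),
]


def _run_record(run) -> dict:
    return {
        "algorithm": run.algorithm,
        "seed": run.seed,
        "split_seed": run.split_seed,
        "mask": "".join("1" if b else "0" for b in run.mask),
        "n_selected": int(run.n_selected),
        "n_features": int(run.n_features),
        "best_fitness": float(run.best_fitness),
        "accuracy": float(run.metrics.accuracy),
        "precision": float(run.metrics.precision),
        "recall": float(run.metrics.recall),
        "f1": float(run.metrics.f1),
        "elapsed": float(run.elapsed),
    }


def export_report(reports, out_dir, friedman: dict | None = None) -> dict:
    """Write aggregate CSV, per-run JSON, convergence and boxplot CSVs.

    ``reports`` is one experiment report or a list of them (one per
    algorithm).  Returns the mapping of artifact names to paths.
    """
    if not isinstance(reports, (list, tuple)):
        reports = [reports]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    agg_rows = []
    run_records = []
    conv_rows = []
    box_rows = []
    for rep in reports:
        row = {"Algorithm": rep.algorithm}
        row.update({col: rep.aggregates[key] for col, key in _AGG_COLUMNS})
        agg_rows.append(row)
        for r_idx, run in enumerate(rep.runs):
            run_records.append(_run_record(run))
            for it, fit in enumerate(run.trace):
                conv_rows.append(
                    {
                        "algorithm": rep.algorithm,
                        "run": r_idx,
                        "iteration": it,
                        "best_fitness": float(fit),
                    }
                )
            box_rows.append(
                {
                    "algorithm": rep.algorithm,
                    "run": r_idx,
                    "accuracy": run.metrics.accuracy,
                    "precision": run.metrics.precision,
                    "recall": run.metrics.recall,
                    "f1": run.metrics.f1,
                    "best_fitness": run.best_fitness,
                    "n_selected": run.n_selected,
                }
            )
    paths = {
        "aggregate": out_dir / "aggregate.csv",
        "runs": out_dir / "runs.json",
        "convergence": out_dir / "convergence.csv",
        "boxplot": out_dir / "boxplot.csv",
    }
    pd.DataFrame(agg_rows).to_csv(paths["aggregate"], index=False)
    paths["runs"].write_text(json.dumps(run_records, indent=2))
    pd.DataFrame(conv_rows).to_csv(paths["convergence"], index=False)
    pd.DataFrame(box_rows).to_csv(paths["boxplot"], index=False)
    if friedman is not None:
        paths["friedman"] = out_dir / "friedman.json"
        payload = {
            metric: {
                "mean_ranks": res.mean_ranks,
                "chi_square": res.chi_square,
                "p_value": res.p_value,
                "blocks": res.blocks,
            }
            for metric, res in friedman.items()
        }
        paths["friedman"].write_text(json.dumps(payload, indent=2))
    return paths
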