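"""Native / cross-pair prediction matrix and formula-defined performance measures.

Every model (pair i, algorithm, trial t) predicts the held-out test half of
trial t for its own pair (a *native* record) and for every other pair j != i
(a *cross* record), so a library of n pairs produces n^2 records per
(algorithm, trial): n native plus n*(n-1) cross.  Each record stores its
confusion counts (positive class = DT) and five measures:

    BA        = (TPR + TNR) / 2
    MCC       = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    F1        = 2*TP / (2*TP + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)

Measures whose denominator vanishes are recorded as missing (None) rather
than zero so that distribution summaries are not silently biased; MCC with a
zero marginal is the one exception, reported as 0 with a degeneracy flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from promisig.assembly import SplitTrial, TargetPair
from promisig.models import FittedClassifier

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "PredictionRecord",
    "PairData",
    "SummaryStats",
    "UndefinedMetricError",
    "OrchestrationError",
    "balanced_accuracy",
    "mcc",
    "f1",
    "precision",
    "recall",
    "run_matrix",
    "count_predictions",
    "count_cross_predictions",
    "family_subsets",
    "summarize",
    "records_to_dataframe",
]

MEASURES = ("ba", "mcc", "f1", "precision", "recall")


class UndefinedMetricError(ZeroDivisionError):
    """A performance measure is undefined for these confusion counts."""


class OrchestrationError(RuntimeError):
    """The model/dataset grid passed to run_matrix has gaps."""


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with DT as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @staticmethod
    def from_labels(
        y_true: Sequence[int], y_pred: Sequence[int], positive: int = 1
    ) -> "ConfusionCounts":
        yt = np.asarray(y_true)
        yp = np.asarray(y_pred)
        if yt.shape != yp.shape:
            raise ValueError("label arrays differ in length")
        pos = yt == positive
        pred_pos = yp == positive
        return ConfusionCounts(
            tp=int(np.sum(pos & pred_pos)),
            tn=int(np.sum(~pos & ~pred_pos)),
            fp=int(np.sum(~pos & pred_pos)),
            fn=int(np.sum(pos & ~pred_pos)),
        )


def balanced_accuracy(c: ConfusionCounts) -> float:
    """Mean of true-positive and true-negative rates."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise UndefinedMetricError("BA needs at least one instance of each class")
    return 0.5 * (c.tp / (c.tp + c.fn) + c.tn / (c.tn + c.fp))


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a marginal sum vanishes.

    Use :func:`mcc_degenerate` to distinguish a true 0 from the degenerate
    case.
    """
    if mcc_degenerate(c):
        return 0.0
    denom = math.sqrt(
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    return (c.tp * c.tn - c.fp * c.fn) / denom


def mcc_degenerate(c: ConfusionCounts) -> bool:
    """True when any marginal of the confusion table is zero."""
    return 0 in (c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn)


def f1(c: ConfusionCounts) -> float:
    if 2 * c.tp + c.fp + c.fn == 0:
        raise UndefinedMetricError("F1 undefined: no positives in truth or prediction")
    return 2 * c.tp / (2 * c.tp + c.fp + c.fn)


def precision(c: ConfusionCounts) -> float:
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no positive predictions")
    return c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: no positive instances")
    return c.tp / (c.tp + c.fn)


_METRIC_FUNCS = {
    "ba": balanced_accuracy,
    "mcc": mcc,
    "f1": f1,
    "precision": precision,
    "recall": recall,
}


@dataclass(frozen=True)
class MetricSet:
    """The five measures for one prediction run; None marks undefined values."""

    ba: float | None
    mcc: float | None
    f1: float | None
    precision: float | None
    recall: float | None
    mcc_degenerate: bool = False

    @staticmethod
    def from_counts(c: ConfusionCounts) -> "MetricSet":
        values: dict[str, float | None] = {}
        for name, func in _METRIC_FUNCS.items():
            try:
                values[name] = func(c)
            except UndefinedMetricError:
                values[name] = None
        return MetricSet(mcc_degenerate=mcc_degenerate(c), **values)

    def get(self, measure: str) -> float | None:
        return getattr(self, measure)


@dataclass(frozen=True)
class PredictionRecord:
    """Outcome of one model predicting one test set (native or cross)."""

    model_pair_id: str
    test_pair_id: str
    algorithm: str
    trial_index: int
    counts: ConfusionCounts
    metrics: MetricSet

    @property
    def kind(self) -> str:
        return "native" if self.model_pair_id == self.test_pair_id else "cross"


@dataclass
class PairData:
    """Everything the matrix needs about one pair: fingerprints and splits."""

    pair: TargetPair
    compound_ids: list[str]
    X: np.ndarray            # (n, n_bits), row order matches compound_ids
    y: np.ndarray            # +1 DT / -1 ST
    trials: list[SplitTrial]

    def __post_init__(self) -> None:
        self._row = {cid: i for i, cid in enumerate(self.compound_ids)}

    @property
    def pair_id(self) -> str:
        return self.pair.pair_id

    def test_rows(self, trial_index: int) -> np.ndarray:
        ids = self.trials[trial_index].test
        return np.array(sorted(self._row[c] for c in ids))

    def train_rows(self, trial_index: int) -> np.ndarray:
        ids = self.trials[trial_index].train
        return np.array(sorted(self._row[c] for c in ids))


def run_matrix(
    pair_data: Mapping[str, PairData],
    models: Mapping[tuple[str, str, int], FittedClassifier],
    algorithms: Sequence[str],
    n_trials: int,
) -> list[PredictionRecord]:
    """Run all native and cross predictions over pairs, algorithms, trials.

    ``models`` maps (pair_id, algorithm, trial_index) to a fitted model; the
    model of pair i at trial t predicts the test half of trial t of every
    pair's dataset (its own -> native record, others -> cross records), so
    native and cross comparisons at a trial share identical test data.
    """
    pair_ids = sorted(pair_data)
    missing = [
        (p, a, t)
        for p in pair_ids
        for a in algorithms
        for t in range(n_trials)
        if (p, a, t) not in models
    ]
    if missing:
        raise OrchestrationError(f"missing models for: {missing[:10]}" +
                                 (" ..." if len(missing) > 10 else ""))
    records = []
    for algorithm in algorithms:
        for t in range(n_trials):
            for model_pid in pair_ids:
                model = models[(model_pid, algorithm, t)]
                for test_pid in pair_ids:
                    data = pair_data[test_pid]
                    rows = data.test_rows(t)
                    y_pred = model.predict(data.X[rows])
                    c = ConfusionCounts.from_labels(data.y[rows], y_pred)
                    records.append(
                        PredictionRecord(
                            model_pair_id=model_pid,
                            test_pair_id=test_pid,
                            algorithm=algorithm,
                            trial_index=t,
                            counts=c,
                            metrics=MetricSet.from_counts(c),
                        )
                    )
    return records


def count_predictions(n_pairs: int, n_trials: int, n_algorithms: int) -> int:
    """Total native + cross predictions: n_pairs^2 * n_trials * n_algorithms."""
    if min(n_pairs, n_trials, n_algorithms) < 1:
        raise ValueError("all counts must be >= 1")
    return n_pairs * n_pairs * n_trials * n_algorithms


def count_cross_predictions(n_pairs: int) -> int:
    """Entries of the cross-prediction matrix: one per ordered pair (i, j), i != j."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    return n_pairs * (n_pairs - 1)


def family_subsets(
    records: Iterable[PredictionRecord],
    pairs: Mapping[str, TargetPair],
) -> dict[str, list[PredictionRecord]]:
    """Partition cross records by protein-family relation between the pairs.

    ``same``: all four targets share one family; ``different``: the model
    pair's and test pair's family sets are disjoint; ``mixed``: everything
    else (e.g. one shared family plus one differing).  Native records are
    ignored.
    """
    buckets: dict[str, list[PredictionRecord]] = {
        "same": [], "different": [], "mixed": []
    }
    for rec in records:
        if rec.kind != "cross":
            continue
        fam_model = _families(pairs, rec.model_pair_id)
        fam_test = _families(pairs, rec.test_pair_id)
        if len(fam_model | fam_test) == 1:
            buckets["same"].append(rec)
        elif not (fam_model & fam_test):
            buckets["different"].append(rec)
        else:
            buckets["mixed"].append(rec)
    return buckets


def _families(pairs: Mapping[str, TargetPair], pair_id: str) -> frozenset[str]:
    pair = pairs[pair_id]
    for t in (pair.target_a, pair.target_b):
        if not t.family:
            raise ValueError(f"target {t.target_id} has no family label")
    return pair.families


@dataclass(frozen=True)
class SummaryStats:
    """Five-number summary with 1.5*IQR outliers for one (kind, algorithm, measure)."""

    n: int
    n_missing: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    outliers: tuple[float, ...]

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "n_missing": self.n_missing,
            "min": self.min,
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "max": self.max,
            "outliers": list(self.outliers),
        }


def summarize(
    records: Iterable[PredictionRecord],
    measures: Sequence[str] = MEASURES,
) -> dict[tuple[str, str, str], SummaryStats]:
    """Distribution summaries per (kind, algorithm, measure).

    Undefined metric values are excluded and counted in ``n_missing``.
    Outliers are the values outside [q1 - 1.5*IQR, q3 + 1.5*IQR].
    """
    groups: dict[tuple[str, str, str], list[float | None]] = {}
    for rec in records:
        for m in measures:
            groups.setdefault((rec.kind, rec.algorithm, m), []).append(
                rec.metrics.get(m)
            )
    out = {}
    for key, raw in groups.items():
        values = np.array([v for v in raw if v is not None], dtype=float)
        n_missing = len(raw) - values.size
        if values.size == 0:
            continue
        q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        outliers = tuple(float(v) for v in values[(values < lo) | (values > hi)])
        out[key] = SummaryStats(
            n=int(values.size),
            n_missing=int(n_missing),
            min=float(values.min()),
            q1=float(q1),
            median=float(med),
            q3=float(q3),
            max=float(values.max()),
            outliers=outliers,
        )
    return out


def records_to_dataframe(records: Iterable[PredictionRecord]) -> pd.DataFrame:
    """One tidy row per record, metrics as columns (NaN where undefined)."""
    rows = []
    for r in records:
        rows.append(
            {
                "model_pair_id": r.model_pair_id,
                "test_pair_id": r.test_pair_id,
                "algorithm": r.algorithm,
                "trial_index": r.trial_index,
                "kind": r.kind,
                "tp": r.counts.tp,
                "tn": r.counts.tn,
                "fp": r.counts.fp,
                "fn": r.counts.fn,
                **{m: (np.nan if r.metrics.get(m) is None else r.metrics.get(m))
                   for m in MEASURES},
                "mcc_degenerate": r.metrics.mcc_degenerate,
            }
        )
    return pd.DataFrame(rows)
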