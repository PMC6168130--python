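"""Cross-validated evaluation: stratified folds, confusion metrics
(Sn/Sp/Ac/MCC), ROC curves and the area under them.

Folds are stratified by class — with only 36 positives, plain random 10-fold
splits can produce positive-free folds, so "randomly and evenly" is enforced
per class.  Metrics at a threshold are computed on the pooled out-of-fold
scores (micro-averaged), and the frequency model and scaler are refitted
inside each training fold by default so held-out windows never leak into the
feature definition (``leaky=True`` reproduces the fit-once-then-split variant
for comparison).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import sqrt
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn import metrics as _skm

from .dataio import LabeledDataset
from .features import apply_scaler, encode_windows, fit_frequency_model, fit_scaler


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity, specificity, accuracy and Matthews correlation.

    A metric whose denominator is zero is reported as ``None`` (undefined),
    never silently as 0.
    """

    sn: float | None
    sp: float | None
    ac: float | None
    mcc: float | None
    counts: ConfusionCounts | None = None


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Exact confusion metrics.

    Sn = TP/(TP+FN); Sp = TN/(TN+FP); Ac = (TP+TN)/total;
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)).
    Ratios are computed in exact rational arithmetic before conversion.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total == 0:
        return MetricSet(sn=None, sp=None, ac=None, mcc=None, counts=counts)
    sn = float(Fraction(tp, tp + fn)) if tp + fn else None
    sp = float(Fraction(tn, tn + fp)) if tn + fp else None
    ac = float(Fraction(tp + tn, counts.total))
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = (tp * tn - fn * fp) / sqrt(denom) if denom else None
    return MetricSet(sn=sn, sp=sp, ac=ac, mcc=mcc, counts=counts)


def confusion_at_cutoff(
    scores: Sequence[float], labels: Sequence[str], cutoff: float
) -> ConfusionCounts:
    """Confusion table with "positive" predicted when score >= cutoff."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pred = s >= cutoff
    pos = y == "positive"
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


@dataclass
class ROCCurve:
    """ROC points (1-Sp, Sn) swept over distinct cutoffs, ties grouped,
    anchored at (0,0) and (1,1); ``auroc`` by the trapezoidal rule."""

    fpr: np.ndarray
    tpr: np.ndarray
    cutoffs: np.ndarray
    auroc: float


def roc_curve(scores: Sequence[float], labels: Sequence[str]) -> ROCCurve:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == "positive"
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _skm.roc_curve(y.astype(int), s, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, cutoffs=thr, auroc=float(_skm.auc(fpr, tpr)))


def auroc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Area under the ROC; equals the Mann-Whitney statistic with ties at 1/2."""
    return roc_curve(scores, labels).auroc


def split_folds(dataset: LabeledDataset, n_folds: int, seed: int) -> np.ndarray:
    """Stratified fold assignment (one integer in [0, n_folds) per window).

    Within each class the windows are shuffled with the seeded generator and
    dealt round-robin, so per-class fold sizes differ by at most one.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    labels = np.array([w.label for w in dataset.windows])
    assign = np.full(len(labels), -1, dtype=int)
    rng = np.random.default_rng(seed)
    for klass in ("positive", "negative"):
        idx = np.flatnonzero(labels == klass)
        if idx.size < n_folds:
            raise ValueError(
                f"class {klass!r} has {idx.size} windows, fewer than {n_folds} folds"
            )
        perm = rng.permutation(idx)
        assign[perm] = np.arange(perm.size) % n_folds
    return assign


@dataclass
class CVResult:
    """Pooled out-of-fold scores plus the derived curves, cutoffs and metrics."""

    fold_assignment: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    roc: ROCCurve | None
    auroc: float
    thresholds: "ThresholdSet | None"
    metrics_by_level: dict[str, MetricSet]
    n_folds: int
    seed: int


def cross_validate(
    dataset: LabeledDataset,
    config=None,
    n_folds: int = 10,
    seed: int = 42,
    calibrate: bool = True,
    specificity_targets: dict[str, float] | None = None,
    leaky: bool = False,
    pseudocount: float = 0.0,
) -> CVResult:
    """n-fold cross-validation of the full pipeline.

    For each fold the frequency model, scaler and SVM are fitted on the other
    folds and the held-out windows scored, so every window receives exactly
    one out-of-fold score.  Scores are pooled for ROC/AROC; when ``calibrate``
    is set, high/medium/low cutoffs are chosen on the pooled scores and a
    :class:`MetricSet` is reported at each.
    """
    from .model import SVMConfig, calibrate_thresholds  # circular at module level
    from sklearn.svm import SVC

    config = config or SVMConfig(seed=seed)
    windows = dataset.windows
    assign = split_folds(dataset, n_folds, seed)
    labels = np.array([w.label for w in windows])
    scores = np.full(len(windows), np.nan)

    shared_freq = shared_scaler = None
    if leaky:
        shared_freq = fit_frequency_model(windows, pseudocount=pseudocount)
        shared_scaler = fit_scaler(encode_windows(windows, shared_freq))

    for fold in range(n_folds):
        test_ix = np.flatnonzero(assign == fold)
        train_ix = np.flatnonzero(assign != fold)
        train_w = [windows[i] for i in train_ix]
        test_w = [windows[i] for i in test_ix]
        if leaky:
            freq, scaler = shared_freq, shared_scaler
        else:
            freq = fit_frequency_model(train_w, pseudocount=pseudocount)
            scaler = fit_scaler(encode_windows(train_w, freq))
        x_train = apply_scaler(encode_windows(train_w, freq), scaler)
        y_train = (labels[train_ix] == "positive").astype(int)
        svc = SVC(
            kernel=config.kernel,
            C=config.C,
            gamma=config.gamma,
            class_weight=config.class_weight,
            random_state=config.seed,
        )
        svc.fit(x_train, y_train)
        x_test = apply_scaler(encode_windows(test_w, freq), scaler)
        scores[test_ix] = svc.decision_function(x_test)

    assert not np.isnan(scores).any(), "every window must be scored exactly once"
    roc = roc_curve(scores, labels)
    thresholds = None
    metrics_by_level: dict[str, MetricSet] = {}
    if calibrate:
        thresholds = calibrate_thresholds(scores, labels, specificity_targets)
        for level, t in thresholds.thresholds.items():
            metrics_by_level[level] = compute_metrics(
                confusion_at_cutoff(scores, labels, t.cutoff)
            )
    return CVResult(
        fold_assignment=assign,
        scores=scores,
        labels=labels,
        roc=roc,
        auroc=roc.auroc,
        thresholds=thresholds,
        metrics_by_level=metrics_by_level,
        n_folds=n_folds,
        seed=seed,
    )


def export_scores_tsv(result: CVResult, dataset: LabeledDataset, path: str | Path) -> None:
    """Per-window out-of-fold scores as TSV."""
    with open(path, "w") as fh:
        fh.write("accession\tposition\tlabel\tfold\tscore\n")
        for w, fold, score in zip(dataset.windows, result.fold_assignment, result.scores):
            fh.write(f"{w.accession}\t{w.position}\t{w.label}\t{fold}\t{score:.6f}\n")


def export_summary_tsv(results: dict[int, CVResult], path: str | Path) -> None:
    """Summary table (one row per n-fold x threshold level) with Sn, Sp, Ac,
    MCC and AROC as percentages/values."""
    with open(path, "w") as fh:
        fh.write("n_fold\tthreshold\tSn\tSp\tAc\tMCC\tAROC\n")
        for n_fold in sorted(results):
            r = results[n_fold]
            for level, m in r.metrics_by_level.items():
                fh.write(
                    f"{n_fold}\t{level}\t{100 * m.sn:.2f}\t{100 * m.sp:.2f}\t"
                    f"{100 * m.ac:.2f}\t{m.mcc:.4f}\t{r.auroc:.4f}\n"
                )
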