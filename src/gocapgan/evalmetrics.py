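"""Repeated k-fold evaluation and multi-label metrics.

Precision, recall and F1 are computed from pooled (micro) or per-class
(macro) confusion counts; Hamming loss is the fraction of protein x class
label slots where prediction and truth disagree.  The cross-validation plan
is plain shuffled k-fold (k=3) repeated R=5 times with reshuffling, the
published evaluation protocol for this pipeline.  Zero denominators yield 0
and the affected classes are flagged in the report rather than propagating
NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .funcpred import (ClassifierConfig, FeatureMatrix, LabelMatrix,
                       predict_labels, train_classifier)

__all__ = [
    "FoldPlan",
    "ConfusionCounts",
    "MetricsReport",
    "plan_repeated_kfold",
    "confusion",
    "precision_recall_f1",
    "f1_from_precision_recall",
    "hamming_loss",
    "evaluate_cv",
]


@dataclass
class FoldPlan:
    """assignments[r][f] is the held-out index array of fold f in repeat r."""

    assignments: list
    n: int
    k: int
    repeats: int
    seed: int

    def check(self) -> None:
        for folds in self.assignments:
            cat = np.concatenate(folds)
            if len(cat) != self.n or len(np.unique(cat)) != self.n:
                raise AssertionError("folds do not partition the index set")
            sizes = [len(f) for f in folds]
            if max(sizes) - min(sizes) > 1:
                raise AssertionError("fold sizes differ by more than one")


def plan_repeated_kfold(n: int, k: int = 3, repeats: int = 5,
                        seed: int = 0) -> FoldPlan:
    """Shuffled k-fold partition per repeat; deterministic given seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split n={n} samples into k={k} folds")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(repeats):
        perm = rng.permutation(n)
        assignments.append([np.sort(f) for f in np.array_split(perm, k)])
    return FoldPlan(assignments=assignments, n=n, k=k, repeats=repeats, seed=seed)


@dataclass
class ConfusionCounts:
    """Per-class and pooled tp/fp/fn/tn over label slots."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def pooled(self) -> tuple:
        return (int(self.tp.sum()), int(self.fp.sum()),
                int(self.fn.sum()), int(self.tn.sum()))


def _as_binary(m, name: str) -> np.ndarray:
    a = m.Y if isinstance(m, LabelMatrix) else np.asarray(m)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary")
    return a.astype(np.float64)


def confusion(y_true, y_pred) -> ConfusionCounts:
    yt = _as_binary(y_true, "y_true")
    yp = _as_binary(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise ValueError(f"shape mismatch: {yt.shape} vs {yp.shape}")
    return ConfusionCounts(
        tp=(yt * yp).sum(axis=0),
        fp=((1 - yt) * yp).sum(axis=0),
        fn=(yt * (1 - yp)).sum(axis=0),
        tn=((1 - yt) * (1 - yp)).sum(axis=0),
    )


def _prf(tp, fp, fn):
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1


def precision_recall_f1(counts: ConfusionCounts, mode: str = "micro") -> tuple:
    """precision = tp/(tp+fp); recall = tp/(tp+fn); F1 = their harmonic mean.

    micro pools counts over classes first; macro averages per-class values.
    """
    if mode == "micro":
        tp, fp, fn, _ = counts.pooled
        return _prf(tp, fp, fn)
    if mode == "macro":
        per = [_prf(t, p, n) for t, p, n in zip(counts.tp, counts.fp, counts.fn)]
        arr = np.array(per)
        return tuple(arr.mean(axis=0))
    raise ValueError("mode must be 'micro' or 'macro'")


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """F1 = 2 * precision * recall / (precision + recall); 0 when both are 0."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be nonnegative")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def hamming_loss(y_true, y_pred) -> float:
    """Fraction of label slots where prediction and truth differ (XOR mean)."""
    yt = _as_binary(y_true, "y_true")
    yp = _as_binary(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise ValueError(f"shape mismatch: {yt.shape} vs {yp.shape}")
    return float(np.abs(yt - yp).mean())


@dataclass
class MetricsReport:
    """Per-fold metric table plus mean +/- sd aggregates."""

    per_fold: pd.DataFrame
    mode: str
    flagged_classes: list = field(default_factory=list)

    @property
    def mean(self) -> dict:
        return self.per_fold[["precision", "recall", "f1", "hamming"]].mean().to_dict()

    @property
    def sd(self) -> dict:
        return self.per_fold[["precision", "recall", "f1", "hamming"]].std(ddof=1).to_dict()

    def summary(self) -> dict:
        mean = {k: float(v) for k, v in self.mean.items()}
        # label-slot accuracy: the complement of the Hamming loss
        mean["accuracy"] = 1.0 - mean["hamming"]
        return {
            "mode": self.mode,
            "n_evaluations": int(len(self.per_fold)),
            "mean": mean,
            "sd": {k: float(v) for k, v in self.sd.items()},
            "flagged_classes": sorted(set(map(str, self.flagged_classes))),
        }

    def write(self, tsv_path=None, json_path=None) -> None:
        if tsv_path is not None:
            self.per_fold.to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            import json as _json
            from pathlib import Path
            Path(json_path).write_text(_json.dumps(self.summary(), indent=2))


def evaluate_cv(features, labels, plan: FoldPlan,
                clf_config: ClassifierConfig | None = None,
                mode: str = "micro") -> MetricsReport:
    """Train/evaluate over every (repeat, fold) pair of the plan.

    Per fold: fit the classifier on the other k-1 folds, predict the held-out
    fold, compute precision/recall/F1 and Hamming loss.  Classifier seeds are
    derived from the plan seed, so the whole report is deterministic.
    """
    cfg = clf_config or ClassifierConfig()
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    Y = labels.Y if isinstance(labels, LabelMatrix) else np.asarray(labels, dtype=np.float64)
    classes = labels.classes if isinstance(labels, LabelMatrix) else list(range(Y.shape[1]))
    if X.shape[0] != Y.shape[0] or X.shape[0] != plan.n:
        raise ValueError("features, labels and fold plan are not aligned")
    rows = []
    flagged = set()
    for r, folds in enumerate(plan.assignments):
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(plan.n), test_idx)
            fold_seed = (plan.seed + 9973 * (r * plan.k + f) + 1) % (2**31)
            fold_cfg = replace(cfg, seed=fold_seed)
            model = train_classifier(
                FeatureMatrix(X[train_idx], accessions=[str(i) for i in train_idx]),
                LabelMatrix(Y[train_idx], classes=classes),
                fold_cfg,
            )
            pred = predict_labels(model, X[test_idx])
            counts = confusion(Y[test_idx], pred.Y)
            for j, go in enumerate(classes):
                if counts.tp[j] + counts.fn[j] == 0 or counts.tp[j] + counts.fp[j] == 0:
                    flagged.add(go)
            p, rec, f1 = precision_recall_f1(counts, mode=mode)
            rows.append({
                "repeat": r, "fold": f, "n_test": len(test_idx),
                "precision": p, "recall": rec, "f1": f1,
                "hamming": hamming_loss(Y[test_idx], pred.Y),
            })
    return MetricsReport(per_fold=pd.DataFrame(rows), mode=mode,
                         flagged_classes=sorted(flagged))
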