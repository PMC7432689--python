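"""Classification metrics, stratified cross-validation, and McNemar's test.

Metric definitions (lncRNA = positive class):
ACC = (TP+TN)/total, Sn = TP/(TP+FN), Sp = TN/(TN+FP),
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .model import ModelConfig, Prediction, train_model
from .sequence_io import LabeledDataset


@dataclass(frozen=True)
class ConfusionCounts:
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


@dataclass(frozen=True)
class MetricSet:
    acc: float
    sn: float
    sp: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.acc, "Sn": self.sn, "Sp": self.sp, "MCC": self.mcc}


def _labels_of(preds: Sequence[Prediction] | Sequence[int] | np.ndarray) -> np.ndarray:
    if len(preds) and isinstance(preds[0], Prediction):
        return np.array([p.label for p in preds], dtype=np.int64)
    return np.asarray(preds, dtype=np.int64)


def confusion(preds: Sequence[Prediction] | Sequence[int],
              labels: Sequence[int] | np.ndarray) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with lncRNA (1) as the positive class."""
    yhat = _labels_of(preds)
    y = np.asarray(labels, dtype=np.int64)
    if yhat.shape != y.shape:
        raise ValueError(f"length mismatch: {yhat.shape} predictions vs {y.shape} labels")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    return ConfusionCounts(
        tp=int(((yhat == 1) & (y == 1)).sum()),
        tn=int(((yhat == 0) & (y == 0)).sum()),
        fp=int(((yhat == 1) & (y == 0)).sum()),
        fn=int(((yhat == 0) & (y == 1)).sum()),
    )


def metrics(c: ConfusionCounts) -> MetricSet:
    """ACC/Sn/Sp/MCC from confusion counts; MCC is 0 when its denominator
    has a zero factor (the formula is undefined there)."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("Sn/Sp undefined: one class is absent")
    acc = (c.tp + c.tn) / c.total
    sn = c.tp / (c.tp + c.fn)
    sp = c.tn / (c.tn + c.fp)
    denom = math.sqrt(float(c.tp + c.fp) * (c.tp + c.fn)
                      * (c.tn + c.fp) * (c.tn + c.fn))
    mcc = (c.tp * c.tn - c.fp * c.fn) / denom if denom > 0 else 0.0
    return MetricSet(acc=acc, sn=sn, sp=sp, mcc=mcc)


@dataclass
class McNemarResult:
    b: int            # first classifier correct, second wrong
    c: int            # first classifier wrong, second correct
    statistic: float  # chi-square statistic (nan for the exact branch)
    p_value: float
    method: str       # "exact-binomial" | "chi-square" | "degenerate"


def mcnemar(preds_a: Sequence[Prediction] | Sequence[int],
            preds_b: Sequence[Prediction] | Sequence[int],
            labels: Sequence[int] | np.ndarray,
            exact_threshold: int = 25) -> McNemarResult:
    """Paired comparison on the discordant counts (b, c).

    Exact two-sided binomial when b + c < ``exact_threshold``, otherwise
    the continuity-corrected chi-square (|b-c|-1)^2/(b+c) on 1 df.
    """
    a = _labels_of(preds_a)
    bb = _labels_of(preds_b)
    y = np.asarray(labels, dtype=np.int64)
    if not (a.shape == bb.shape == y.shape):
        raise ValueError("preds_a, preds_b and labels must have equal length")
    correct_a = a == y
    correct_b = bb == y
    b = int((correct_a & ~correct_b).sum())
    c = int((~correct_a & correct_b).sum())
    n = b + c
    if n == 0:
        return McNemarResult(b=0, c=0, statistic=float("nan"), p_value=1.0,
                             method="degenerate")
    if n < exact_threshold:
        p = float(stats.binomtest(min(b, c), n, 0.5, alternative="two-sided").pvalue)
        return McNemarResult(b=b, c=c, statistic=float("nan"),
                             p_value=min(p, 1.0), method="exact-binomial")
    statistic = (abs(b - c) - 1) ** 2 / n
    p = float(stats.chi2.sf(statistic, df=1))
    return McNemarResult(b=b, c=c, statistic=statistic, p_value=p,
                         method="chi-square")


def stratified_folds(labels: np.ndarray, folds: int,
                     seed: int) -> list[np.ndarray]:
    """Seeded stratified fold assignment; returns per-fold test index arrays
    that partition the dataset with near-equal class counts per fold."""
    labels = np.asarray(labels)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    assignments = np.empty(len(labels), dtype=np.int64)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < folds:
            raise ValueError(
                f"class {cls} has {len(idx)} members, fewer than {folds} folds")
        idx = rng.permutation(idx)
        assignments[idx] = np.arange(len(idx)) % folds
    return [np.flatnonzero(assignments == f) for f in range(folds)]


@dataclass
class CVReport:
    fold_metrics: list[MetricSet]
    seed: int

    @property
    def folds(self) -> int:
        return len(self.fold_metrics)

    def summary(self) -> dict[str, tuple[float, float]]:
        """Per-metric (mean, sd) across folds; sd uses the n denominator."""
        out = {}
        for name in ("ACC", "Sn", "Sp", "MCC"):
            vals = np.array([m.as_dict()[name] for m in self.fold_metrics])
            out[name] = (float(vals.mean()), float(vals.std()))
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("fold\tACC\tSn\tSp\tMCC\n")
            for i, m in enumerate(self.fold_metrics):
                fh.write(f"{i}\t{m.acc:.6f}\t{m.sn:.6f}\t{m.sp:.6f}\t{m.mcc:.6f}\n")
            s = self.summary()
            fh.write("mean±sd\t" + "\t".join(
                f"{s[k][0]:.6f}±{s[k][1]:.6f}" for k in ("ACC", "Sn", "Sp", "MCC"))
                + "\n")


def cross_validate(data: LabeledDataset, config: ModelConfig,
                   folds: int = 10, seed: int = 0,
                   collect_tables: list | None = None) -> CVReport:
    """Stratified k-fold CV with the full two-step training schedule.

    The hexamer table and OFH standardization are re-fitted from each
    fold's training partition only (no leakage).  ``collect_tables``, when
    given, receives each fold's hexamer-table fingerprint.
    """
    fold_idx = stratified_folds(data.labels, folds, seed)
    fold_metrics: list[MetricSet] = []
    all_idx = np.arange(len(data))
    for f, test_idx in enumerate(fold_idx):
        train_idx = np.setdiff1d(all_idx, test_idx)
        train_set = data.subset(train_idx)
        test_set = data.subset(test_idx)
        model = train_model(train_set, config)
        if collect_tables is not None:
            collect_tables.append(model.encoder.hexamer_table.fingerprint())
        preds = model.predict(test_set.transcripts)
        fold_metrics.append(metrics(confusion(preds, test_set.labels)))
    return CVReport(fold_metrics=fold_metrics, seed=seed)
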