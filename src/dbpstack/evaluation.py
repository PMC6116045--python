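"""Metrics, cross-validation schemes and coefficient significance analysis.

Metrics follow the standard binary-classification definitions:
SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/total and the Matthews
correlation coefficient with the four-factor product under one square
root. Any metric whose denominator is zero is defined as 0.

Cross-validation schemes: stratified k-fold (per-fold and pooled metrics),
leave-one-out (metrics pooled over all held-out predictions — per-fold
metrics are undefined for single samples), and repeated r x k CV (mean and
population standard deviation of each metric across the r run-level
results). Each fold trains a full stacked model; the meta-coefficients
collected across folds feed a one-sample t-test against zero per base
model, reported with the distance ``alpha - p`` (positive = significant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from . import stacking
from .stacking import BaseModelSpec, StackedModel


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    sn: float
    sp: float
    acc: float
    mcc: float

    def as_dict(self) -> dict:
        return {"sn": self.sn, "sp": self.sp, "acc": self.acc, "mcc": self.mcc}


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """SN, SP, ACC and MCC from confusion counts (zero denominators -> 0)."""
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    acc = (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else 0.0
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=mcc)


@dataclass(frozen=True)
class CvScheme:
    """``kfold`` (k folds), ``loo``, or ``repeated`` (repeats x k)."""

    kind: str = "kfold"
    k: int = 5
    repeats: int = 5

    def __post_init__(self) -> None:
        if self.kind not in ("kfold", "loo", "repeated"):
            raise ValueError(f"unknown CV scheme {self.kind!r}")
        if self.kind != "loo" and self.k < 2:
            raise ValueError("k must be >= 2")
        if self.kind == "repeated" and self.repeats < 2:
            raise ValueError("repeated CV needs >= 2 repeats")

    @classmethod
    def parse(cls, text: str) -> "CvScheme":
        """Parse ``loo``, ``kfold:5`` or ``repeated:5x5``."""
        if text == "loo":
            return cls("loo")
        kind, _, arg = text.partition(":")
        if kind == "kfold":
            return cls("kfold", k=int(arg or 5))
        if kind == "repeated":
            r, _, k = arg.partition("x")
            return cls("repeated", k=int(k or 5), repeats=int(r or 5))
        raise ValueError(f"unknown CV scheme {text!r}")


@dataclass(eq=False)
class CoefficientReport:
    """Meta-coefficient vectors (intercept first) collected across folds."""

    model_names: list[tuple[str, str]]
    fold_thetas: np.ndarray  # folds x (N + 1)

    @property
    def n_folds(self) -> int:
        return self.fold_thetas.shape[0]

    def slopes(self) -> np.ndarray:
        return self.fold_thetas[:, 1:]


@dataclass(eq=False)
class CvResult:
    scheme: CvScheme
    pooled: MetricSet
    pooled_counts: ConfusionCounts
    per_fold: Optional[list[MetricSet]]
    coefficient_report: Optional[CoefficientReport]
    per_run: Optional[list[MetricSet]] = None
    run_mean: Optional[dict] = None
    run_std: Optional[dict] = None


def _subset(blocks: Mapping[str, np.ndarray], idx) -> dict:
    return {name: np.asarray(x, float)[idx] for name, x in blocks.items()}


def _fold_splits(y: np.ndarray, scheme: CvScheme, seed: int):
    if scheme.kind == "loo":
        return list(LeaveOneOut().split(np.zeros((y.size, 1)), y))
    if scheme.k > y.size:
        raise ValueError(f"k={scheme.k} exceeds the {y.size} samples")
    return list(
        StratifiedKFold(n_splits=scheme.k, shuffle=True, random_state=seed).split(
            np.zeros((y.size, 1)), y
        )
    )


def _run_folds(blocks, y, specs, splits, seed, k_inner, oof, freeze_grids):
    counts = ConfusionCounts(0, 0, 0, 0)
    per_fold: list[MetricSet] = []
    thetas: list[np.ndarray] = []
    for train, test in splits:
        model = stacking.fit_stacked(
            _subset(blocks, train),
            y[train],
            specs,
            k=min(k_inner, int(np.unique(y[train], return_counts=True)[1].min())),
            seed=seed,
            oof=oof,
            freeze_grids=freeze_grids,
        )
        _, pred = stacking.predict(model, _subset(blocks, test))
        fold_counts = confusion_from_predictions(y[test], pred)
        counts = counts + fold_counts
        thetas.append(model.theta)
        if len(test) > 1:
            per_fold.append(compute_metrics(fold_counts))
    return counts, per_fold, np.vstack(thetas)


def run_cv(
    blocks: Mapping[str, np.ndarray],
    y,
    specs: Sequence[BaseModelSpec],
    scheme: CvScheme,
    seed: int = 0,
    k_inner: int = 5,
    oof: bool = True,
    freeze_grids: bool = True,
) -> CvResult:
    """Cross-validate the stacked pipeline under ``scheme``.

    Every fold trains a complete stacked model from scratch on the training
    split and predicts the held-out split; pooled metrics come from the
    summed confusion counts.
    """
    y = np.asarray(y, dtype=int)
    model_names = [(s.classifier_kind, s.feature_block) for s in specs]
    if scheme.kind == "repeated":
        rng = np.random.SeedSequence(seed)
        run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(scheme.repeats)]
        per_run: list[MetricSet] = []
        total = ConfusionCounts(0, 0, 0, 0)
        all_thetas = []
        for run_seed in run_seeds:
            splits = _fold_splits(y, CvScheme("kfold", scheme.k), run_seed)
            counts, _, thetas = _run_folds(
                blocks, y, specs, splits, run_seed, k_inner, oof, freeze_grids
            )
            per_run.append(compute_metrics(counts))
            total = total + counts
            all_thetas.append(thetas)
        metric_arrays = {
            name: np.array([m.as_dict()[name] for m in per_run])
            for name in ("sn", "sp", "acc", "mcc")
        }
        return CvResult(
            scheme=scheme,
            pooled=compute_metrics(total),
            pooled_counts=total,
            per_fold=None,
            coefficient_report=CoefficientReport(model_names, np.vstack(all_thetas)),
            per_run=per_run,
            run_mean={k: float(v.mean()) for k, v in metric_arrays.items()},
            run_std={k: float(v.std()) for k, v in metric_arrays.items()},
        )
    splits = _fold_splits(y, scheme, seed)
    counts, per_fold, thetas = _run_folds(
        blocks, y, specs, splits, seed, k_inner, oof, freeze_grids
    )
    return CvResult(
        scheme=scheme,
        pooled=compute_metrics(counts),
        pooled_counts=counts,
        per_fold=per_fold if scheme.kind == "kfold" else None,
        coefficient_report=CoefficientReport(model_names, thetas),
    )


def coefficient_ttest(report: CoefficientReport, alpha: float = 0.05) -> list[dict]:
    """One-sample two-sided t-test of each base model's meta-coefficient
    across folds against zero.

    Zero spread with a nonzero mean is a degenerate-variance case: reported
    with p = 0 and flagged. ``distance = alpha - p`` (positive means the
    coefficient is significantly nonzero at level ``alpha``).
    """
    if report.n_folds < 2:
        raise ValueError("need >= 2 folds for a t-test")
    out = []
    slopes = report.slopes()
    for j, name in enumerate(report.model_names):
        coefs = slopes[:, j]
        mean = float(coefs.mean())
        sd = float(coefs.std(ddof=1))
        degenerate = sd == 0.0
        if degenerate:
            t = math.inf if mean > 0 else (-math.inf if mean < 0 else 0.0)
            p = 0.0 if mean != 0 else 1.0
        else:
            t, p = stats.ttest_1samp(coefs, 0.0)
            t, p = float(t), float(p)
        out.append(
            {
                "classifier": name[0],
                "feature_block": name[1],
                "mean": mean,
                "std": sd,
                "t": t,
                "p": p,
                "distance": alpha - p,
                "degenerate_variance": degenerate,
            }
        )
    return out
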