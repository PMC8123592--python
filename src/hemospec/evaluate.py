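"""Data splitting and classification metrics.

Two holdout splitting schemes are supported, mirroring how stain data can
leak between partitions:

* sample-based -- whole stains travel together: 70% of stains (per class /
  day / substrate stratum) form the training pool, 30% the external test
  set, and 20% of training-pool stains are held out for internal
  validation;
* pixel-based -- every stain is split: per stain, 70% of pixels to the
  training pool (of which 20% internal validation) and 30% to the external
  test set.

Metrics come from the confusion matrix: overall accuracy, Cohen's kappa
(observed vs. chance agreement from the row/column marginals), and
macro-averaged one-vs-rest precision, sensitivity/recall, specificity and
F1. Two printed-form variants that circulate in the application literature
(an overall "accuracy" that is a raw TP count, and a chance term using the
truth marginal twice) are provided for documentation but not used: only
the standard forms behave as a proportion and a chance-corrected
agreement coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SplitPlan:
    scheme: str  # "sample_based" | "pixel_based"
    train: np.ndarray
    internal_val: np.ndarray
    external_test: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        parts = [self.train, self.internal_val, self.external_test]
        total = sum(p.size for p in parts)
        if np.unique(np.concatenate(parts)).size != total:
            raise ValueError("split partitions overlap")

    @property
    def train_pool(self) -> np.ndarray:
        return np.concatenate([self.train, self.internal_val])


def split_sample_based(
    labels: pd.DataFrame,
    train_frac: float = 0.7,
    internal_frac: float = 0.2,
    seed: int = 0,
    strata_cols=("class_label", "day", "substrate"),
) -> SplitPlan:
    """Stain-level split: all pixels of a stain travel together.

    Within each stratum the stains are shuffled; ~70% go to the training
    pool and the rest to the external test set; ~20% of the training-pool
    stains become internal validation.
    """
    rng = np.random.default_rng(seed)
    strata_cols = [c for c in strata_cols if c in labels.columns]
    train_ids, val_ids, test_ids = [], [], []
    for key, grp in labels.groupby(strata_cols, sort=True, dropna=False):
        stains = grp["stain_id"].unique()
        if stains.size < 2:
            raise ValueError(f"stratum {key} has a single stain; cannot split")
        stains = stains[rng.permutation(stains.size)]
        n_pool = int(round(train_frac * stains.size))
        n_pool = min(max(n_pool, 1), stains.size - 1)
        pool, test = stains[:n_pool], stains[n_pool:]
        n_val = int(round(internal_frac * pool.size))
        n_val = min(n_val, pool.size - 1)
        val_ids.extend(pool[:n_val])
        train_ids.extend(pool[n_val:])
        test_ids.extend(test)
    sid = labels["stain_id"].to_numpy()
    to_idx = lambda ids: np.flatnonzero(np.isin(sid, list(ids)))
    return SplitPlan(
        scheme="sample_based",
        train=to_idx(train_ids),
        internal_val=to_idx(val_ids),
        external_test=to_idx(test_ids),
        seed=seed,
    )


def split_pixel_based(
    labels: pd.DataFrame,
    train_frac: float = 0.7,
    internal_frac: float = 0.2,
    seed: int = 0,
) -> SplitPlan:
    """Pixel-level split: every stain contributes to all three partitions.

    Per stain the pixels are shuffled; floor((1-train_frac)*n) go to the
    external test set (remainder to the training pool), and
    floor(internal_frac * pool) of the pool to internal validation.
    """
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for _, grp in labels.groupby("stain_id", sort=True):
        idx = grp.index.to_numpy()
        if idx.size < 5:
            raise ValueError(
                f"stain {grp['stain_id'].iloc[0]!r} has {idx.size} pixels (< 5)"
            )
        idx = idx[rng.permutation(idx.size)]
        n_test = int(np.floor((1.0 - train_frac) * idx.size))
        test.extend(idx[:n_test])
        pool = idx[n_test:]
        n_val = int(np.floor(internal_frac * pool.size))
        val.extend(pool[:n_val])
        train.extend(pool[n_val:])
    return SplitPlan(
        scheme="pixel_based",
        train=np.sort(np.array(train, dtype=int)),
        internal_val=np.sort(np.array(val, dtype=int)),
        external_test=np.sort(np.array(test, dtype=int)),
        seed=seed,
    )


def split_tally(labels: pd.DataFrame, plan: SplitPlan, by: str = "substrate") -> pd.DataFrame:
    """Pixel counts per (group, class) x (training pool, test) -- the
    accounting layout of per-substrate splitting tables."""
    rows = []
    for group, grp in labels.groupby(by, sort=True):
        for cls, cgrp in grp.groupby("class_label", sort=True):
            idx = cgrp.index.to_numpy()
            rows.append(
                {
                    by: group,
                    "class_label": cls,
                    "training": int(np.isin(idx, plan.train_pool).sum()),
                    "test": int(np.isin(idx, plan.external_test).sum()),
                    "total": idx.size,
                }
            )
    return pd.DataFrame(rows)


def check_split_accounting(table: pd.DataFrame) -> bool:
    """Additivity of a splitting table: per group, training + test counts
    over the classes sum to the group total."""
    for _, grp in table.groupby(table.columns[0], sort=False):
        if int(grp["training"].sum() + grp["test"].sum()) != int(grp["total"].sum()):
            return False
        if not np.all(grp["training"] + grp["test"] == grp["total"]):
            return False
    return True


# ---------------------------------------------------------------------------
# confusion matrix and metrics


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = truth, cols = prediction
    classes: list

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.classes):
            raise ValueError("confusion matrix must be C x C with C class labels")
        if np.any(c < 0):
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, i: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class i by one-vs-rest collapse."""
        c = self.counts
        tp = int(c[i, i])
        fp = int(c[:, i].sum() - c[i, i])
        fn = int(c[i, :].sum() - c[i, i])
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def confusion(y_true, y_pred, classes) -> ConfusionMatrix:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("cannot build a confusion matrix from empty inputs")
    if y_true.shape != y_pred.shape:
        raise ValueError("truth and prediction must have equal lengths")
    classes = list(classes)
    lookup = {c: i for i, c in enumerate(classes)}
    unknown = (set(y_true.tolist()) | set(y_pred.tolist())) - set(classes)
    if unknown:
        raise ValueError(f"labels not in class order: {sorted(map(str, unknown))}")
    ti = np.array([lookup[v] for v in y_true.tolist()])
    pi = np.array([lookup[v] for v in y_pred.tolist()])
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    np.add.at(counts, (ti, pi), 1)
    return ConfusionMatrix(counts=counts, classes=classes)


@dataclass
class MetricsReport:
    """Overall accuracy, kappa (with its agreement terms) and macro-averaged
    one-vs-rest metrics. Undefined ratios are NaN, never 0."""

    oa: float
    kappa: float
    po: float
    pe: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    average_accuracy: float
    per_class: pd.DataFrame
    n_classes: int
    total: int
    py: float | None = None  # binary only, positive class first
    pn: float | None = None

    @property
    def recall(self) -> float:
        return self.sensitivity

    def to_dict(self) -> dict:
        return {
            "Sensitivity": self.sensitivity,
            "Specificity": self.specificity,
            "F1-Score": self.f1,
            "Precision": self.precision,
            "OA": self.oa,
            "Kappa": self.kappa,
            "AA": self.average_accuracy,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def _ratio(num: float, den: float) -> float:
    return num / den if den else float("nan")


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Compute the full metric suite from a confusion matrix.

    OA = trace / total; kappa = (Po - Pe) / (1 - Pe) with the standard
    chance agreement Pe = sum_i row_i * col_i / total^2; macro-averaged
    precision / sensitivity / specificity over one-vs-rest collapses, and
    F1 as the harmonic mean of the macro precision and recall. For binary
    matrices the positive class is the first class and PY/PN (the class-wise
    chance terms) are reported.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts.astype(float)
    po = np.trace(c) / n
    row, col = c.sum(axis=1), c.sum(axis=0)
    pe = float(np.sum(row * col) / n**2)
    kappa = (po - pe) / (1.0 - pe) if pe != 1.0 else (1.0 if po == 1.0 else float("nan"))

    rows = []
    for i, cls in enumerate(cm.classes):
        tp, fp, fn, tn = cm.one_vs_rest(i)
        rows.append(
            {
                "class": cls,
                "TP": tp,
                "FP": fp,
                "FN": fn,
                "TN": tn,
                "precision": _ratio(tp, tp + fp),
                "sensitivity": _ratio(tp, tp + fn),
                "specificity": _ratio(tn, tn + fp),
            }
        )
    per_class = pd.DataFrame(rows)
    precision = float(per_class["precision"].mean())
    sensitivity = float(per_class["sensitivity"].mean())
    specificity = float(per_class["specificity"].mean())
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if (precision + sensitivity)
        else float("nan")
    )
    py = pn = None
    if len(cm.classes) == 2:
        tp, fp, fn, tn = cm.one_vs_rest(0)
        py = ((tp + fn) / n) * ((tp + fp) / n)
        pn = ((fp + tn) / n) * ((fn + tn) / n)
    return MetricsReport(
        oa=float(po),
        kappa=float(kappa),
        po=float(po),
        pe=pe,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=float(f1),
        average_accuracy=sensitivity,
        per_class=per_class,
        n_classes=len(cm.classes),
        total=n,
        py=py,
        pn=pn,
    )


# Printed-form variants (documented alternatives; see module docstring).


def printed_form_oa(cm: ConfusionMatrix) -> float:
    """(1/C) * sum_i TP_i -- a count, not a proportion; documentation only."""
    return float(np.trace(cm.counts) / len(cm.classes))


def printed_form_pe(cm: ConfusionMatrix) -> float:
    """Binary chance term using the truth marginal twice in PY; disagrees
    with the standard Pe whenever the truth and prediction marginals
    differ. Documentation only."""
    if len(cm.classes) != 2:
        raise ValueError("printed-form Pe is defined for binary matrices")
    tp, fp, fn, tn = cm.one_vs_rest(0)
    n = cm.total
    py = ((tp + fn) / n) ** 2
    pn = ((fp + tn) / n) * ((fn + tn) / n)
    return py + pn
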