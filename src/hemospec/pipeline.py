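"""Experiment orchestration: classifiers, binary and multi-class runs,
blind-scene prediction maps, and the PCA-baseline comparison.

Seven model families are supported (linear / RBF / cubic-polynomial SVM,
a 3 x 30-unit dense neural network trained for 50 epochs, k-nearest
neighbours with k tuned on internal validation over [1, 20], an
entropy-criterion decision tree of depth 10, and a 500-tree random
forest). On cleanly separable derivative features every family reaches the
same ceiling; the families differ only in how they degrade as noise grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluate import SplitPlan, confusion, metrics, split_pixel_based, split_sample_based
from .features import DerivativeFeaturePipeline, PCAFeaturePipeline, build_feature_table
from .preprocess import SGSpec, extract_roi
from .synthetic_data import BlindScene, LabeledDataset

MODEL_FAMILIES = ("svm_linear", "svm_rbf", "svm_cubic", "ann", "dt", "rf", "knn")
KNN_K_RANGE = (1, 20)


@dataclass(frozen=True)
class ModelSpec:
    family: str
    seed: int = 0
    knn_k: int | None = None  # fixed k; None = tune on internal validation
    ann_epochs: int = 50
    ann_hidden: tuple[int, ...] = (30, 30, 30)
    dt_max_depth: int = 10
    rf_estimators: int = 500

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.knn_k is not None and not KNN_K_RANGE[0] <= self.knn_k <= KNN_K_RANGE[1]:
            raise ValueError(f"knn k must lie in {KNN_K_RANGE}")


def default_model_specs(seed: int = 0) -> list[ModelSpec]:
    return [ModelSpec(family=f, seed=seed) for f in MODEL_FAMILIES]


def _make_estimator(spec: ModelSpec):
    if spec.family == "svm_linear":
        return SVC(kernel="linear")
    if spec.family == "svm_rbf":
        return SVC(kernel="rbf")
    if spec.family == "svm_cubic":
        return SVC(kernel="poly", degree=3)
    if spec.family == "ann":
        return MLPClassifier(
            hidden_layer_sizes=spec.ann_hidden,
            activation="relu",
            solver="adam",
            batch_size=128,
            max_iter=spec.ann_epochs,
            random_state=spec.seed,
        )
    if spec.family == "dt":
        return DecisionTreeClassifier(
            criterion="entropy", max_depth=spec.dt_max_depth, random_state=spec.seed
        )
    if spec.family == "rf":
        return RandomForestClassifier(
            n_estimators=spec.rf_estimators, random_state=spec.seed, n_jobs=1
        )
    raise AssertionError(spec.family)


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: object
    chosen_k: int | None = None
    internal_val_accuracy: float | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)


def _tune_knn(X, y, X_val, y_val, k_range=KNN_K_RANGE) -> int:
    """Pick k by internal-validation accuracy. The neighbour lists are
    computed once at k_max and truncated, so the scan over k is cheap."""
    k_max = min(k_range[1], X.shape[0])
    nn = NearestNeighbors(n_neighbors=k_max).fit(X)
    _, idx = nn.kneighbors(X_val)
    y = np.asarray(y)
    neigh = y[idx]  # (n_val, k_max)
    best_k, best_acc = k_range[0], -1.0
    classes = np.unique(y)
    for k in range(k_range[0], k_max + 1):
        votes = (neigh[:, :k, None] == classes[None, None, :]).sum(axis=1)
        pred = classes[votes.argmax(axis=1)]
        acc = float(np.mean(pred == np.asarray(y_val)))
        if acc > best_acc:
            best_k, best_acc = k, acc
    return best_k


def train_model(
    spec: ModelSpec,
    X_train: np.ndarray,
    y_train,
    X_val: np.ndarray | None = None,
    y_val=None,
) -> TrainedModel:
    """Fit one model; kNN selects k on the internal-validation set."""
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("training set contains a single class")
    if spec.family == "knn":
        if spec.knn_k is not None:
            k = spec.knn_k
        elif X_val is not None and len(X_val):
            k = _tune_knn(X_train, y_train, X_val, y_val)
        else:
            k = 5
        est = KNeighborsClassifier(n_neighbors=k).fit(X_train, y_train)
        model = TrainedModel(spec=spec, estimator=est, chosen_k=k)
    else:
        est = _make_estimator(spec)
        with warnings.catch_warnings():
            # the 50-epoch budget is part of the model spec, not a failure
            warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
            warnings.filterwarnings("ignore", category=UserWarning)
            est.fit(X_train, y_train)
        model = TrainedModel(spec=spec, estimator=est)
    if X_val is not None and len(X_val):
        model.internal_val_accuracy = float(np.mean(model.predict(X_val) == np.asarray(y_val)))
    return model


def _split(labels: pd.DataFrame, scheme: str, seed: int) -> SplitPlan:
    if scheme in ("sample", "sample_based"):
        return split_sample_based(labels, seed=seed)
    if scheme in ("pixel", "pixel_based"):
        return split_pixel_based(labels, seed=seed)
    raise ValueError(f"unknown splitting scheme {scheme!r}")


@dataclass
class ExperimentResult:
    reports: dict  # (substrate or key) -> {family: MetricsReport}
    models: dict
    plans: dict
    pipeline: object

    def summary(self) -> pd.DataFrame:
        rows = []
        for key, fams in self.reports.items():
            for fam, rep in fams.items():
                rows.append({"key": key, "model": fam, **rep.to_dict()})
        return pd.DataFrame(rows)

    def min_oa(self) -> float:
        return min(rep.oa for fams in self.reports.values() for rep in fams.values())


def run_binary_experiment(
    datasets: Sequence[LabeledDataset],
    scheme: str = "sample_based",
    model_specs: Sequence[ModelSpec] | None = None,
    pipeline_factory=None,
    seed: int = 0,
    per_substrate: bool = True,
) -> ExperimentResult:
    """Blood vs. non-blood with derivative features, per substrate.

    Features are built with the default pipeline (second-derivative SG,
    13-point window, order-3 polynomial, 470-770 nm, min-max on train
    statistics); the split is computed first so the pipeline fits on
    training rows only.
    """
    model_specs = list(model_specs) if model_specs else default_model_specs(seed)
    pipeline_factory = pipeline_factory or (lambda: DerivativeFeaturePipeline())
    groups: dict[str, list[LabeledDataset]] = {}
    for ds in datasets:
        groups.setdefault(ds.substrate if per_substrate else "all", []).append(ds)

    reports, models, plans, pipe = {}, {}, {}, None
    for key in sorted(groups):
        raw, _ = build_feature_table(groups[key], pipeline=None)
        plan = _split(raw.labels, scheme, seed)
        pipe = pipeline_factory()
        table, pipe = build_feature_table(groups[key], pipeline=pipe, fit_rows=plan.train)
        y = raw.labels["class_label"].to_numpy()
        Xtr, ytr = table.X[plan.train], y[plan.train]
        Xv, yv = table.X[plan.internal_val], y[plan.internal_val]
        Xte, yte = table.X[plan.external_test], y[plan.external_test]
        reports[key], models[key], plans[key] = {}, {}, plan
        for spec in model_specs:
            model = train_model(spec, Xtr, ytr, Xv, yv)
            cm = confusion(yte, model.predict(Xte), classes=["blood", "non_blood"])
            reports[key][spec.family] = metrics(cm)
            models[key][spec.family] = model
    return ExperimentResult(reports=reports, models=models, plans=plans, pipeline=pipe)


def run_multiclass_experiment(
    datasets: Sequence[LabeledDataset],
    day: int,
    model_specs: Sequence[ModelSpec] | None = None,
    scheme: str = "sample_based",
    seed: int = 0,
) -> ExperimentResult:
    """Donors-as-classes: 3 blood donors + 8 confusers = 11 classes,
    per substrate, for one aging day, on full-wavelength derivative spectra
    (no band selection)."""
    model_specs = list(model_specs) if model_specs else default_model_specs(seed)
    day_sets = [ds for ds in datasets if ds.day == day]
    if not day_sets:
        raise ValueError(f"no datasets for day {day}")
    groups: dict[str, list[LabeledDataset]] = {}
    for ds in day_sets:
        groups.setdefault(ds.substrate, []).append(ds)

    reports, models, plans, pipe = {}, {}, {}, None
    for key in sorted(groups):
        raw, _ = build_feature_table(groups[key], pipeline=None)
        lab = raw.labels
        y = np.where(
            lab["class_label"] == "blood",
            "donor_" + lab["donor"].astype("Int64").astype(str),
            lab["substance"],
        )
        classes = sorted(np.unique(y))
        if len(classes) != 11:
            raise ValueError(f"expected 11 classes, found {len(classes)}")
        plan = _split(lab, scheme, seed)
        pipe = DerivativeFeaturePipeline(band_range=None)
        table, pipe = build_feature_table(groups[key], pipeline=pipe, fit_rows=plan.train)
        reports[key], models[key], plans[key] = {}, {}, plan
        for spec in model_specs:
            model = train_model(
                spec,
                table.X[plan.train], y[plan.train],
                table.X[plan.internal_val], y[plan.internal_val],
            )
            cm = confusion(y[plan.external_test], model.predict(table.X[plan.external_test]), classes)
            reports[key][spec.family] = metrics(cm)
            models[key][spec.family] = model
    return ExperimentResult(reports=reports, models=models, plans=plans, pipeline=pipe)


@dataclass
class PredictionMap:
    """Per-pixel label image over the ROI (0 = background), stain-level
    majority-vote calls, and the blood extraction rate."""

    labels: np.ndarray  # 0 background, 1 blood, 2 non_blood
    stain_calls: pd.DataFrame
    extraction_rate: float | None
    provenance: dict = field(default_factory=dict)


def run_blind_test(
    model: TrainedModel,
    pipeline,
    scene: BlindScene,
    batch: int = 200_000,
) -> PredictionMap:
    """ROI-extract a blind scene, classify every stain pixel, and call each
    stain by majority vote over its pixels.

    The extraction rate is the fraction of truth-blood stains whose
    majority-vote label is blood; with no blood stains (or an empty ROI)
    it is undefined (None), not 0.
    """
    roi = extract_roi(scene.cube)
    code = {"blood": 1, "non_blood": 2}
    label_img = np.zeros(roi.labels.shape, dtype=np.uint8)
    if roi.is_empty:
        warnings.warn("empty ROI on blind scene; extraction rate undefined")
        return PredictionMap(labels=label_img, stain_calls=pd.DataFrame(), extraction_rate=None)

    mask = roi.mask
    spectra = scene.cube.data[mask]
    preds = np.empty(spectra.shape[0], dtype=object)
    for start in range(0, spectra.shape[0], batch):
        X = pipeline.transform(spectra[start : start + batch])
        preds[start : start + batch] = model.predict(X)
    label_img[mask] = [code[p] for p in preds]

    comp = roi.labels[mask]
    calls = []
    for k in range(1, roi.n_stains + 1):
        sel = comp == k
        votes = preds[sel]
        call = "blood" if np.mean(votes == "blood") > 0.5 else "non_blood"
        truth_ids, truth_counts = np.unique(scene.labels[roi.component(k)], return_counts=True)
        nz = truth_ids != 0
        truth_id = int(truth_ids[nz][truth_counts[nz].argmax()]) if nz.any() else 0
        truth = (
            scene.stains[truth_id - 1]["class_label"] if truth_id else "background"
        )
        calls.append(
            {"component": k, "n_pixels": int(sel.sum()), "call": call, "truth": truth}
        )
    calls = pd.DataFrame(calls)
    blood_rows = calls[calls["truth"] == "blood"]
    rate = (
        float(np.mean(blood_rows["call"] == "blood")) if len(blood_rows) else None
    )
    if rate is None:
        warnings.warn("no blood stains in scene truth; extraction rate undefined")
    return PredictionMap(
        labels=label_img,
        stain_calls=calls,
        extraction_rate=rate,
        provenance={"model": model.spec.family, "donor_seed": scene.donor_seed},
    )


def run_comparison(
    datasets: Sequence[LabeledDataset],
    scheme: str = "sample_based",
    seed: int = 0,
    derivative_families: Sequence[str] = ("svm_linear", "ann", "knn", "dt", "rf"),
) -> pd.DataFrame:
    """PCA(3)+SVM baseline vs. the derivative pipeline, per substrate.

    Rows follow the comparison layout: Accuracy, Sensitivity, Specificity,
    F1-Score, Precision, Kappa.
    """
    rows = []
    pca_res = run_binary_experiment(
        datasets, scheme=scheme, seed=seed,
        model_specs=[ModelSpec("svm_linear", seed=seed)],
        pipeline_factory=lambda: PCAFeaturePipeline(n_components=3),
    )
    deriv_res = run_binary_experiment(
        datasets, scheme=scheme, seed=seed,
        model_specs=[ModelSpec(f, seed=seed) for f in derivative_families],
    )
    for key in sorted(pca_res.reports):
        rep = pca_res.reports[key]["svm_linear"]
        rows.append(_comparison_row(key, "smoothing+pca3+svm", rep))
        for fam in derivative_families:
            rep = deriv_res.reports[key][fam]
            rows.append(_comparison_row(key, f"smoothing+derivative+{fam}", rep))
    return pd.DataFrame(rows)


def _comparison_row(key: str, method: str, rep) -> dict:
    return {
        "substrate": key,
        "method": method,
        "Accuracy": rep.oa,
        "Sensitivity": rep.sensitivity,
        "Specificity": rep.specificity,
        "F1-Score": rep.f1,
        "Precision": rep.precision,
        "Kappa": rep.kappa,
    }
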