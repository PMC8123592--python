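"""Derivative-based band selection and feature-table construction.

The identification criteria live in the 470-770 nm window, where the
second-derivative spectrum of blood departs sharply from every red
confuser. Features are built per pixel: optional SNV/MSC, a single
Savitzky-Golay pass (second derivative by default) over the full spectrum,
band selection, then min-max normalization to [0, 1] using training-set
statistics only -- normalization never sees validation or test rows.

A PCA pipeline (smoothing + first principal components) is provided as the
comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .grid import WavelengthGrid
from .preprocess import SGSpec, msc, sg_filter, snv

BAND_RANGE_NM = (470.0, 770.0)


@dataclass(frozen=True)
class BandSelection:
    lower: float
    upper: float
    indices: np.ndarray
    centers: np.ndarray

    def __len__(self) -> int:
        return self.indices.size


def select_bands(
    grid: WavelengthGrid,
    lower: float = BAND_RANGE_NM[0],
    upper: float = BAND_RANGE_NM[1],
) -> BandSelection:
    """All band centers c with lower <= c <= upper (closed interval)."""
    if lower >= upper:
        raise ValueError("lower must be < upper")
    idx = grid.window(lower, upper)
    if idx.size == 0:
        raise ValueError(f"no band centers inside [{lower}, {upper}] nm")
    return BandSelection(lower=lower, upper=upper, indices=idx, centers=grid.centers[idx])


@dataclass
class FeatureTable:
    """Observations x features with per-observation labels."""

    X: np.ndarray
    labels: pd.DataFrame
    feature_names: list[str]

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.labels):
            raise ValueError("label vector length must equal row count")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature table contains non-finite values")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        pd.concat([df, self.labels.reset_index(drop=True)], axis=1).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label_columns) -> "FeatureTable":
        df = pd.read_csv(path)
        feats = [c for c in df.columns if c not in label_columns]
        return cls(
            X=df[feats].to_numpy(float),
            labels=df[list(label_columns)].copy(),
            feature_names=feats,
        )


class _MinMaxScaler:
    """[0, 1] scaling with statistics frozen on the training rows."""

    def fit(self, X: np.ndarray) -> "_MinMaxScaler":
        self.min_ = X.min(axis=0)
        span = X.max(axis=0) - self.min_
        self.span_ = np.where(span == 0, 1.0, span)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.min_) / self.span_


class DerivativeFeaturePipeline:
    """The derivative feature pipeline: SG filter over the full spectrum,
    band selection, then train-statistic min-max normalization.

    Filtering precedes selection so the 470/770 nm feature edges are
    interior points of the filter and never see window-edge refits.
    """

    def __init__(
        self,
        sg: SGSpec = SGSpec(13, 3, 2),
        band_range: tuple[float, float] | None = BAND_RANGE_NM,
        use_snv: bool = False,
        use_msc: bool = False,
        per_nm: bool = True,
    ) -> None:
        self.sg = sg
        self.band_range = band_range
        self.use_snv = use_snv
        self.use_msc = use_msc
        self.per_nm = per_nm

    def _pretreat(self, X: np.ndarray) -> np.ndarray:
        if self.use_snv:
            X = snv(X)
        if self.use_msc:
            X = msc(X, reference=self._msc_reference)
        spacing = self.grid.spacing if self.per_nm else 1.0
        X = sg_filter(X, self.sg, spacing=spacing)
        if self.selection is not None:
            X = X[:, self.selection.indices]
        return X

    def fit(self, X_train: np.ndarray, grid: WavelengthGrid) -> "DerivativeFeaturePipeline":
        self.grid = grid
        self.selection = (
            select_bands(grid, *self.band_range) if self.band_range else None
        )
        self._msc_reference = X_train.mean(axis=0) if self.use_msc else None
        F = self._pretreat(np.asarray(X_train, float))
        self.scaler = _MinMaxScaler().fit(F)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.scaler.transform(self._pretreat(np.asarray(X, float)))

    @property
    def feature_names(self) -> list[str]:
        if self.selection is not None:
            return [f"d2_{c:.1f}nm" for c in self.selection.centers]
        return [f"d2_{c:.1f}nm" for c in self.grid.centers]


class PCAFeaturePipeline:
    """Comparison baseline: SG smoothing, PCA to a few components (fit on
    training rows only), min-max normalization of the scores."""

    def __init__(self, n_components: int = 3, sg: SGSpec = SGSpec(13, 3, 0)) -> None:
        self.n_components = n_components
        self.sg = sg

    def fit(self, X_train: np.ndarray, grid: WavelengthGrid) -> "PCAFeaturePipeline":
        self.grid = grid
        S = sg_filter(np.asarray(X_train, float), self.sg, spacing=grid.spacing)
        if np.allclose(S.var(axis=0), 0):
            raise ValueError("zero-variance input; PCA undefined")
        self.pca = PCA(n_components=self.n_components, svd_solver="full").fit(S)
        self.explained_variance_ratio_ = self.pca.explained_variance_ratio_
        self.scaler = _MinMaxScaler().fit(self.pca.transform(S))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        S = sg_filter(np.asarray(X, float), self.sg, spacing=self.grid.spacing)
        return self.scaler.transform(self.pca.transform(S))

    @property
    def feature_names(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.n_components)]


def pca_reduce(table: FeatureTable, n_components: int = 3, train_rows=None):
    """Mean-centred projection onto the top principal axes.

    Fit uses ``train_rows`` only (all rows if None); returns the reduced
    table and the fitted PCA (reusable on held-out rows).
    """
    X = table.X
    fit_X = X if train_rows is None else X[train_rows]
    if fit_X.shape[0] < n_components or np.allclose(fit_X.var(axis=0), 0):
        raise ValueError("degenerate input for PCA")
    pca = PCA(n_components=n_components, svd_solver="full").fit(fit_X)
    reduced = FeatureTable(
        X=pca.transform(X),
        labels=table.labels,
        feature_names=[f"PC{i + 1}" for i in range(n_components)],
    )
    return reduced, pca


def build_feature_table(
    datasets,
    pipeline: DerivativeFeaturePipeline | PCAFeaturePipeline | None = None,
    fit_rows=None,
) -> tuple[FeatureTable, object]:
    """Stack pixel spectra from LabeledDatasets and apply a feature pipeline.

    ``fit_rows`` restricts pipeline fitting (normalization statistics, PCA
    axes) to the given row indices -- pass the training rows of a split to
    keep test statistics out of the fit. With ``pipeline=None`` the raw
    spectra are returned (identity pipeline).
    """
    from .synthetic_data import combine_datasets

    grids = {id(ds.grid): ds.grid for ds in datasets}
    ref = next(iter(grids.values()))
    if any(g != ref for g in grids.values()):
        raise ValueError("datasets carry different wavelength grids")
    X, labels = combine_datasets(datasets)
    if pipeline is None:
        names = [f"r_{c:.1f}nm" for c in ref.centers]
        return FeatureTable(X=X.astype(float), labels=labels, feature_names=names), None
    fit_X = X if fit_rows is None else X[fit_rows]
    pipeline.fit(fit_X, ref)
    return (
        FeatureTable(X=pipeline.transform(X), labels=labels, feature_names=pipeline.feature_names),
        pipeline,
    )
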