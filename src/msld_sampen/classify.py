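"""SVM classification of MSLD-SampEn feature tables.

The classifier menu mirrors the study design: a soft-margin SVM with a
linear kernel x.y or a polynomial kernel (x.y + coef0)^degree with degree
2 (quadratic) or 3 (cubic), evaluated by stratified 5-fold
cross-validation. Features are standardized with statistics fitted inside
each training fold only, so no information leaks from a test fold.
Multiclass problems are reduced one-vs-one, the standard reduction for
kernel SVMs on a three-class problem.

`accuracy_grid` drives the full experimental grid: tolerance r in
{0.1, 0.15, 0.2, 0.25} x contiguous distance ranges (1-20, 1-15, 1-10,
1-5) x kernel. For each r the widest feature table is extracted once and
narrower ranges are column slices of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureTable, extract_feature_table, restrict_scales
from .sampen import SampEnParams
from .signal_io import LabeledSignalSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KernelSpec:
    """SVM kernel: linear x.y or polynomial (x.y + coef0)^degree.

    The polynomial offset defaults to 1 (inhomogeneous form); set
    ``coef0=0`` for the homogeneous (x.y)^degree variant. The box
    constraint C defaults to 1.
    """

    kind: str = "linear"
    degree: int = 1
    coef0: float = 1.0
    box_constraint: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "polynomial"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "linear" and self.degree != 1:
            raise ValueError("linear kernel implies degree 1")
        if self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        if not self.box_constraint > 0:
            raise ValueError("box constraint C must be positive")

    @property
    def name(self) -> str:
        if self.kind == "linear":
            return "linear"
        return {2: "quadratic", 3: "cubic"}.get(self.degree, f"poly{self.degree}")


def linear_kernel(C: float = 1.0) -> KernelSpec:
    return KernelSpec(kind="linear", degree=1, box_constraint=C)


def quadratic_kernel(coef0: float = 1.0, C: float = 1.0) -> KernelSpec:
    return KernelSpec(kind="polynomial", degree=2, coef0=coef0, box_constraint=C)


def cubic_kernel(coef0: float = 1.0, C: float = 1.0) -> KernelSpec:
    return KernelSpec(kind="polynomial", degree=3, coef0=coef0, box_constraint=C)


def kernel_from_name(name: str, coef0: float = 1.0, C: float = 1.0) -> KernelSpec:
    name = name.strip().lower()
    if name == "linear":
        return linear_kernel(C)
    if name == "quadratic":
        return quadratic_kernel(coef0, C)
    if name == "cubic":
        return cubic_kernel(coef0, C)
    raise ValueError(f"unknown kernel name {name!r}")


@dataclass
class CVResult:
    """Cross-validation outcome for one (table, kernel, seed) triple."""

    fold_accuracies: np.ndarray
    mean_accuracy: float
    confusion: pd.DataFrame
    kernel: KernelSpec
    seed: int
    n_folds: int

    def to_dict(self) -> dict:
        return {
            "kernel": self.kernel.name,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": float(self.mean_accuracy),
            "confusion_matrix": self.confusion.to_dict(),
        }


@dataclass
class AccuracyGrid:
    """Mean CV accuracies (percent) over r values, scale ranges, kernels."""

    cells: dict
    r_values: Sequence[float]
    scale_ranges: Sequence[tuple[int, int]]
    kernel_names: Sequence[str]
    details: dict = field(default_factory=dict)

    def to_dataframe(self, kernel_name: str) -> pd.DataFrame:
        """One kernel's grid: rows = r values, columns = scale ranges."""
        cols = [f"scale {lo}-{hi}" for lo, hi in self.scale_ranges]
        data = [
            [self.cells[(r, rng, kernel_name)] for rng in self.scale_ranges]
            for r in self.r_values
        ]
        return pd.DataFrame(
            data, index=pd.Index([f"r = {r:g}" for r in self.r_values]), columns=cols
        )


def _make_estimator(kernel: KernelSpec) -> Pipeline:
    if kernel.kind == "linear":
        svc = SVC(kernel="linear", C=kernel.box_constraint)
    else:
        svc = SVC(
            kernel="poly",
            degree=kernel.degree,
            coef0=kernel.coef0,
            gamma=1.0,  # plain inner product, no bandwidth rescaling
            C=kernel.box_constraint,
        )
    return Pipeline([("scale", StandardScaler()), ("svm", svc)])


def _validate_table(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    X, y = table.to_arrays()
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains non-finite values")
    classes = pd.unique(y)
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes, got {list(classes)}")
    return X, y


def train_svm(table: FeatureTable, kernel: KernelSpec) -> Pipeline:
    """Fit a standardize-then-SVM pipeline on the whole table."""
    X, y = _validate_table(table)
    est = _make_estimator(kernel)
    est.fit(X, y.astype(str))
    return est


def cross_validate(
    table: FeatureTable,
    kernel: KernelSpec,
    n_folds: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> CVResult:
    """Stratified k-fold cross-validation accuracy.

    Folds are deterministic given the seed. Standardization statistics are
    fitted on each training fold only. The confusion matrix pools test-fold
    predictions over all folds, with rows/columns in table class order.
    """
    X, y = _validate_table(table)
    y = y.astype(str)
    counts = pd.Series(y).value_counts()
    if counts.min() < n_folds:
        raise ValueError(
            f"every class needs >= {n_folds} rows for {n_folds}-fold CV; "
            f"smallest class has {counts.min()}"
        )
    splitter_cls = StratifiedKFold if stratified else KFold
    splitter = splitter_cls(n_splits=n_folds, shuffle=True, random_state=seed)
    classes = [str(c) for c in table.class_names] or sorted(set(y))
    fold_acc = []
    y_true_all: list[str] = []
    y_pred_all: list[str] = []
    for train_idx, test_idx in splitter.split(X, y):
        est = _make_estimator(kernel)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        fold_acc.append(float(np.mean(pred == y[test_idx])))
        y_true_all.extend(y[test_idx])
        y_pred_all.extend(pred)
    conf = confusion_matrix(y_true_all, y_pred_all, labels=classes)
    conf_df = pd.DataFrame(conf, index=classes, columns=classes)
    fold_acc = np.array(fold_acc)
    return CVResult(
        fold_accuracies=fold_acc,
        mean_accuracy=float(fold_acc.mean()),
        confusion=conf_df,
        kernel=kernel,
        seed=seed,
        n_folds=n_folds,
    )


def accuracy_grid(
    signal_set: LabeledSignalSet,
    kernels: Sequence[KernelSpec],
    r_values: Sequence[float] = (0.1, 0.15, 0.2, 0.25),
    scale_ranges: Sequence[tuple[int, int]] = ((1, 20), (1, 15), (1, 10), (1, 5)),
    m: int = 2,
    tolerance_mode: str = "relative_sd",
    n_folds: int = 5,
    seed: int = 0,
) -> AccuracyGrid:
    """Mean CV accuracy for every (r, scale range, kernel) cell.

    For each tolerance r the features are extracted once at the widest
    range; narrower ranges are column slices (entropy at each distance is
    independent of the others, so slicing equals re-extraction). Cell
    values are percentages.
    """
    signal_set.validate_for_classification()
    scale_ranges = [tuple(rng) for rng in scale_ranges]
    widest = max(hi for _, hi in scale_ranges)
    narrowest = min(lo for lo, _ in scale_ranges)
    cells: dict = {}
    details: dict = {}
    for r in r_values:
        params = SampEnParams(m=m, r=r, tolerance_mode=tolerance_mode)
        logger.info("extracting features at r=%g (d=%d..%d)", r, narrowest, widest)
        wide = extract_feature_table(signal_set, narrowest, widest, params)
        for rng in scale_ranges:
            sub = restrict_scales(wide, rng[0], rng[1])
            for kernel in kernels:
                result = cross_validate(sub, kernel, n_folds=n_folds, seed=seed)
                cells[(r, rng, kernel.name)] = 100.0 * result.mean_accuracy
                details[(r, rng, kernel.name)] = result
                logger.info(
                    "r=%g scale %d-%d %s: %.1f%%",
                    r, rng[0], rng[1], kernel.name, cells[(r, rng, kernel.name)],
                )
    return AccuracyGrid(
        cells=cells,
        r_values=list(r_values),
        scale_ranges=scale_ranges,
        kernel_names=[k.name for k in kernels],
        details=details,
    )
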