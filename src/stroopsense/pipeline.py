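"""Tuned, Monte-Carlo cross-validated classification pipeline.

Evaluation uses repeated random stratified 70/30 train-test splits (100
repetitions by default) — a Monte-Carlo cross-validation, which is the only
reading compatible with a fixed 70%/30% split proportion at this sample
size.  Per repetition the pipeline fits, on the training partition only:

1. robust variance thresholds (rMAD / rIQR lower bounds, on raw values),
2. per-feature z-scoring,
3. PCA,
4. one of four classifiers: logistic regression (LR), k-nearest neighbors
   (KNN), random forest (RF) or a radial-kernel support vector machine
   (SVM),

then scores the held-out partition.  The experimental group (EG) is the
positive class throughout, so sensitivity is the EG recall and specificity
the CG recall.  Hyperparameters (classifier-specific settings plus the two
variance thresholds and the PCA dimensionality) are tuned by maximizing
mean test accuracy over the same folds — an in-sample selection scheme that
can yield optimistic estimates; it is retained deliberately, and the
caveat travels with the report.

The full-versus-reduced comparison summarizes the effect of i-KNN point
filtering through the balanced accuracy (mean of sensitivity and
specificity) and its relative change per classifier, averaged over the
four datasets (EDA, HRV, ST, fusion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._util import round_half_up
from .errors import AlignmentError, InvalidGridError, StratificationError
from .variance import apply_variance_thresholds

__all__ = [
    "PipelineConfig",
    "FoldResult",
    "MetricsEntry",
    "MetricsReport",
    "ComparisonReport",
    "POSITIVE_LABEL",
    "DEFAULT_CLASSIFIER_GRIDS",
    "split_stratified",
    "evaluate_config",
    "tune_and_evaluate",
    "balanced_accuracy_change",
]

POSITIVE_LABEL = "EG"
CONTROL_LABEL = "CG"

#: modest expert-default hyperparameter grids (fully overridable)
DEFAULT_CLASSIFIER_GRIDS: dict[str, list[dict]] = {
    "LR": [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)],
    "KNN": [{"n_neighbors": k} for k in (3, 5, 7, 9)],
    "RF": [
        {"n_estimators": n, "max_depth": d}
        for n, d in product((100, 300), (None, 5))
    ],
    "SVM": [
        {"C": c, "gamma": g}
        for c, g in product((0.1, 1.0, 10.0), ("scale", 0.01, 0.1))
    ],
}

#: default tuning grids for the shared (non-classifier) knobs
DEFAULT_THRESHOLD_GRID: list[tuple[float, float]] = [(0.0, 0.0), (0.05, 0.05), (0.1, 0.1)]
DEFAULT_PCA_GRID: list[float | int] = [0.90, 0.95, 10]


@dataclass(frozen=True)
class PipelineConfig:
    """One point in the evaluation space.

    ``pca_components`` follows the scikit-learn convention: a float in
    (0, 1) keeps enough components for that fraction of variance, an int
    keeps that many components (clamped to the training rank).
    """

    classifier: str = "SVM"
    classifier_params: tuple[tuple[str, object], ...] = ()
    pca_components: float | int = 0.95
    theta_rmad: float = 0.0
    theta_riqr: float = 0.0
    n_folds: int = 100
    test_fraction: float = 0.3
    stratified: bool = True
    seed: int = 0
    dataset_variant: str = "full"  # "full" | "reduced"
    signal_set: str = "fusion"

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_folds < 1:
            raise ValueError("n_folds must be >= 1")
        if self.classifier not in DEFAULT_CLASSIFIER_GRIDS:
            raise ValueError(f"unknown classifier {self.classifier!r}")

    @property
    def params(self) -> dict:
        return dict(self.classifier_params)

    def with_(self, **kwargs) -> "PipelineConfig":
        if "classifier_params" in kwargs and isinstance(kwargs["classifier_params"], dict):
            kwargs["classifier_params"] = tuple(sorted(kwargs["classifier_params"].items()))
        return replace(self, **kwargs)


@dataclass
class FoldResult:
    """Confusion counts and derived metrics for one train-test repetition."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


@dataclass
class MetricsEntry:
    """Mean metrics for one (dataset, variant, classifier) cell."""

    dataset: str
    classifier: str
    variant: str
    accuracy: float
    sensitivity: float
    specificity: float
    folds: list[FoldResult] = field(default_factory=list, repr=False)
    config: PipelineConfig | None = field(default=None, repr=False)

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0


@dataclass
class MetricsReport:
    """Collection of metric cells, one per (dataset, variant, classifier)."""

    entries: list[MetricsEntry]

    def get(self, dataset: str, classifier: str, variant: str | None = None) -> MetricsEntry:
        for e in self.entries:
            if e.dataset == dataset and e.classifier == classifier and (
                variant is None or e.variant == variant
            ):
                return e
        raise KeyError((dataset, classifier, variant))

    @property
    def datasets(self) -> list[str]:
        return list(dict.fromkeys(e.dataset for e in self.entries))

    @property
    def classifiers(self) -> list[str]:
        return list(dict.fromkeys(e.classifier for e in self.entries))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "dataset": e.dataset,
                    "classifier": e.classifier,
                    "variant": e.variant,
                    "accuracy": e.accuracy,
                    "sensitivity": e.sensitivity,
                    "specificity": e.specificity,
                }
                for e in self.entries
            ]
        )


@dataclass
class ComparisonReport:
    """Balanced-accuracy comparison of full vs reduced datasets.

    ``mean_relative_change_pct`` is the per-classifier mean, over the
    datasets, of (reduced - original) / original, expressed in percent.
    """

    table: pd.DataFrame  # classifier, dataset, ba_original, ba_reduced, relative_change
    mean_relative_change_pct: dict[str, float]


def split_stratified(labels, test_fraction: float, seed) -> tuple[np.ndarray, np.ndarray]:
    """Random stratified split: per class, round(test_fraction * n_class)
    points (round half up) go to the test set.  Deterministic given seed.
    """
    labels = np.asarray(labels)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    test_parts = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            raise StratificationError(f"class {c!r} has fewer than 2 members")
        n_test = round_half_up(test_fraction * len(idx))
        if n_test == 0 or n_test == len(idx):
            raise StratificationError(
                f"class {c!r} too small to appear in both partitions"
            )
        test_parts.append(rng.permutation(idx)[:n_test])
    test = np.sort(np.concatenate(test_parts))
    train = np.setdiff1d(np.arange(len(labels)), test)
    return train, test


def make_classifier(name: str, params: dict, seed: int):
    """Instantiate one of the four supported classifiers."""
    if name == "LR":
        return LogisticRegression(max_iter=2000, **params)
    if name == "KNN":
        return KNeighborsClassifier(**params)
    if name == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    if name == "SVM":
        return SVC(kernel="rbf", **params)
    raise ValueError(f"unknown classifier {name!r}")


def _fold_seed(seed: int, fold: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), 101, int(fold)]))


def evaluate_config(x, y, config: PipelineConfig) -> MetricsEntry:
    """Monte-Carlo cross-validated evaluation of one configuration.

    Every per-fold transform (variance thresholds, z-scoring, PCA) and the
    classifier are fitted on the training partition only.  Folds whose
    training partition degenerates to a single class are skipped with a
    warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y)
    folds: list[FoldResult] = []
    for fold in range(config.n_folds):
        rng = _fold_seed(config.seed, fold)
        train, test = split_stratified(y, config.test_fraction, rng)
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {fold}: single-class training partition, skipped")
            continue
        mask = apply_variance_thresholds(
            x[train], config.theta_rmad, config.theta_riqr
        ).mask
        xtr, xte = x[train][:, mask], x[test][:, mask]
        scaler = StandardScaler().fit(xtr)
        xtr, xte = scaler.transform(xtr), scaler.transform(xte)
        n_comp = config.pca_components
        max_rank = min(xtr.shape[0], xtr.shape[1])
        if isinstance(n_comp, (int, np.integer)) and n_comp > max_rank:
            warnings.warn(
                f"PCA components {n_comp} exceed training rank {max_rank}; adjusted down"
            )
            n_comp = max_rank
        pca = PCA(n_components=n_comp, random_state=0).fit(xtr)
        xtr, xte = pca.transform(xtr), pca.transform(xte)
        clf = make_classifier(config.classifier, config.params, seed=int(config.seed))
        clf.fit(xtr, y[train])
        pred = clf.predict(xte)
        truth = y[test]
        tp = int(np.sum((pred == POSITIVE_LABEL) & (truth == POSITIVE_LABEL)))
        fn = int(np.sum((pred != POSITIVE_LABEL) & (truth == POSITIVE_LABEL)))
        tn = int(np.sum((pred != POSITIVE_LABEL) & (truth != POSITIVE_LABEL)))
        fp = int(np.sum((pred == POSITIVE_LABEL) & (truth != POSITIVE_LABEL)))
        folds.append(FoldResult(tp=tp, fp=fp, tn=tn, fn=fn))
    return MetricsEntry(
        dataset=config.signal_set,
        classifier=config.classifier,
        variant=config.dataset_variant,
        accuracy=float(np.mean([f.accuracy for f in folds])),
        sensitivity=float(np.mean([f.sensitivity for f in folds])),
        specificity=float(np.mean([f.specificity for f in folds])),
        folds=folds,
        config=config,
    )


def tune_and_evaluate(
    x,
    y,
    base: PipelineConfig,
    classifier_grid: list[dict] | None = None,
    threshold_grid: list[tuple[float, float]] | None = None,
    pca_grid: list[float | int] | None = None,
) -> tuple[PipelineConfig, MetricsEntry]:
    """Grid-tune hyperparameters by mean test accuracy over shared folds.

    All grid points are evaluated under identical fold seeds (set by
    ``base.seed``), so the selection compares like with like; the argmax
    configuration and its metrics are returned.  Ties resolve to the
    earliest grid point.  The full-vs-reduced dataset choice is *not* part
    of the grid — both variants are evaluated on the same points across
    folds, outside this function.
    """
    classifier_grid = (
        DEFAULT_CLASSIFIER_GRIDS[base.classifier]
        if classifier_grid is None
        else classifier_grid
    )
    threshold_grid = DEFAULT_THRESHOLD_GRID if threshold_grid is None else threshold_grid
    pca_grid = DEFAULT_PCA_GRID if pca_grid is None else pca_grid
    if not classifier_grid or not threshold_grid or not pca_grid:
        raise InvalidGridError("all grids must be non-empty")

    best: tuple[PipelineConfig, MetricsEntry] | None = None
    for params in classifier_grid:
        for theta_rmad, theta_riqr in threshold_grid:
            for n_comp in pca_grid:
                cfg = base.with_(
                    classifier_params=tuple(sorted(params.items())),
                    theta_rmad=theta_rmad,
                    theta_riqr=theta_riqr,
                    pca_components=n_comp,
                )
                entry = evaluate_config(x, y, cfg)
                if best is None or entry.accuracy > best[1].accuracy:
                    best = (cfg, entry)
    return best


def balanced_accuracy_change(
    original: MetricsReport, reduced: MetricsReport
) -> ComparisonReport:
    """Per-classifier balanced-accuracy comparison of two dataset variants.

    Both reports must cover the same (dataset, classifier) cells.  The
    relative change is (reduced - original) / original per dataset; the
    per-classifier summary is its mean over the datasets, in percent.
    """
    key_o = {(e.dataset, e.classifier) for e in original.entries}
    key_r = {(e.dataset, e.classifier) for e in reduced.entries}
    if key_o != key_r:
        raise AlignmentError(
            f"reports cover different cells: {sorted(key_o ^ key_r)}"
        )
    rows = []
    means: dict[str, float] = {}
    for clf in original.classifiers:
        rels = []
        for ds in original.datasets:
            ba_o = original.get(ds, clf).balanced_accuracy
            ba_r = reduced.get(ds, clf).balanced_accuracy
            rel = (ba_r - ba_o) / ba_o
            rels.append(rel)
            rows.append(
                {
                    "classifier": clf,
                    "dataset": ds,
                    "ba_original": ba_o,
                    "ba_reduced": ba_r,
                    "relative_change": rel,
                }
            )
        means[clf] = float(np.mean(rels) * 100.0)
    return ComparisonReport(table=pd.DataFrame(rows), mean_relative_change_pct=means)
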