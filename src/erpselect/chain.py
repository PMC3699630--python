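"""The full single-trial ERP classification chain.

standardize -> low-pass -> xDAWN (retain the k most relevant virtual channels
when more than k sensors are used) -> slope features -> feature
standardization (training statistics only) -> class-weighted linear SVM whose
complexity parameter is chosen by an inner cross-validated grid search on
balanced accuracy.

The chain is what sensor constellations are ultimately judged by; it is
deliberately identical for every selection method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .core import STANDARD, TARGET, EpochedDataset, SensorSet
from .preprocessing import lowpass, slope_features, standardize_epochs
from .spatial import FilterModel, fit_xdawn

logger = logging.getLogger("erpselect")

DEFAULT_SVM_GRID = tuple(10.0**e for e in range(-6, 1))


def balanced_accuracy(tp: int, fn: int, tn: int, fp: int) -> float:
    """Mean of true positive rate and true negative rate.

    Independent of the class ratio, hence suited to rare-target paradigms.
    """
    if tp + fn <= 0:
        raise ValueError("no positive-class samples (tp + fn == 0)")
    if tn + fp <= 0:
        raise ValueError("no negative-class samples (tn + fp == 0)")
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def balanced_accuracy_from_labels(
    y_true: np.ndarray, y_pred: np.ndarray
) -> float:
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    tp = int(np.sum(y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fp = int(np.sum(~y_true & y_pred))
    return balanced_accuracy(tp, fn, tn, fp)


@dataclass(frozen=True)
class ChainConfig:
    """Parameters of the processing/classification chain.

    ``n_xdawn`` is the retained virtual-channel count k; the xDAWN step is
    skipped when the constellation has k or fewer sensors.  ``svm_grid`` is
    the complexity grid searched by inner cross-validation; ``ranking_svm_c``
    is the fixed complexity used when an SVM is trained once for
    weight-based sensor ranking (no grid there).
    """

    window_ms: tuple[float, float] = (0.0, 1000.0)
    lowpass_hz: float = 4.0
    lowpass_order: int = 5
    n_xdawn: int = 5
    seg_len_ms: float = 400.0
    seg_step_ms: float = 120.0
    svm_grid: tuple[float, ...] = DEFAULT_SVM_GRID
    inner_cv_folds: int = 5
    cv_folds: int = 5  # folds of the performance-based ranking criterion
    ranking_svm_c: float = 0.1


def class_weights(labels: np.ndarray) -> dict[int, float]:
    """Target class upweighted by the standard:target count ratio."""
    n_t = int(np.sum(labels == TARGET))
    n_s = int(np.sum(labels == STANDARD))
    if n_t == 0 or n_s == 0:
        raise ValueError("both stimulus classes required for training")
    return {0: 1.0, 1: n_s / n_t}


def make_svm(norm: int, c: float, weights: dict[int, float]) -> LinearSVC:
    """Linear SVM with hinge-type loss and 1- or 2-norm weight penalty."""
    if norm not in (1, 2):
        raise ValueError("norm must be 1 or 2")
    return LinearSVC(
        penalty="l1" if norm == 1 else "l2",
        loss="squared_hinge",
        dual=False,
        C=c,
        class_weight=weights,
        max_iter=5000,
    )


def _grid_search_c(
    features: np.ndarray, y: np.ndarray, cfg: ChainConfig,
    weights: dict[int, float],
) -> float:
    """Pick the SVM complexity maximizing inner-CV balanced accuracy."""
    grid = cfg.svm_grid
    if len(grid) == 1:
        return grid[0]
    n_min = int(min(np.sum(y == 1), np.sum(y == 0)))
    folds = min(cfg.inner_cv_folds, n_min)
    if folds < 2:
        logger.warning("grid search skipped: too few samples per class")
        return grid[0]
    splitter = StratifiedKFold(n_splits=folds, shuffle=False)
    best_c, best_score = grid[0], -np.inf
    for c in grid:
        scores = []
        for tr, va in splitter.split(features, y):
            if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
                continue
            svc = make_svm(2, c, weights)
            svc.fit(features[tr], y[tr])
            scores.append(
                balanced_accuracy_from_labels(y[va], svc.predict(features[va]))
            )
        mean = float(np.mean(scores)) if scores else -np.inf
        if mean > best_score:
            best_c, best_score = c, mean
    return best_c


@dataclass
class ChainModel:
    """A trained chain: spatial filter (optional), feature scaler, SVM."""

    sensors: SensorSet
    cfg: ChainConfig
    filter_model: Optional[FilterModel]
    scaler: StandardScaler
    svc: LinearSVC

    def _features(self, data: EpochedDataset) -> np.ndarray:
        data = data.restrict(self.sensors)
        pre = lowpass(
            standardize_epochs(data), self.cfg.lowpass_hz, self.cfg.lowpass_order
        )
        if self.filter_model is not None:
            virt = self.filter_model.apply(pre.epochs)
            pre = EpochedDataset(
                epochs=virt,
                labels=pre.labels,
                window_ms=pre.window_ms,
                sample_rate=pre.sample_rate,
                channel_names=[
                    f"xdawn{i}" for i in range(self.filter_model.n_filters)
                ],
                run_id=pre.run_id,
                session_id=pre.session_id,
                subject_id=pre.subject_id,
            )
        feats = slope_features(pre, self.cfg.seg_len_ms, self.cfg.seg_step_ms)
        return self.scaler.transform(feats.matrix)

    def predict(self, data: EpochedDataset) -> np.ndarray:
        return self.svc.predict(self._features(data))

    def score(self, test: EpochedDataset) -> float:
        """Balanced accuracy on a test split."""
        y_true = test.labels == TARGET
        return balanced_accuracy_from_labels(y_true, self.predict(test) == 1)


def fit_chain(
    train: EpochedDataset, sensors: SensorSet, cfg: ChainConfig = ChainConfig()
) -> ChainModel:
    """Train the full chain on one split, restricted to ``sensors``."""
    data = train.restrict(sensors)
    weights = class_weights(data.labels)  # raises on single-class input
    pre = lowpass(standardize_epochs(data), cfg.lowpass_hz, cfg.lowpass_order)
    fm: Optional[FilterModel] = None
    if pre.n_channels > cfg.n_xdawn:
        fm = fit_xdawn(pre, n_filters=cfg.n_xdawn)
        virt = fm.apply(pre.epochs)
        pre = EpochedDataset(
            epochs=virt,
            labels=pre.labels,
            window_ms=pre.window_ms,
            sample_rate=pre.sample_rate,
            channel_names=[f"xdawn{i}" for i in range(fm.n_filters)],
            run_id=pre.run_id,
            session_id=pre.session_id,
            subject_id=pre.subject_id,
        )
    feats = slope_features(pre, cfg.seg_len_ms, cfg.seg_step_ms)
    scaler = StandardScaler().fit(feats.matrix)
    X = scaler.transform(feats.matrix)
    y = (data.labels == TARGET).astype(int)
    c = _grid_search_c(X, y, cfg, weights)
    svc = make_svm(2, c, weights)
    svc.fit(X, y)
    return ChainModel(sensors=sensors, cfg=cfg, filter_model=fm, scaler=scaler, svc=svc)


def run_chain(
    train: EpochedDataset,
    test: EpochedDataset,
    sensors: SensorSet,
    cfg: ChainConfig = ChainConfig(),
) -> float:
    """Train on one split, evaluate balanced accuracy on the other."""
    return fit_chain(train, sensors, cfg).score(test)
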