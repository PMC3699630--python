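"""Sensor-set ranking criteria R(S) behind one plug-in interface.

Eight criteria, all returning a real-valued score where higher is better:

====================  ======================================================
``xdawn/csp/pca``     sum over sensors of absolute spatial-filter weights in
                      the k most relevant filters, filters fitted on the set
``ssnr_s``            sum of per-sensor SSNRs (sensor space; additive)
``ssnr_v``            sum of the SSNRs of the first k xDAWN virtual channels
                      fitted on the set (virtual space; redundancy-aware)
``svm1/svm2``         sum of absolute linear-SVM feature weights per sensor,
                      1-norm / 2-norm penalty, no spatial filter in the chain
``performance``       mean balanced accuracy of the full chain over a 5-fold
                      cross-validation on the selection run
====================  ======================================================

Weight-based criteria expose per-sensor contributions, which the fast
backward-elimination variant consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .chain import (
    ChainConfig,
    balanced_accuracy,
    balanced_accuracy_from_labels,
    class_weights,
    fit_chain,
    make_svm,
)
from .core import TARGET, ContinuousRun, EpochedDataset, SensorSet, epoch
from .preprocessing import (
    FeatureTable,
    lowpass,
    slope_features,
    standardize_epochs,
)
from .spatial import (
    FilterModel,
    SSNRModel,
    fit_csp,
    fit_pca,
    fit_ssnr_model,
    ssnr_of_sensor,
    xdawn_from_ssnr_model,
)

__all__ = [
    "RANKER_IDS",
    "RankingScore",
    "SvmModel",
    "Ranker",
    "balanced_accuracy",
    "make_ranker",
    "rank_filter_weights",
    "rank_performance",
    "rank_ssnr_s",
    "rank_ssnr_v",
    "rank_svm",
    "train_ranking_svm",
]

logger = logging.getLogger("erpselect")

RANKER_IDS = (
    "xdawn", "csp", "pca", "ssnr_s", "ssnr_v", "svm1", "svm2", "performance",
)


@dataclass
class RankingScore:
    value: float
    method: str
    contributions: Optional[dict[str, float]] = None


@dataclass
class SvmModel:
    """A linear SVM in feature space with its per-sensor feature grouping."""

    weights: np.ndarray  # one weight per feature
    bias: float
    norm: int
    c: float
    feature_map: list[tuple[str, float]]
    channel_names: list[str]

    def sensor_contribution(self, channel: str) -> float:
        idx = [j for j, (ch, _) in enumerate(self.feature_map) if ch == channel]
        return float(np.sum(np.abs(self.weights[idx])))


def rank_filter_weights(
    model: FilterModel, sensors: SensorSet, k: int
) -> RankingScore:
    """Sum of absolute filter weights of each sensor in the first k filters."""
    if k > model.n_filters:
        raise ValueError(f"k={k} exceeds the {model.n_filters} fitted filters")
    lookup = {name: i for i, name in enumerate(model.channel_names)}
    contrib: dict[str, float] = {}
    for ch in sensors:
        if ch not in lookup:
            raise KeyError(f"sensor {ch!r} not covered by the filter model")
        contrib[ch] = float(np.sum(np.abs(model.W[lookup[ch], :k])))
    return RankingScore(
        value=float(sum(contrib.values())),
        method=model.method,
        contributions=contrib,
    )


def rank_ssnr_s(
    model_or_run: Union[SSNRModel, ContinuousRun], sensors: SensorSet
) -> RankingScore:
    """Sensor-space SSNR criterion: additive over the set's individual SSNRs."""
    model = (
        fit_ssnr_model(model_or_run)
        if isinstance(model_or_run, ContinuousRun)
        else model_or_run
    )
    contrib = {ch: ssnr_of_sensor(model, ch) for ch in sensors}
    return RankingScore(
        value=float(sum(contrib.values())), method="ssnr_s", contributions=contrib
    )


def rank_ssnr_v(
    model_or_run: Union[SSNRModel, ContinuousRun],
    sensors: SensorSet,
    k: int = 5,
) -> RankingScore:
    """Virtual-space SSNR: sum over the first k xDAWN channels on the set.

    xDAWN is refitted on the data projected onto the set, so redundant
    sensors are absorbed into shared virtual channels instead of being
    double-counted.
    """
    model = (
        fit_ssnr_model(model_or_run)
        if isinstance(model_or_run, ContinuousRun)
        else model_or_run
    )
    sub = model.restrict(sensors)
    if len(sensors) < k:
        logger.warning(
            "rank_ssnr_v: set size %d < k=%d, using k=%d",
            len(sensors), k, len(sensors),
        )
        k = len(sensors)
    fm = xdawn_from_ssnr_model(sub, n_filters=k)
    return RankingScore(value=float(np.sum(fm.values)), method="ssnr_v")


def train_ranking_svm(
    features: FeatureTable, norm: int = 1, c: float = 0.1
) -> SvmModel:
    """Train the no-spatial-filter linear SVM used for weight-based ranking."""
    y = (features.labels == TARGET).astype(int)
    weights = class_weights(features.labels)
    X = StandardScaler().fit_transform(features.matrix)
    svc = make_svm(norm, c, weights)
    svc.fit(X, y)
    return SvmModel(
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        norm=norm,
        c=c,
        feature_map=list(features.feature_map),
        channel_names=list(features.channel_names),
    )


def rank_svm(
    features: FeatureTable,
    sensors: SensorSet,
    norm: int = 1,
    c: float = 0.1,
) -> RankingScore:
    """SVM-coefficient criterion: train on the set's features, sum |weights|."""
    model = train_ranking_svm(features.restrict(sensors), norm=norm, c=c)
    contrib = {ch: model.sensor_contribution(ch) for ch in sensors}
    return RankingScore(
        value=float(sum(contrib.values())),
        method=f"svm{norm}",
        contributions=contrib,
    )


def _trial_subset(data: EpochedDataset, idx: np.ndarray) -> EpochedDataset:
    return EpochedDataset(
        epochs=data.epochs[idx],
        labels=data.labels[idx],
        window_ms=data.window_ms,
        sample_rate=data.sample_rate,
        channel_names=list(data.channel_names),
        run_id=data.run_id,
        session_id=data.session_id,
        subject_id=data.subject_id,
    )


def rank_performance(
    data: EpochedDataset,
    sensors: SensorSet,
    cfg: ChainConfig = ChainConfig(),
) -> RankingScore:
    """Mean balanced accuracy of the full chain over a k-fold CV on one run.

    Every fold retrains the entire chain (spatial filter and classifier) on
    its training split; folds whose validation split degenerates to a single
    class are skipped with a warning.
    """
    restricted = data.restrict(sensors)
    y = (restricted.labels == TARGET).astype(int)
    n_min = int(min(np.sum(y == 1), np.sum(y == 0)))
    folds = min(cfg.cv_folds, n_min)
    if folds < 2:
        raise ValueError("performance ranking needs >= 2 samples per class")
    scores = []
    for tr, va in StratifiedKFold(n_splits=folds, shuffle=False).split(
        restricted.epochs[:, 0, 0], y
    ):
        if len(np.unique(y[va])) < 2:
            logger.warning("rank_performance: single-class fold skipped")
            continue
        model = fit_chain(
            _trial_subset(restricted, tr), SensorSet(restricted.channel_names), cfg
        )
        scores.append(model.score(_trial_subset(restricted, va)))
    return RankingScore(value=float(np.mean(scores)), method="performance")


# ---------------------------------------------------------------------------
# plug-in rankers over a single selection run


class Ranker:
    """Scores sensor subsets of one selection run; higher is better."""

    method: str = ""

    def score(self, sensors: SensorSet) -> RankingScore:
        raise NotImplementedError

    def contributions(self, sensors: SensorSet) -> Optional[dict[str, float]]:
        """Per-sensor contributions under the model fitted on ``sensors``.

        ``None`` when the criterion is not an additive sum over sensors.
        """
        return None


class _SsnrContextMixin:
    def __init__(self, run: ContinuousRun, cfg: ChainConfig):
        filtered = lowpass(run, cfg.lowpass_hz, cfg.lowpass_order)
        erp_len = cfg.window_ms[1] - cfg.window_ms[0]
        self.model = fit_ssnr_model(filtered, erp_len_ms=erp_len)
        self.cfg = cfg


class SsnrSRanker(_SsnrContextMixin, Ranker):
    method = "ssnr_s"

    def score(self, sensors: SensorSet) -> RankingScore:
        return rank_ssnr_s(self.model, sensors)

    def contributions(self, sensors: SensorSet) -> dict[str, float]:
        return {ch: ssnr_of_sensor(self.model, ch) for ch in sensors}


class SsnrVRanker(_SsnrContextMixin, Ranker):
    method = "ssnr_v"

    def __init__(self, run: ContinuousRun, cfg: ChainConfig, k: int):
        super().__init__(run, cfg)
        self.k = k

    def score(self, sensors: SensorSet) -> RankingScore:
        return rank_ssnr_v(self.model, sensors, self.k)


class XdawnWeightRanker(_SsnrContextMixin, Ranker):
    method = "xdawn"

    def __init__(self, run: ContinuousRun, cfg: ChainConfig, k: int):
        super().__init__(run, cfg)
        self.k = k

    def _fit(self, sensors: SensorSet) -> FilterModel:
        k = min(self.k, len(sensors))
        return xdawn_from_ssnr_model(self.model.restrict(sensors), n_filters=k)

    def score(self, sensors: SensorSet) -> RankingScore:
        fm = self._fit(sensors)
        return rank_filter_weights(fm, sensors, fm.n_filters)

    def contributions(self, sensors: SensorSet) -> dict[str, float]:
        fm = self._fit(sensors)
        return rank_filter_weights(fm, sensors, fm.n_filters).contributions


class _EpochFilterRanker(Ranker):
    """CSP/PCA weight ranking on standardized, low-passed epochs."""

    def __init__(self, run: ContinuousRun, cfg: ChainConfig, k: int):
        epochs = epoch(run, cfg.window_ms)
        self.epochs = lowpass(
            standardize_epochs(epochs), cfg.lowpass_hz, cfg.lowpass_order
        )
        self.k = k

    def _fit(self, sensors: SensorSet) -> FilterModel:
        raise NotImplementedError

    def score(self, sensors: SensorSet) -> RankingScore:
        fm = self._fit(sensors)
        return rank_filter_weights(fm, sensors, fm.n_filters)

    def contributions(self, sensors: SensorSet) -> dict[str, float]:
        fm = self._fit(sensors)
        return rank_filter_weights(fm, sensors, fm.n_filters).contributions


class CspWeightRanker(_EpochFilterRanker):
    method = "csp"

    def _fit(self, sensors: SensorSet) -> FilterModel:
        k = min(self.k, len(sensors))
        return fit_csp(self.epochs.restrict(sensors), n_filters=k)


class PcaWeightRanker(_EpochFilterRanker):
    method = "pca"

    def _fit(self, sensors: SensorSet) -> FilterModel:
        k = min(self.k, len(sensors))
        return fit_pca(self.epochs.restrict(sensors), n_filters=k)


class SvmWeightRanker(Ranker):
    """1-norm / 2-norm SVM coefficient ranking (no spatial filter)."""

    def __init__(self, run: ContinuousRun, cfg: ChainConfig, norm: int):
        epochs = lowpass(
            standardize_epochs(epoch(run, cfg.window_ms)),
            cfg.lowpass_hz,
            cfg.lowpass_order,
        )
        self.features = slope_features(epochs, cfg.seg_len_ms, cfg.seg_step_ms)
        self.norm = norm
        self.method = f"svm{norm}"
        self.c = cfg.ranking_svm_c

    def score(self, sensors: SensorSet) -> RankingScore:
        return rank_svm(self.features, sensors, norm=self.norm, c=self.c)

    def contributions(self, sensors: SensorSet) -> dict[str, float]:
        return self.score(sensors).contributions


class PerformanceRanker(Ranker):
    method = "performance"

    def __init__(self, run: ContinuousRun, cfg: ChainConfig):
        self.epochs = epoch(run, cfg.window_ms)
        self.cfg = cfg

    def score(self, sensors: SensorSet) -> RankingScore:
        return rank_performance(self.epochs, sensors, self.cfg)


def make_ranker(
    method: str,
    run: ContinuousRun,
    cfg: ChainConfig = ChainConfig(),
    k: Optional[int] = None,
) -> Ranker:
    """Instantiate a ranking criterion over one selection run.

    ``k`` is the retained-filter count of the weight- and virtual-space
    criteria; it defaults to the chain's xDAWN retention count.
    """
    k = cfg.n_xdawn if k is None else k
    if method == "ssnr_s":
        return SsnrSRanker(run, cfg)
    if method == "ssnr_v":
        return SsnrVRanker(run, cfg, k)
    if method == "xdawn":
        return XdawnWeightRanker(run, cfg, k)
    if method == "csp":
        return CspWeightRanker(run, cfg, k)
    if method == "pca":
        return PcaWeightRanker(run, cfg, k)
    if method in ("svm1", "svm2"):
        return SvmWeightRanker(run, cfg, int(method[-1]))
    if method == "performance":
        return PerformanceRanker(run, cfg)
    raise KeyError(f"unknown ranking method {method!r}; known: {RANKER_IDS}")
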