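"""Spatial filters (xDAWN, CSP, PCA) and the SSNR signal decomposition.

The signal-to-signal-plus-noise-ratio (SSNR) machinery follows the
least-squares decomposition of a continuous recording into (i) a response
evoked only by target stimuli, (ii) a response common to every stimulus, and
(iii) residual noise.  With ``X`` the channels x samples recording, ``D1``
the target-onset design matrix and ``D2`` the all-stimulus design matrix
(both Toeplitz-like matrices of shifted onset indicators), the responses
``A1, A2`` solve

    min_{A1,A2} || X^T - D1 A1 - D2 A2 ||_F^2 .

The SSNR of sensor ``i`` is the energy ratio ||D1 A1 e_i||^2 / ||X^T e_i||^2,
and of a spatial filter ``w`` the same ratio on the virtual channel ``X^T w``.
xDAWN filters are the stationary points of that ratio, obtained here as a
generalized symmetric eigenproblem on (ERP-component Gram, total signal Gram).

Because the least-squares fit is column-separable in channels, a fitted
:class:`SSNRModel` can be restricted to a channel subset exactly, without
re-solving — backward elimination exploits this heavily.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import scipy.linalg
import scipy.sparse

from .core import TARGET, ContinuousRun, EpochedDataset, SensorSet

logger = logging.getLogger("erpselect")

DEFAULT_ERP_LEN_MS = 1000.0
DEFAULT_N_FILTERS = 5
_RIDGE_EPS = 1e-6


@dataclass
class FilterModel:
    """A bank of spatial filters, most relevant first.

    ``W`` is channels x n_filters; ``values`` holds the per-filter criterion
    (SSNR for xDAWN, max(lambda, 1-lambda) for CSP, eigenvalue for PCA) in
    weakly decreasing order.
    """

    W: np.ndarray
    method: str
    n_filters: int
    values: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        if self.W.shape[1] != self.n_filters:
            raise ValueError("W must have n_filters columns")
        if self.n_filters > self.W.shape[0]:
            raise ValueError("cannot retain more filters than channels")

    def apply(self, epochs: np.ndarray) -> np.ndarray:
        """Project trials x channels x samples onto the filter bank."""
        return np.einsum("cf,tcs->tfs", self.W, epochs)


def build_design(
    events: Sequence[tuple[int, str]],
    n_samples: int,
    erp_len_samples: int,
    which: str,
) -> scipy.sparse.csr_matrix:
    """Shifted-onset indicator design matrix (samples x erp_len).

    Column ``j`` carries a 1 at row ``onset + j`` for every selected event;
    overlapping responses superpose linearly in the model.  Events whose
    response would extend past the recording end are truncated there.
    """
    if erp_len_samples < 1:
        raise ValueError("erp_len_samples must be >= 1")
    if which not in ("target", "all"):
        raise ValueError("which must be 'target' or 'all'")
    onsets = [
        o for o, cls in events if which == "all" or cls == TARGET
    ]
    rows, cols = [], []
    truncated = 0
    for onset in onsets:
        end = min(erp_len_samples, n_samples - onset)
        if end < erp_len_samples:
            truncated += 1
        rows.extend(range(onset, onset + end))
        cols.extend(range(end))
    if truncated:
        logger.warning(
            "build_design: truncated %d event response(s) at recording end",
            truncated,
        )
    data = np.ones(len(rows))
    return scipy.sparse.csr_matrix(
        (data, (rows, cols)), shape=(n_samples, erp_len_samples)
    )


@dataclass
class SSNRModel:
    """Fitted least-squares decomposition of one continuous run.

    Besides the response estimates ``A1`` (target-only) and ``A2``
    (all-stimulus), the model caches the channel Gram matrices of the ERP
    component (``erp_gram`` = (D1 A1)^T (D1 A1)) and of the raw signal
    (``signal_gram`` = X X^T); every SSNR quantity and every channel-subset
    restriction derives from those two matrices alone.
    """

    D1: scipy.sparse.csr_matrix
    D2: scipy.sparse.csr_matrix
    A1: np.ndarray  # erp_len x channels
    A2: np.ndarray
    erp_len_ms: float
    channel_names: list[str]
    erp_gram: np.ndarray
    signal_gram: np.ndarray

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def restrict(self, sensors: Union[SensorSet, Sequence[str]]) -> "SSNRModel":
        """Exact model for the channel subset (least squares is per-channel)."""
        if not isinstance(sensors, SensorSet):
            sensors = SensorSet(sensors)
        idx = sensors.indices_in(self.channel_names)
        return SSNRModel(
            D1=self.D1,
            D2=self.D2,
            A1=self.A1[:, idx],
            A2=self.A2[:, idx],
            erp_len_ms=self.erp_len_ms,
            channel_names=list(sensors),
            erp_gram=self.erp_gram[np.ix_(idx, idx)],
            signal_gram=self.signal_gram[np.ix_(idx, idx)],
        )


def fit_ssnr_model(
    run: ContinuousRun,
    erp_len_ms: float = DEFAULT_ERP_LEN_MS,
    ridge: Optional[float] = None,
) -> SSNRModel:
    """Fit the three-component least-squares model to a continuous run.

    Solved through the normal equations on the sparse joint design; a
    rank-deficient design falls back to a minimum-norm (SVD) solution, or to
    an explicit ridge if ``ridge`` is given.
    """
    erp_len = int(round(erp_len_ms * run.sample_rate / 1000.0))
    D1 = build_design(run.events, run.n_samples, erp_len, "target")
    D2 = build_design(run.events, run.n_samples, erp_len, "all")
    XT = run.signal.T  # samples x channels
    has_target = any(cls == TARGET for _, cls in run.events)
    has_standard = any(cls != TARGET for _, cls in run.events)
    # with a single stimulus class the target-specific and common responses
    # are not separately identifiable; fit only the identifiable block
    if has_target and not has_standard:
        blocks = [D1]
    elif run.events:
        blocks = [D1, D2] if has_target else [D2]
    else:
        blocks = []
    if blocks:
        D = scipy.sparse.hstack(blocks, format="csr")
        DtD = (D.T @ D).toarray()
        DtX = D.T @ XT
        if ridge is not None:
            DtD = DtD + ridge * np.eye(DtD.shape[0])
        try:
            coef = scipy.linalg.solve(DtD, DtX, assume_a="pos")
        except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
            logger.warning(
                "fit_ssnr_model: joint design rank-deficient on run %s; "
                "using minimum-norm least squares", run.run_id,
            )
            coef, *_ = np.linalg.lstsq(DtD, DtX, rcond=None)
    else:
        coef = np.zeros((0, run.n_channels))
    zeros = np.zeros((erp_len, run.n_channels))
    if has_target and not has_standard:
        A1, A2 = coef, zeros
    elif has_target:
        A1, A2 = coef[:erp_len], coef[erp_len:]
    else:
        A1, A2 = zeros, (coef if run.events else zeros)
    erp_signal = D1 @ A1  # samples x channels
    return SSNRModel(
        D1=D1,
        D2=D2,
        A1=A1,
        A2=A2,
        erp_len_ms=erp_len_ms,
        channel_names=list(run.channel_names),
        erp_gram=erp_signal.T @ erp_signal,
        signal_gram=run.signal @ XT,
    )


def _channel_index(model: SSNRModel, channel: Union[int, str]) -> int:
    if isinstance(channel, str):
        return model.channel_names.index(channel)
    return int(channel)


def ssnr_of_sensor(model: SSNRModel, channel: Union[int, str]) -> float:
    """SSNR of one physical sensor: ERP-component energy / signal energy."""
    i = _channel_index(model, channel)
    total = model.signal_gram[i, i]
    if total <= 0:
        return 0.0
    return float(np.clip(model.erp_gram[i, i] / total, 0.0, 1.0))


def ssnr_of_filter(model: SSNRModel, w: np.ndarray) -> float:
    """SSNR of the virtual channel X^T w; invariant to rescaling of ``w``."""
    w = np.asarray(w, dtype=np.float64)
    if w.shape != (model.n_channels,):
        raise ValueError(
            f"filter length {w.shape} does not match {model.n_channels} channels"
        )
    total = float(w @ model.signal_gram @ w)
    if total <= 0:
        raise ValueError("zero filter (or zero-energy projection)")
    return float(np.clip((w @ model.erp_gram @ w) / total, 0.0, 1.0))


def _generalized_eigh(
    S1: np.ndarray, Sx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """eigh(S1, Sx) with an automatic ridge on Sx if it is singular."""
    try:
        return scipy.linalg.eigh(S1, Sx)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
        ridge = _RIDGE_EPS * np.trace(Sx) / Sx.shape[0]
        if ridge <= 0:
            ridge = _RIDGE_EPS
        logger.warning(
            "generalized eigenproblem: singular denominator, ridge %.3g added",
            ridge,
        )
        return scipy.linalg.eigh(S1, Sx + ridge * np.eye(Sx.shape[0]))


def xdawn_from_ssnr_model(
    model: SSNRModel, n_filters: Optional[int] = None
) -> FilterModel:
    """xDAWN filter bank from a fitted SSNR model (eigenvalues are SSNRs)."""
    vals, vecs = _generalized_eigh(model.erp_gram, model.signal_gram)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, 1.0)
    vecs = vecs[:, order]
    k = model.n_channels if n_filters is None else min(n_filters, model.n_channels)
    return FilterModel(
        W=vecs[:, :k],
        method="xdawn",
        n_filters=k,
        values=vals[:k],
        channel_names=list(model.channel_names),
    )


def _epoch_covariances(epochs: EpochedDataset) -> dict[str, np.ndarray]:
    """Per-class and pooled channel Gram matrices of an epoched dataset."""
    out: dict[str, np.ndarray] = {}
    n, s = epochs.n_trials, epochs.n_samples
    x = epochs.epochs
    flat = np.swapaxes(x, 0, 1).reshape(epochs.n_channels, n * s)
    out["total"] = flat @ flat.T / (n * s)
    for cls in ("standard", "target"):
        mask = epochs.labels == cls
        if mask.any():
            xc = x[mask]
            fc = np.swapaxes(xc, 0, 1).reshape(epochs.n_channels, -1)
            out[cls] = fc @ fc.T / fc.shape[1]
    return out


def fit_xdawn(
    data: Union[ContinuousRun, EpochedDataset],
    n_filters: Optional[int] = None,
    erp_len_ms: float = DEFAULT_ERP_LEN_MS,
) -> FilterModel:
    """Spatial filters maximizing the evoked-response SSNR.

    On a continuous run the exact least-squares decomposition is used and the
    reported per-filter values are SSNRs in [0, 1].  On an epoched dataset the
    target-average waveform stands in for the ERP component estimate, and the
    values are ERP-energy/total-energy ratios on the same relevance ordering.
    """
    if isinstance(data, ContinuousRun):
        if not any(cls == TARGET for _, cls in data.events):
            raise ValueError("xDAWN needs at least one target event")
        return xdawn_from_ssnr_model(fit_ssnr_model(data, erp_len_ms), n_filters)
    mask = data.labels == TARGET
    if not mask.any():
        raise ValueError("xDAWN needs at least one target trial")
    mean_target = data.epochs[mask].mean(axis=0)  # channels x samples
    S1 = (mean_target @ mean_target.T) / data.n_samples
    Sx = _epoch_covariances(data)["total"]
    vals, vecs = _generalized_eigh(S1, Sx)
    order = np.argsort(vals)[::-1]
    k = data.n_channels if n_filters is None else min(n_filters, data.n_channels)
    return FilterModel(
        W=vecs[:, order][:, :k],
        method="xdawn",
        n_filters=k,
        values=np.maximum(vals[order][:k], 0.0),
        channel_names=list(data.channel_names),
    )


def fit_csp(
    epochs: EpochedDataset, n_filters: Optional[int] = None
) -> FilterModel:
    """Common spatial patterns for the target/standard variance contrast.

    Generalized eigenvectors of (Sigma_target, Sigma_target + Sigma_standard);
    filters are retained alternately from both eigenvalue extremes and the
    per-filter relevance is max(lambda, 1 - lambda).
    """
    covs = _epoch_covariances(epochs)
    if "target" not in covs or "standard" not in covs:
        raise ValueError("CSP needs trials from both classes")
    St, Ss = covs["target"], covs["standard"]
    vals, vecs = _generalized_eigh(St, St + Ss)
    # eigh returns ascending eigenvalues; interleave extremes: high, low, ...
    n = len(vals)
    order = []
    lo, hi = 0, n - 1
    while lo <= hi:
        order.append(hi)
        if lo < hi:
            order.append(lo)
        hi -= 1
        lo += 1
    order = np.asarray(order)
    relevance = np.maximum(vals[order], 1.0 - vals[order])
    k = epochs.n_channels if n_filters is None else min(n_filters, n)
    return FilterModel(
        W=vecs[:, order][:, :k],
        method="csp",
        n_filters=k,
        values=relevance[:k],
        channel_names=list(epochs.channel_names),
    )


def fit_pca(
    epochs: EpochedDataset, n_filters: Optional[int] = None
) -> FilterModel:
    """Principal axes of the pooled channel covariance, descending variance."""
    if epochs.n_trials < 2:
        raise ValueError("PCA needs at least 2 trials")
    x = epochs.epochs
    flat = np.swapaxes(x, 0, 1).reshape(epochs.n_channels, -1)
    centered = flat - flat.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / centered.shape[1]
    vals, vecs = scipy.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    k = epochs.n_channels if n_filters is None else min(n_filters, epochs.n_channels)
    return FilterModel(
        W=vecs[:, order][:, :k],
        method="pca",
        n_filters=k,
        values=np.maximum(vals[order][:k], 0.0),
        channel_names=list(epochs.channel_names),
    )
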