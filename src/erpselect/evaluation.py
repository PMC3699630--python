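"""Intra-/inter-session benchmarking of sensor selection methods.

Both schemes separate three roles: the data the selection is computed on, the
data the chain is trained on, and the data it is scored on.  *Intra-session*
selects on the very run the chain is then trained on and tests on the
session's remaining runs (a jackknife over runs).  *Inter-session* transfers
the selected constellation — never the trained chain — to a different session
of the same subject: selection on each run of session A, training on each run
of session B, testing on B's remaining runs.

Score tables are tidy pandas DataFrames with one row per
(selection run, train run, test run, method, size) combination.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .chain import ChainConfig, ChainModel, fit_chain, run_chain
from .constellations import BetaFit
from .core import (
    ChannelLayout,
    ContinuousRun,
    EpochedDataset,
    SensorSet,
    epoch,
    get_layout,
)
from .ranking import RANKER_IDS, make_ranker
from .search import (
    EliminationTrace,
    backward_eliminate,
    backward_eliminate_fast,
    sample_random_constellations,
)

__all__ = [
    "SCORE_COLUMNS",
    "cap_baseline",
    "evaluate_inter",
    "evaluate_intra",
    "random_constellation_accuracies",
    "report",
    "run_chain",
    "select_constellations",
]

logger = logging.getLogger("erpselect")

SCORE_COLUMNS = [
    "subject", "session", "scheme", "method", "size",
    "selection_run", "train_run", "test_run", "bacc",
]

#: criteria whose additive per-sensor contributions allow the fast RBE
FAST_METHODS = ("xdawn", "csp", "pca", "ssnr_s", "svm1", "svm2")


def _full_set(run: ContinuousRun) -> SensorSet:
    return SensorSet(run.channel_names)


def select_constellations(
    method: str,
    run: ContinuousRun,
    sizes: Sequence[int],
    cfg: ChainConfig = ChainConfig(),
    engine: str = "auto",
) -> dict[int, SensorSet]:
    """Backward-eliminate on one run; returns the retained set per size.

    ``engine`` is ``auto`` (fast single-fit-per-step elimination for additive
    weight criteria, generic otherwise), ``generic`` or ``fast``.
    """
    full = _full_set(run)
    ranker = make_ranker(method, run, cfg)
    if engine == "auto":
        engine = "fast" if method in FAST_METHODS else "generic"
    eliminate = backward_eliminate_fast if engine == "fast" else backward_eliminate
    trace = eliminate(ranker, full, min(sizes))
    return {m: trace.at(m) for m in sizes}


def _random_sets(
    full: SensorSet, sizes: Sequence[int], seed: int
) -> dict[int, SensorSet]:
    """One reusable random constellation per size (selection-run independent)."""
    out = {}
    for m in sizes:
        rng = np.random.default_rng(np.random.SeedSequence([seed, m]))
        out[m] = sample_random_constellations(full, m, 1, rng=rng)[0]
    return out


def _epoch_all(
    runs: Sequence[ContinuousRun], cfg: ChainConfig
) -> list[EpochedDataset]:
    return [epoch(r, cfg.window_ms) for r in runs]


def _score_rows(
    sets: dict[int, SensorSet],
    train: EpochedDataset,
    tests: Sequence[EpochedDataset],
    scheme: str,
    method: str,
    selection_run: str,
    cfg: ChainConfig,
) -> list[dict]:
    rows = []
    for size, sensors in sets.items():
        model = fit_chain(train, sensors, cfg)
        for test in tests:
            rows.append(
                {
                    "subject": train.subject_id,
                    "session": train.session_id,
                    "scheme": scheme,
                    "method": method,
                    "size": size,
                    "selection_run": selection_run,
                    "train_run": train.run_id,
                    "test_run": test.run_id,
                    "bacc": model.score(test),
                }
            )
    return rows


def evaluate_intra(
    session_runs: Sequence[ContinuousRun],
    method: str,
    sizes: Sequence[int],
    cfg: ChainConfig = ChainConfig(),
    seed: int = 0,
    engine: str = "auto",
) -> pd.DataFrame:
    """Intra-session scheme: select on run r, train on r, test on the rest.

    Yields ``n_runs * (n_runs - 1)`` scores per size.  ``method`` is any
    ranking criterion id or ``"random"`` for the seeded random baseline
    (whose constellation is shared across selection runs).
    """
    if len(session_runs) < 2:
        raise ValueError("intra-session evaluation needs >= 2 runs")
    epochs = _epoch_all(session_runs, cfg)
    rows: list[dict] = []
    random_sets = (
        _random_sets(_full_set(session_runs[0]), sizes, seed)
        if method == "random"
        else None
    )
    for i, run in enumerate(session_runs):
        sets = (
            random_sets
            if random_sets is not None
            else select_constellations(method, run, sizes, cfg, engine)
        )
        tests = [e for j, e in enumerate(epochs) if j != i]
        rows.extend(
            _score_rows(sets, epochs[i], tests, "intra", method, run.run_id, cfg)
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def evaluate_inter(
    session_a_runs: Sequence[ContinuousRun],
    session_b_runs: Sequence[ContinuousRun],
    method: str,
    sizes: Sequence[int],
    cfg: ChainConfig = ChainConfig(),
    seed: int = 0,
    engine: str = "auto",
) -> pd.DataFrame:
    """Inter-session scheme: constellations transfer, trained chains do not.

    Selection on each run of session A; for each training run of session B
    the chain is trained there and tested on B's remaining runs, giving
    ``n_a * n_b * (n_b - 1)`` scores per size.
    """
    if len(session_b_runs) < 2:
        raise ValueError("inter-session evaluation needs >= 2 usage-session runs")
    epochs_b = _epoch_all(session_b_runs, cfg)
    rows: list[dict] = []
    random_sets = (
        _random_sets(_full_set(session_a_runs[0]), sizes, seed)
        if method == "random"
        else None
    )
    for sel_run in session_a_runs:
        sets = (
            random_sets
            if random_sets is not None
            else select_constellations(method, sel_run, sizes, cfg, engine)
        )
        for j, train in enumerate(epochs_b):
            tests = [e for t, e in enumerate(epochs_b) if t != j]
            rows.extend(
                _score_rows(
                    sets, train, tests, "inter", method, sel_run.run_id, cfg
                )
            )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def cap_baseline(
    layout: Union[str, ChannelLayout],
    session_runs: Sequence[ContinuousRun],
    cfg: ChainConfig = ChainConfig(),
) -> pd.DataFrame:
    """Fixed commercial-cap constellation, no selection involved.

    Because nothing is adapted to a session, the same scores apply to both
    evaluation schemes; rows are emitted with scheme ``"cap"``.
    """
    if isinstance(layout, str):
        layout = get_layout(layout)
    available = set(session_runs[0].channel_names)
    missing = [c for c in layout.channels if c not in available]
    if missing:
        raise ValueError(f"layout {layout.name} channels absent from data: {missing}")
    sensors = layout.sensor_set()
    epochs = _epoch_all(session_runs, cfg)
    rows: list[dict] = []
    for i, train in enumerate(epochs):
        tests = [e for j, e in enumerate(epochs) if j != i]
        rows.extend(
            _score_rows(
                {len(sensors): sensors}, train, tests, "cap",
                f"cap-{layout.name}", "none", cfg,
            )
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def random_constellation_accuracies(
    session_runs: Sequence[ContinuousRun],
    size: int,
    n: int,
    cfg: ChainConfig = ChainConfig(),
    seed: int = 0,
    train_run: int = 0,
) -> tuple[list[SensorSet], np.ndarray]:
    """Balanced accuracies of n random constellations of one size.

    Each constellation's chain is trained on ``train_run`` and its score is
    the mean balanced accuracy over the session's remaining runs.  This is
    the sample the beta model of constellation performance is fitted to.
    """
    epochs = _epoch_all(session_runs, cfg)
    train = epochs[train_run]
    tests = [e for j, e in enumerate(epochs) if j != train_run]
    constellations = sample_random_constellations(
        _full_set(session_runs[0]), size, n, seed=seed
    )
    accs = np.empty(n)
    for i, sensors in enumerate(constellations):
        model = fit_chain(train, sensors, cfg)
        accs[i] = float(np.mean([model.score(t) for t in tests]))
    return constellations, accs


def report(
    tables: Union[pd.DataFrame, Sequence[pd.DataFrame]],
    beta_fits: Optional[dict[int, BetaFit]] = None,
    path: Optional[Union[str, Path]] = None,
) -> dict:
    """Mean-performance curves (bACC vs size per method) as a JSON-able dict."""
    if not isinstance(tables, pd.DataFrame):
        tables = (
            pd.concat(tables, ignore_index=True)
            if len(tables)
            else pd.DataFrame(columns=SCORE_COLUMNS)
        )
    curves: dict[str, dict] = {}
    if len(tables):
        grouped = tables.groupby(["scheme", "method", "size"])["bacc"]
        for (scheme, method, size), mean in grouped.mean().items():
            key = f"{scheme}:{method}"
            entry = curves.setdefault(key, {"sizes": [], "mean_bacc": []})
            entry["sizes"].append(int(size))
            entry["mean_bacc"].append(float(mean))
    out = {
        "curves": curves,
        "n_scores": int(len(tables)),
        "beta_fits": {
            str(m): {
                "alpha": f.alpha,
                "beta": f.beta,
                "n_samples": f.n_samples,
                "size": f.size,
            }
            for m, f in (beta_fits or {}).items()
        },
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)
    return out


def plot_curves(report_dict: dict, path: Union[str, Path]) -> None:
    """Render the report's mean curves to a figure file (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for key, entry in report_dict["curves"].items():
        order = np.argsort(entry["sizes"])
        ax.plot(
            np.asarray(entry["sizes"])[order],
            np.asarray(entry["mean_bacc"])[order],
            marker="o", label=key,
        )
    ax.set_xlabel("number of sensors")
    ax.set_ylabel("mean balanced accuracy")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
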