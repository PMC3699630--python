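"""Search over sensor constellations: recursive backward elimination (RBE),
an exhaustive small-instance oracle, and random-constellation baselines.

RBE starts from the full sensor set and repeatedly drops the sensor whose
removal leaves the best-scoring subset.  For criteria that expose per-sensor
contributions the fast variant removes the minimum-contribution sensor after
a single criterion fit per step instead of one fit per candidate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb
from typing import Optional, Sequence

import numpy as np

from .core import SensorSet
from .ranking import Ranker

logger = logging.getLogger("erpselect")

EXHAUSTIVE_CAP = 100_000


@dataclass
class EliminationTrace:
    """Retained sensor set and criterion score at every visited size."""

    method: str
    sets: dict[int, SensorSet] = field(default_factory=dict)
    scores: dict[int, float] = field(default_factory=dict)

    def record(self, sensors: SensorSet, score: float) -> None:
        self.sets[len(sensors)] = sensors
        self.scores[len(sensors)] = score

    def at(self, size: int) -> SensorSet:
        return self.sets[size]

    @property
    def sizes(self) -> list[int]:
        return sorted(self.sets, reverse=True)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "steps": [
                {
                    "size": m,
                    "sensors": list(self.sets[m]),
                    "score": self.scores[m],
                }
                for m in self.sizes
            ],
        }


def _safe_score(ranker: Ranker, sensors: SensorSet) -> float:
    try:
        return ranker.score(sensors).value
    except Exception as exc:  # scored -inf so the search stays total
        logger.warning(
            "ranker %s failed on %s: %s; candidate scored -inf",
            ranker.method, list(sensors), exc,
        )
        return float("-inf")


def backward_eliminate(
    ranker: Ranker, full_set: SensorSet, target_size: int
) -> EliminationTrace:
    """Generic RBE: every single-sensor removal is scored with a refit.

    At each step the retained set is the argmax-score candidate; ties are
    broken by removing the sensor earliest in the current set's order (i.e.
    lowest channel index).
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    if target_size > len(full_set):
        raise ValueError("target_size exceeds the full set size")
    trace = EliminationTrace(method=ranker.method)
    current = full_set
    trace.record(current, _safe_score(ranker, current))
    while len(current) > target_size:
        best_set, best_score = None, float("-inf")
        for ch in current:
            candidate = current.without(ch)
            score = _safe_score(ranker, candidate)
            if score > best_score:  # strict: first (lowest-index) wins ties
                best_set, best_score = candidate, score
        current = best_set
        trace.record(current, best_score)
    return trace


def backward_eliminate_fast(
    ranker: Ranker, full_set: SensorSet, target_size: int
) -> EliminationTrace:
    """Contribution-based RBE: one criterion fit per step.

    Requires a ranker whose score is an additive sum of per-sensor
    contributions (filter-weight, SVM-weight and sensor-space SSNR criteria);
    the minimum-contribution sensor is removed, ties by lowest channel index.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    if target_size > len(full_set):
        raise ValueError("target_size exceeds the full set size")
    trace = EliminationTrace(method=ranker.method)
    current = full_set

    def fit(sensors: SensorSet) -> dict[str, float]:
        contrib = ranker.contributions(sensors)
        if contrib is None:
            raise ValueError(
                f"ranker {ranker.method!r} exposes no per-sensor contributions"
            )
        return contrib

    contrib = fit(current)
    trace.record(current, float(sum(contrib.values())))
    while len(current) > target_size:
        min_contrib = min(contrib[ch] for ch in current)
        worst = next(ch for ch in current if contrib[ch] == min_contrib)
        current = current.without(worst)
        contrib = fit(current)
        trace.record(current, float(sum(contrib.values())))
    return trace


def exhaustive_best(
    ranker: Ranker,
    full_set: SensorSet,
    size: int,
    cap: int = EXHAUSTIVE_CAP,
) -> tuple[SensorSet, float]:
    """Global argmax over all subsets of the given size (small instances).

    Raises when the number of subsets exceeds ``cap``; use backward
    elimination beyond that scale.
    """
    n = len(full_set)
    if size > n:
        raise ValueError("size exceeds the full set")
    n_subsets = comb(n, size)
    if n_subsets > cap:
        raise ValueError(
            f"{n_subsets} subsets exceed the cap of {cap}; "
            "use backward elimination instead"
        )
    best_set, best_score = None, float("-inf")
    for members in itertools.combinations(full_set, size):
        candidate = SensorSet(members)
        score = _safe_score(ranker, candidate)
        if score > best_score:
            best_set, best_score = candidate, score
    return best_set, best_score


def sample_random_constellations(
    full_set: SensorSet,
    size: int,
    n: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[SensorSet]:
    """n uniform random constellations of the given size (layout order kept)."""
    if size > len(full_set):
        raise ValueError("size exceeds the full set")
    if rng is None:
        rng = np.random.default_rng(seed)
    members = full_set.members
    out = []
    for _ in range(n):
        idx = np.sort(rng.choice(len(members), size=size, replace=False))
        out.append(SensorSet(members[i] for i in idx))
    return out
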