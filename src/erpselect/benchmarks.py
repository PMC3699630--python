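"""Reference study conditions for the synthetic sensor-selection benchmark.

Two canonical configurations:

* :func:`benchmark_config` — the default benchmark: a 32-channel cap with 10
  centro-parietal informative sensors at medium SNR, used for ground-truth
  recovery, random-baseline comparisons and session-transfer contrasts.
* :func:`chance_config` — the negative control: the target-only component is
  switched off entirely (``erp_amplitude = 0``), so no method can legitimately
  exceed chance-level balanced accuracy.

Stimulus counts are scaled to a few hundred trials per run so a full
benchmark repetition runs on a single CPU in minutes; the simulation's
session structure (2 sessions, multiple runs, rare targets, 1 s jittered
stimulus train) is kept.
"""

from __future__ import annotations

from .core import get_layout
from .synthetic import DEFAULT_INFORMATIVE, SimulationConfig

#: 12-channel reduced montage used by the chance-level control
CONTROL_CHANNELS = (
    "Fp1", "Fz", "F3", "FC1", "C3", "Cz", "C4", "CP1", "CP2", "P3", "Pz", "P4",
)


def benchmark_config(seed: int, n_runs: int = 2) -> SimulationConfig:
    """Default benchmark: 10 informative sensors in an actiCAP-32 montage."""
    return SimulationConfig(
        n_runs=n_runs,
        n_standards_per_run=240,
        n_targets_per_run=40,
        channel_names=tuple(get_layout("actiCAP-32").channels),
        informative_sensors=DEFAULT_INFORMATIVE,
        # medium SNR: the all-sensor chain scores high but below ceiling,
        # random reduced constellations spread over the mid range
        erp_amplitude=0.5,
        noise_sd=1.0,
        session_perturbation_sd=0.25,
        seed=seed,
    )


def chance_config(seed: int, n_runs: int = 3) -> SimulationConfig:
    """Negative control: no target-specific component anywhere."""
    return SimulationConfig(
        n_runs=n_runs,
        n_standards_per_run=120,
        n_targets_per_run=30,
        channel_names=CONTROL_CHANNELS,
        informative_sensors=CONTROL_CHANNELS[-5:],
        erp_amplitude=0.0,
        noise_sd=1.0,
        seed=seed,
    )
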