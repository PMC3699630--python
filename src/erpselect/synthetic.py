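"""Synthetic oddball-paradigm ERP recordings with known informative sensors.

The generator emulates the statistical structure that ERP sensor selection
relies on: rare *target* stimuli among frequent *standards*, a class-shared
early visual negativity over occipito-parietal sites (~200 ms), a target-only
late positivity (a P300-like component, ~600 ms) confined to a configured set
of informative sensors, additive background noise per channel, and
session-to-session perturbations of the component loadings that model sensor
repositioning and impedance changes between recording days.

Each component is a Gaussian-windowed bump (a smooth unimodal deflection) —
the morphology of averaged evoked responses — added to the continuous signal
at every qualifying stimulus onset.  No head-model forward simulation and no
ocular/muscular artifacts are attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    STANDARD,
    TARGET,
    ContinuousRun,
    SensorSet,
    get_layout,
)

DEFAULT_INFORMATIVE = (
    "Cz", "CP1", "CP2", "CP5", "CP6", "P3", "Pz", "P4", "P7", "P8",
)


@dataclass
class SimulationConfig:
    """Study-design and signal parameters of the synthetic oddball recordings.

    Amplitudes and the noise standard deviation share one arbitrary unit;
    latencies/widths are milliseconds.  ``visual_amplitude`` is the magnitude
    of the early *negative* visual deflection (applied with negative sign).
    """

    n_subjects: int = 1
    n_sessions: int = 2
    n_runs: int = 5
    n_standards_per_run: int = 720
    n_targets_per_run: int = 120
    sample_rate: float = 100.0
    isi_ms: float = 1000.0
    isi_jitter_ms: float = 100.0
    erp_amplitude: float = 1.0
    erp_latency_ms: float = 600.0
    erp_sigma_ms: float = 80.0
    visual_amplitude: float = 1.0
    visual_latency_ms: float = 200.0
    visual_sigma_ms: float = 30.0
    channel_names: tuple[str, ...] = tuple(get_layout("actiCAP-32").channels)
    informative_sensors: tuple[str, ...] = DEFAULT_INFORMATIVE
    noise_sd: float = 1.0
    noise_mode: str = "white"  # "white" or "pink"
    session_perturbation_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_subjects", "n_sessions", "n_runs",
            "n_standards_per_run", "n_targets_per_run",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_targets_per_run >= self.n_standards_per_run:
            raise ValueError("targets must be rarer than standards")
        if self.erp_amplitude != 0 and not self.informative_sensors:
            raise ValueError(
                "informative_sensors must be non-empty when erp_amplitude != 0"
            )
        unknown = set(self.informative_sensors) - set(self.channel_names)
        if unknown:
            raise ValueError(f"informative sensors not in layout: {unknown}")
        if self.noise_mode not in ("white", "pink"):
            raise ValueError("noise_mode must be 'white' or 'pink'")
        if self.noise_sd < 0 or self.isi_jitter_ms < 0:
            raise ValueError("noise_sd and isi_jitter_ms must be >= 0")


def ground_truth(cfg: SimulationConfig) -> SensorSet:
    """The sensors that actually carry the target-only component."""
    if cfg.erp_amplitude == 0:
        return SensorSet(())
    return SensorSet(cfg.informative_sensors)


def _bump(
    n: int, sample_rate: float, latency_ms: float, sigma_ms: float,
    amplitude: float,
) -> np.ndarray:
    """Gaussian bump sampled on [0, n) samples, peaking at ``latency_ms``."""
    t_ms = np.arange(n) * 1000.0 / sample_rate
    return amplitude * np.exp(-0.5 * ((t_ms - latency_ms) / sigma_ms) ** 2)


def _template_len(cfg: SimulationConfig) -> int:
    end_ms = max(
        cfg.erp_latency_ms + 4 * cfg.erp_sigma_ms,
        cfg.visual_latency_ms + 4 * cfg.visual_sigma_ms,
    )
    return int(round(end_ms * cfg.sample_rate / 1000.0))


def erp_template(cfg: SimulationConfig) -> np.ndarray:
    """Unit-loading target-only (P300-like) component waveform."""
    return _bump(
        _template_len(cfg), cfg.sample_rate,
        cfg.erp_latency_ms, cfg.erp_sigma_ms, cfg.erp_amplitude,
    )


def visual_template(cfg: SimulationConfig) -> np.ndarray:
    """Unit-loading class-shared early visual component (negative peak)."""
    return _bump(
        _template_len(cfg), cfg.sample_rate,
        cfg.visual_latency_ms, cfg.visual_sigma_ms, -cfg.visual_amplitude,
    )


def _base_loadings(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Session-1 loading vectors (visual, erp) over the full layout."""
    visual = np.zeros(len(cfg.channel_names))
    erp = np.zeros(len(cfg.channel_names))
    informative = set(cfg.informative_sensors)
    for i, name in enumerate(cfg.channel_names):
        if name.startswith(("O", "PO")):
            visual[i] = 1.0
        elif name.startswith("P"):
            visual[i] = 0.5
        if name in informative:
            erp[i] = 1.0
    return visual, erp


def session_loadings(
    cfg: SimulationConfig, subject: int, session: int
) -> tuple[np.ndarray, np.ndarray]:
    """Loading vectors for a subject/session.

    Session 0 uses the configured base loadings; each later session adds an
    independent Gaussian perturbation (sd ``session_perturbation_sd``) to the
    previous session's vectors, modelling day-to-day changes in electrode
    position and impedance.
    """
    visual, erp = _base_loadings(cfg)
    for s in range(1, session + 1):
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 7, subject, s])
        )
        visual = visual + rng.normal(0, cfg.session_perturbation_sd, visual.shape)
        erp = erp + rng.normal(0, cfg.session_perturbation_sd, erp.shape)
    return visual, erp


def expected_target_response(
    cfg: SimulationConfig, channel: str, subject: int = 0, session: int = 0
) -> np.ndarray:
    """Noise-free response of one channel to a single target stimulus."""
    visual_w, erp_w = session_loadings(cfg, subject, session)
    i = list(cfg.channel_names).index(channel)
    return visual_w[i] * visual_template(cfg) + erp_w[i] * erp_template(cfg)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Unit-variance 1/f-spectrum noise per channel via FFT shaping."""
    n_ch, n = shape
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = scale[1] if len(scale) > 1 else 1.0
    pink = np.fft.irfft(spec * scale, n=n, axis=1)
    sd = pink.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def _simulate_run(
    cfg: SimulationConfig, subject: int, session: int, run: int,
    visual_w: np.ndarray, erp_w: np.ndarray,
) -> ContinuousRun:
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 11, subject, session, run])
    )
    fs = cfg.sample_rate
    n_events = cfg.n_standards_per_run + cfg.n_targets_per_run
    labels = np.array(
        [STANDARD] * cfg.n_standards_per_run + [TARGET] * cfg.n_targets_per_run,
        dtype=object,
    )
    rng.shuffle(labels)

    isi_samples = cfg.isi_ms * fs / 1000.0
    jitter = cfg.isi_jitter_ms * fs / 1000.0
    increments = isi_samples + rng.uniform(-jitter, jitter, n_events)
    onsets = np.round(isi_samples + np.concatenate(
        ([0.0], np.cumsum(increments[:-1]))
    )).astype(int)
    n_samples = int(onsets[-1] + 2 * round(isi_samples))

    n_ch = len(cfg.channel_names)
    if cfg.noise_sd > 0:
        if cfg.noise_mode == "white":
            signal = rng.normal(0.0, cfg.noise_sd, (n_ch, n_samples))
        else:
            signal = cfg.noise_sd * _pink_noise(rng, (n_ch, n_samples))
    else:
        signal = np.zeros((n_ch, n_samples))

    vis = visual_template(cfg)
    erp = erp_template(cfg)
    L = len(vis)
    for onset, lab in zip(onsets, labels):
        stop = min(onset + L, n_samples)
        seg = slice(onset, stop)
        k = stop - onset
        signal[:, seg] += np.outer(visual_w, vis[:k])
        if lab == TARGET:
            signal[:, seg] += np.outer(erp_w, erp[:k])

    return ContinuousRun(
        signal=signal,
        sample_rate=fs,
        channel_names=list(cfg.channel_names),
        events=[(int(o), str(l)) for o, l in zip(onsets, labels)],
        run_id=f"run{run}",
        session_id=f"session{session}",
        subject_id=f"subject{subject}",
    )


def simulate_session(
    cfg: SimulationConfig, subject: int = 0, session: int = 0
) -> list[ContinuousRun]:
    """Simulate all runs of one recording session of one subject.

    Deterministic given ``cfg.seed`` and the subject/session indices; runs,
    sessions and subjects use independent random streams, so any session can
    be generated without generating the others.
    """
    if not 0 <= subject < cfg.n_subjects:
        raise ValueError(f"subject index {subject} outside 0..{cfg.n_subjects - 1}")
    if not 0 <= session < cfg.n_sessions:
        raise ValueError(f"session index {session} outside 0..{cfg.n_sessions - 1}")
    visual_w, erp_w = session_loadings(cfg, subject, session)
    return [
        _simulate_run(cfg, subject, session, r, visual_w, erp_w)
        for r in range(cfg.n_runs)
    ]


def simulate_dataset(cfg: SimulationConfig) -> dict[tuple[int, int], list[ContinuousRun]]:
    """All sessions of all subjects, keyed by (subject, session) index."""
    return {
        (subj, sess): simulate_session(cfg, subj, sess)
        for subj in range(cfg.n_subjects)
        for sess in range(cfg.n_sessions)
    }
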