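"""Synthetic EEG/EMG recordings with a known ground-truth hypnogram.

The generator emulates the signal structure the decision tree relies
on: a delta-dominant EEG with low muscle tone in NREMS, a
theta-dominant EEG with muscle atonia in REMS, a mixed EEG with high
muscle tone in WAKE, an EMG band-limited to 40-90 Hz, and optional
spike artifacts. State bouts follow a semi-Markov chain with
exponential dwell times.

EEG per epoch is a sum of random-frequency, random-phase sinusoids —
one mixture per band, with per-state RMS weights — plus white noise.
This gives transparent control over band power (feature-level
assertions are exact) at the cost of physiological realism (no
spindles, K-complexes or 1/f background).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .core import (
    EMG_BAND,
    DEFAULT_BANDS,
    SCORING_BAND_NAMES,
    Channel,
    ScoringConfig,
    ScoringThresholds,
    SignalVector,
    State,
)
from .spectral_features import compute_features

__all__ = [
    "SynthParams",
    "Hypnogram",
    "SyntheticRecording",
    "simulate_hypnogram",
    "simulate_signals",
    "simulate_recording",
    "oracle_thresholds",
    "write_recording",
]

_SLEEP_STATES = (State.WAKE, State.NREMS, State.REMS)


@dataclass(frozen=True)
class SynthParams:
    """Generator settings.

    Band weights are target RMS amplitudes (arbitrary units) of the
    per-band sinusoid mixtures, ordered (delta, theta, alpha, mu,
    beta). EMG amplitudes are target RMS values of the 40-90 Hz
    band-limited muscle signal and must respect the atonia ordering
    WAKE > NREMS > REMS.
    """

    fs: float = 250.0
    duration_s: float = 3600.0
    epoch_length_s: float = 4.0
    dwell_means_s: dict[State, float] = field(
        default_factory=lambda: {
            State.WAKE: 60.0,
            State.NREMS: 120.0,
            State.REMS: 30.0,
        }
    )
    band_weights: dict[State, tuple[float, ...]] = field(
        default_factory=lambda: {
            State.WAKE: (10.0, 12.0, 8.0, 6.0, 6.0),
            State.NREMS: (40.0, 8.0, 6.0, 4.0, 3.0),
            State.REMS: (6.0, 30.0, 5.0, 3.0, 2.0),
        }
    )
    emg_amplitudes: dict[State, float] = field(
        default_factory=lambda: {
            State.WAKE: 3.0,
            State.NREMS: 1.0,
            State.REMS: 0.3,
        }
    )
    noise_amplitude: float = 3.0
    spike_rate_per_min: float = 0.0
    spike_amplitude: float = 500.0
    sinusoids_per_band: int = 3
    forbid_wake_to_rems: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for s in _SLEEP_STATES:
            if self.dwell_means_s[s] <= 0:
                raise ValueError(f"dwell mean for {s.name} must be positive")
        emg = self.emg_amplitudes
        if not emg[State.WAKE] > emg[State.NREMS] > emg[State.REMS]:
            raise ValueError(
                "EMG amplitudes must respect atonia ordering WAKE > NREMS > REMS"
            )
        w = self.band_weights
        if int(np.argmax(w[State.NREMS])) != 0:
            raise ValueError("NREMS band weights must be delta-dominant")
        if int(np.argmax(w[State.REMS])) != 1:
            raise ValueError("REMS band weights must be theta-dominant")


@dataclass(frozen=True)
class Hypnogram:
    """Ground-truth per-epoch state sequence."""

    states: np.ndarray  # int codes, one per epoch
    epoch_length_s: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "states", np.asarray(self.states, dtype=np.int64)
        )

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)


@dataclass(frozen=True)
class SyntheticRecording:
    """A generated recording bundled with its ground truth."""

    eeg: SignalVector
    emg: SignalVector
    hypnogram: Hypnogram
    spike_indices: np.ndarray  # sample indices of injected spikes
    params: SynthParams


def _next_state(rng: np.random.Generator, current: State, p: SynthParams) -> State:
    choices = [s for s in _SLEEP_STATES if s is not current]
    if p.forbid_wake_to_rems and current is State.WAKE:
        choices = [s for s in choices if s is not State.REMS]
    return choices[rng.integers(len(choices))] if len(choices) > 1 else choices[0]


def simulate_hypnogram(p: SynthParams) -> Hypnogram:
    """Semi-Markov state sequence with exponential dwell times.

    Each bout's duration is drawn from an exponential at the state's
    mean dwell and discretized to whole epochs (minimum one). With
    ``forbid_wake_to_rems`` the chain never enters REMS directly from
    WAKE, the default biological constraint in healthy rodents.
    """
    rng = np.random.default_rng(p.seed)
    n_epochs = int(p.duration_s // p.epoch_length_s)
    states: list[int] = []
    current = State.WAKE
    while len(states) < n_epochs:
        dwell = rng.exponential(p.dwell_means_s[current])
        bout = max(1, int(round(dwell / p.epoch_length_s)))
        states.extend([current.value] * bout)
        current = _next_state(rng, current, p)
    return Hypnogram(np.array(states[:n_epochs]), p.epoch_length_s)


def _band_mixture(
    rng: np.random.Generator,
    t: np.ndarray,
    low: float,
    high: float,
    target_rms: float,
    n_sin: int,
) -> np.ndarray:
    """Sum of sinusoids at random frequencies in the band's interior
    (central 80%, avoiding filter roll-off at the edges), scaled to the
    target RMS."""
    span = high - low
    freqs = rng.uniform(low + 0.1 * span, high - 0.1 * span, size=n_sin)
    phases = rng.uniform(0, 2 * np.pi, size=n_sin)
    x = np.sum(
        np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]),
        axis=0,
    )
    # n_sin incoherent unit sinusoids have RMS sqrt(n_sin/2)
    return x * (target_rms / np.sqrt(n_sin / 2.0))


def simulate_signals(
    h: Hypnogram, p: SynthParams
) -> tuple[SignalVector, SignalVector, np.ndarray]:
    """Synthesize EEG and EMG for a hypnogram.

    Returns (eeg, emg, spike_sample_indices). Spikes are injected into
    the EEG at a Poisson rate of ``spike_rate_per_min`` with amplitude
    ``spike_amplitude`` (alternating sign), and their sample indices
    are returned so tests can verify mask coverage.
    """
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 1]))
    n_per_epoch = int(round(p.epoch_length_s * p.fs))
    n_total = h.n_epochs * n_per_epoch
    t_epoch = np.arange(n_per_epoch) / p.fs

    eeg = np.empty(n_total)
    emg = np.empty(n_total)

    # 40-90 Hz band-limited noise for the EMG, normalized to unit RMS
    sos = sps.butter(
        4, [EMG_BAND.low, EMG_BAND.high], btype="bandpass", fs=p.fs, output="sos"
    )
    raw_noise = rng.standard_normal(n_total)
    emg_carrier = sps.sosfiltfilt(sos, raw_noise)
    emg_carrier /= np.sqrt(np.mean(emg_carrier**2))

    for i in range(h.n_epochs):
        state = State(int(h.states[i]))
        sl = slice(i * n_per_epoch, (i + 1) * n_per_epoch)
        x = np.zeros(n_per_epoch)
        for weight, name in zip(p.band_weights[state], SCORING_BAND_NAMES):
            band = DEFAULT_BANDS[name]
            x += _band_mixture(
                rng, t_epoch, band.low, band.high, weight, p.sinusoids_per_band
            )
        x += p.noise_amplitude * rng.standard_normal(n_per_epoch)
        eeg[sl] = x
        emg[sl] = p.emg_amplitudes[state] * emg_carrier[sl]

    n_spikes = rng.poisson(p.spike_rate_per_min * (n_total / p.fs) / 60.0)
    spike_idx = np.sort(rng.choice(n_total, size=n_spikes, replace=False))
    for k, idx in enumerate(spike_idx):
        eeg[idx] = p.spike_amplitude * (1 if k % 2 == 0 else -1)

    return (
        SignalVector(eeg, p.fs, Channel.EEG),
        SignalVector(emg, p.fs, Channel.EMG),
        spike_idx,
    )


def simulate_recording(p: SynthParams) -> SyntheticRecording:
    """Generate hypnogram and signals in one call."""
    h = simulate_hypnogram(p)
    eeg, emg, spikes = simulate_signals(h, p)
    return SyntheticRecording(eeg, emg, h, spikes, p)


def oracle_thresholds(
    eeg: SignalVector,
    emg: SignalVector,
    h: Hypnogram,
    cfg: ScoringConfig,
) -> ScoringThresholds:
    """Threshold placement a competent scorer would choose, derived
    from the ground truth.

    Each cursor is the geometric mean of the medians of the two
    per-state feature distributions it must separate: exp(EMG_RMS) for
    WAKE vs sleep, DELTA and THETA for NREMS vs REMS. Warns when the
    medians do not separate (degenerate generator settings).
    """
    features = compute_features(eeg, emg, cfg)
    n = min(features.n_epochs, h.n_epochs)
    states = h.states[:n]
    ok = ~features.is_artifact[:n]

    def med(values: np.ndarray, member: np.ndarray) -> float:
        sel = values[:n][ok & member]
        if sel.size == 0:
            raise ValueError("a state is absent from the hypnogram")
        return float(np.median(sel))

    wake = states == State.WAKE.value
    nrems = states == State.NREMS.value
    rems = states == State.REMS.value

    emg_hi = med(features.emg_rms, wake)
    emg_lo = med(features.emg_rms, nrems | rems)
    delta_hi = med(features.delta, nrems)
    delta_lo = med(features.delta, rems)
    theta_hi = med(features.theta, rems)
    theta_lo = med(features.theta, nrems)

    for name, hi, lo in (
        ("EMG", emg_hi, emg_lo),
        ("DELTA", delta_hi, delta_lo),
        ("THETA", theta_hi, theta_lo),
    ):
        if hi <= lo:
            warnings.warn(
                f"{name} state medians do not separate ({hi:.3g} <= {lo:.3g}); "
                "threshold placement is degenerate",
                stacklevel=2,
            )

    # geometric mean of exp(m) values == exp(arithmetic mean of RMS medians)
    return ScoringThresholds(
        emg_thr=float(np.exp(0.5 * (emg_hi + emg_lo))),
        delta_thr=float(np.sqrt(delta_hi * delta_lo)),
        theta_thr=float(np.sqrt(theta_hi * theta_lo)),
    )


def write_recording(
    rec: SyntheticRecording, out_prefix: str | Path
) -> dict[str, str]:
    """Write EEG/EMG vectors, the ground-truth hypnogram and a JSON
    metadata sidecar (including the seed) next to ``out_prefix``."""
    from .signal_io import write_signal_vector

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "eeg": str(
            write_signal_vector(rec.eeg, prefix.name + "_eeg", out_dir=prefix.parent)
        ),
        "emg": str(
            write_signal_vector(rec.emg, prefix.name + "_emg", out_dir=prefix.parent)
        ),
    }
    hyp_path = prefix.parent / f"{prefix.name}_hypnogram.txt"
    np.savetxt(hyp_path, rec.hypnogram.states, fmt="%d")
    paths["hypnogram"] = str(hyp_path)

    meta_path = prefix.parent / f"{prefix.name}_meta.json"
    meta = {
        "seed": rec.params.seed,
        "fs": rec.params.fs,
        "duration_s": rec.params.duration_s,
        "epoch_length_s": rec.params.epoch_length_s,
        "n_epochs": rec.hypnogram.n_epochs,
        "spike_sample_indices": [int(i) for i in rec.spike_indices],
        "state_codes": {s.name: s.value for s in State},
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    paths["meta"] = str(meta_path)
    return paths
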