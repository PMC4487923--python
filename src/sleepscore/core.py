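"""Shared domain types for the sleep-scoring pipeline.

The pipeline moves uniformly sampled EEG/EMG vectors through artifact
masking, per-epoch band-RMS feature extraction and a threshold decision
tree, ending in a four-column scored matrix (state, DELTA, THETA,
EMG_RMS) per epoch.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np


class Channel(enum.Enum):
    EEG = "EEG"
    EMG = "EMG"


class State(enum.IntEnum):
    """Vigilance-state codes used in exported matrices.

    ARTIFACT rows are retained (code 0) so epoch indices stay aligned
    with recording time; downstream analyses drop them by filtering.
    """

    ARTIFACT = 0
    WAKE = 1
    NREMS = 2
    REMS = 3

    @classmethod
    def parse(cls, token: str | int) -> "State":
        """Accept integer codes or (case-insensitive) state names.

        'AWAKE' is accepted as a synonym for WAKE.
        """
        if isinstance(token, (int, np.integer)):
            return cls(int(token))
        t = str(token).strip().upper()
        if t.isdigit() or (t.startswith("-") and t[1:].isdigit()):
            return cls(int(t))
        if t == "AWAKE":
            return cls.WAKE
        try:
            return cls[t]
        except KeyError:
            raise ValueError(f"unknown state {token!r}") from None


@dataclass(frozen=True)
class SignalVector:
    """A uniformly sampled raw channel (EEG or EMG).

    Amplitudes are in arbitrary amplifier-output units. NaN values are
    permitted only as artifact labels introduced by masking, never on
    raw ingest.
    """

    samples: np.ndarray
    fs: float
    channel: Channel = Channel.EEG

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray) -> "SignalVector":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class ArtifactMask:
    """Per-sample boolean artifact flags (True = excluded sample)."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "flags", np.asarray(self.flags, dtype=bool))

    def __len__(self) -> int:
        return int(self.flags.size)

    @property
    def n_masked(self) -> int:
        return int(self.flags.sum())

    def __or__(self, other: "ArtifactMask") -> "ArtifactMask":
        if len(self) != len(other):
            raise ValueError(
                f"mask lengths differ: {len(self)} vs {len(other)}"
            )
        return ArtifactMask(self.flags | other.flags)


@dataclass(frozen=True)
class AmplitudeThresholds:
    """Upper/lower amplitude cursors for spike-artifact detection."""

    max_thr: float
    min_thr: float

    def __post_init__(self) -> None:
        if not self.min_thr < self.max_thr:
            raise ValueError(
                f"min_thr must be below max_thr, got "
                f"[{self.min_thr}, {self.max_thr}]"
            )


@dataclass(frozen=True)
class BandDefinition:
    """A named EEG frequency band (Hz)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges {self.low}-{self.high} Hz")

    def validate_for(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.name} high edge {self.high} Hz >= Nyquist "
                f"({fs / 2} Hz)"
            )


#: The five scoring bands plus the display broadband.
DEFAULT_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 0.5, 5.0),
    "theta": BandDefinition("theta", 6.0, 9.0),
    "alpha": BandDefinition("alpha", 10.0, 15.0),
    "mu": BandDefinition("mu", 16.0, 22.75),
    "beta": BandDefinition("beta", 23.0, 31.75),
    "broadband": BandDefinition("broadband", 0.5, 31.75),
}

SCORING_BAND_NAMES = ("delta", "theta", "alpha", "mu", "beta")

#: EMG hardware acquisition band; optional software filter for raw inputs.
EMG_BAND = BandDefinition("emg", 40.0, 90.0)


@dataclass(frozen=True)
class ScoringConfig:
    """Global processing parameters shared by the whole pipeline."""

    fs: float = 250.0
    filter_order: int = 3
    broadband_low: float = 0.5
    broadband_high: float = 31.75
    epoch_length_s: float = 4.0
    file_tag: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if not 0 < self.broadband_low < self.broadband_high < self.fs / 2:
            raise ValueError("broadband edges must satisfy 0 < low < high < fs/2")
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_length_s * self.fs))


@dataclass(frozen=True)
class ScoringThresholds:
    """The three user cursors driving the decision tree.

    ``emg_thr`` is on the exp(EMG_RMS) scale, matching the "EMG
    activity" display; comparisons are performed in log space.
    """

    emg_thr: float
    delta_thr: float
    theta_thr: float

    def __post_init__(self) -> None:
        for name in ("emg_thr", "delta_thr", "theta_thr"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")

    @classmethod
    def from_log_emg(
        cls, log_emg_thr: float, delta_thr: float, theta_thr: float
    ) -> "ScoringThresholds":
        """Build thresholds with the EMG cursor given as ln(threshold)."""
        return cls(float(np.exp(log_emg_thr)), delta_thr, theta_thr)


@dataclass
class EpochFeatureTable:
    """Per-epoch band RMS values and derived scoring features.

    Epochs flagged ``is_artifact`` carry NaN in every feature column;
    non-artifact epochs have finite, strictly positive DELTA, THETA and
    EMG feature values.
    """

    delta_rms: np.ndarray
    theta_rms: np.ndarray
    alpha_rms: np.ndarray
    mu_rms: np.ndarray
    beta_rms: np.ndarray
    emg_rms: np.ndarray
    delta: np.ndarray
    theta: np.ndarray
    emg_feature: np.ndarray
    is_artifact: np.ndarray
    epoch_length_s: float

    @property
    def n_epochs(self) -> int:
        return int(self.delta.size)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "delta_rms": self.delta_rms,
                "theta_rms": self.theta_rms,
                "alpha_rms": self.alpha_rms,
                "mu_rms": self.mu_rms,
                "beta_rms": self.beta_rms,
                "emg_rms": self.emg_rms,
                "DELTA": self.delta,
                "THETA": self.theta,
                "emg_feature": self.emg_feature,
                "is_artifact": self.is_artifact,
            }
        )


@dataclass(frozen=True)
class ScoredMatrix:
    """The four-column scored output: state, DELTA, THETA, EMG_RMS.

    One row per epoch; ARTIFACT rows carry NaN in all feature columns.
    """

    states: np.ndarray  # int codes per State
    delta: np.ndarray
    theta: np.ndarray
    emg_rms: np.ndarray
    epoch_length_s: float = 4.0

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int64)
        object.__setattr__(self, "states", states)
        for name in ("delta", "theta", "emg_rms"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            object.__setattr__(self, name, arr)
            if arr.size != states.size:
                raise ValueError(f"{name} length {arr.size} != {states.size}")
        if not np.isin(states, [s.value for s in State]).all():
            raise ValueError("unknown state code in matrix")

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)

    def state_counts(self) -> dict[State, int]:
        return {s: int((self.states == s.value).sum()) for s in State}

    def with_states(self, states: np.ndarray) -> "ScoredMatrix":
        return replace(self, states=np.asarray(states, dtype=np.int64))
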