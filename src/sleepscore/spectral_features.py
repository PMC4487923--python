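"""Band-pass filtering, per-epoch RMS, and the scoring features.

The EEG is filtered into five bands (delta 0.5-5, theta 6-9, alpha
10-15, mu 16-22.75, beta 23-31.75 Hz) with a zero-phase Butterworth
band-pass of the configured design order (default 3). Per non-
overlapping epoch of the configured block length, the RMS

    RMS = sqrt( (1/N) * sum_i x_i^2 )

is computed for each filtered band and for the EMG, and combined into
the two ratio features separating NREMS from REMS:

    DELTA = delta_RMS / (alpha_RMS * mu_RMS * beta_RMS)
    THETA = theta_RMS**2 / (delta_RMS * alpha_RMS)

plus the muscle-tone feature exp(EMG_RMS). Epochs containing any NaN
(artifact) sample, or any exactly-zero band RMS, are flagged as
artifact epochs with NaN features.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .core import (
    BandDefinition,
    Channel,
    DEFAULT_BANDS,
    EMG_BAND,
    EpochFeatureTable,
    SCORING_BAND_NAMES,
    ScoringConfig,
    SignalVector,
)

__all__ = [
    "bandpass",
    "epoch_rms",
    "compute_features",
    "delta_feature",
    "theta_feature",
]


def _butter_sos(band: BandDefinition, fs: float, order: int) -> np.ndarray:
    return sps.butter(
        order, [band.low, band.high], btype="bandpass", fs=fs, output="sos"
    )


def _finite_runs(x: np.ndarray):
    """Yield (start, stop) of maximal contiguous finite runs."""
    finite = np.isfinite(x)
    if not finite.any():
        return
    edges = np.flatnonzero(np.diff(finite.astype(np.int8)))
    starts = [0] if finite[0] else []
    starts += [int(e) + 1 for e in edges if not finite[e]]
    stops = [int(e) + 1 for e in edges if finite[e]]
    if finite[-1]:
        stops.append(len(x))
    yield from zip(starts, stops)


def bandpass(
    sig: SignalVector, band: BandDefinition, order: int = 3
) -> SignalVector:
    """Zero-phase (forward-backward) Butterworth band-pass.

    The stated ``order`` is the design order of the underlying filter;
    forward-backward application doubles the effective magnitude order
    and cancels phase lag, keeping the five band outputs time-aligned
    within each epoch. NaN (artifact) regions propagate as NaN and the
    filter restarts on each contiguous finite run, so artifacts never
    bleed into neighbouring clean data.
    """
    band.validate_for(sig.fs)
    sos = _butter_sos(band, sig.fs, order)
    x = sig.samples
    out = np.full_like(x, np.nan)
    default_padlen = 3 * (2 * sos.shape[0] + 1)
    for start, stop in _finite_runs(x):
        run = x[start:stop]
        padlen = min(default_padlen, len(run) - 1)
        out[start:stop] = sps.sosfiltfilt(sos, run, padlen=padlen)
    return sig.with_samples(out)


def epoch_rms(sig: SignalVector, epoch_length_s: float) -> np.ndarray:
    """Per-epoch RMS over strictly non-overlapping blocks.

    One value per complete epoch of N = epoch_length_s * fs samples; a
    trailing partial epoch is dropped. Any NaN sample inside an epoch
    makes that epoch's RMS NaN.
    """
    n = int(round(epoch_length_s * sig.fs))
    if n < 1:
        raise ValueError("epoch_length_s * fs must be >= 1")
    n_epochs = len(sig) // n
    if n_epochs == 0:
        warnings.warn(
            f"signal ({len(sig)} samples) shorter than one epoch ({n})",
            stacklevel=2,
        )
        return np.empty(0, dtype=np.float64)
    blocks = sig.samples[: n_epochs * n].reshape(n_epochs, n)
    return np.sqrt(np.mean(np.abs(blocks) ** 2, axis=1))


def delta_feature(
    delta_rms: np.ndarray,
    alpha_rms: np.ndarray,
    mu_rms: np.ndarray,
    beta_rms: np.ndarray,
) -> np.ndarray:
    """DELTA = delta_RMS / (alpha_RMS * mu_RMS * beta_RMS).

    Large during NREMS (delta-rich, desynchronized bands quiet); scales
    as 1/k^2 under a global EEG gain k.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        return delta_rms / (alpha_rms * mu_rms * beta_rms)


def theta_feature(
    theta_rms: np.ndarray, delta_rms: np.ndarray, alpha_rms: np.ndarray
) -> np.ndarray:
    """THETA = theta_RMS^2 / (delta_RMS * alpha_RMS).

    Large during REMS (theta-dominant); invariant under a global EEG
    gain (degree 2 over degree 2), which makes it robust to electrode
    impedance differences between animals.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        return theta_rms**2 / (delta_rms * alpha_rms)


def compute_features(
    eeg: SignalVector,
    emg: SignalVector,
    cfg: ScoringConfig,
    emg_is_epoch_rms: bool = False,
    filter_emg: bool = False,
) -> EpochFeatureTable:
    """Full per-epoch feature table from artifact-masked EEG and EMG.

    ``emg`` is either the raw (already 40-90 Hz hardware-filtered) EMG
    signal, or — with ``emg_is_epoch_rms=True`` — a pre-computed
    per-epoch RMS vector with one value per epoch. ``filter_emg``
    applies a software 40-90 Hz band-pass for EMG recorded without the
    hardware filter.

    Epochs with any NaN band value, or with any exactly-zero band RMS
    (degenerate silent data that would zero a numerator or denominator),
    are flagged ``is_artifact`` with NaN features; ratio evaluation
    never raises on division.
    """
    if eeg.channel is not Channel.EEG:
        warnings.warn("first argument is not tagged as an EEG channel", stacklevel=2)

    band_rms: dict[str, np.ndarray] = {}
    for name in SCORING_BAND_NAMES:
        filtered = bandpass(eeg, DEFAULT_BANDS[name], cfg.filter_order)
        band_rms[name] = epoch_rms(filtered, cfg.epoch_length_s)
    n_epochs = band_rms["delta"].size

    if emg_is_epoch_rms:
        emg_rms = np.asarray(emg.samples, dtype=np.float64)
        if emg_rms.size < n_epochs:
            raise ValueError(
                f"pre-computed EMG RMS vector has {emg_rms.size} epochs, "
                f"EEG yields {n_epochs}"
            )
        emg_rms = emg_rms[:n_epochs]
    else:
        if abs(emg.duration_s - eeg.duration_s) > cfg.epoch_length_s:
            raise ValueError(
                "EEG and EMG durations differ by more than one epoch: "
                f"{eeg.duration_s:.1f} s vs {emg.duration_s:.1f} s"
            )
        emg_sig = bandpass(emg, EMG_BAND, cfg.filter_order) if filter_emg else emg
        emg_rms = epoch_rms(emg_sig, cfg.epoch_length_s)[:n_epochs]
        if emg_rms.size < n_epochs:
            raise ValueError("EMG yields fewer complete epochs than EEG")

    stacked = np.vstack([band_rms[n] for n in SCORING_BAND_NAMES] + [emg_rms])
    nan_epochs = np.isnan(stacked).any(axis=0)
    # zero EEG band RMS would zero a ratio numerator or denominator;
    # zero EMG RMS is harmless (exp(0) = 1)
    eeg_bands = stacked[: len(SCORING_BAND_NAMES)]
    with np.errstate(invalid="ignore"):
        zero_epochs = (eeg_bands == 0).any(axis=0)
    is_artifact = nan_epochs | zero_epochs
    if zero_epochs.any():
        warnings.warn(
            f"{int(zero_epochs.sum())} epoch(s) with zero band RMS flagged "
            "as artifact (degenerate ratio denominator)",
            stacklevel=2,
        )

    delta = delta_feature(
        band_rms["delta"], band_rms["alpha"], band_rms["mu"], band_rms["beta"]
    )
    theta = theta_feature(band_rms["theta"], band_rms["delta"], band_rms["alpha"])
    emg_feature = np.exp(emg_rms)

    for arr in (delta, theta, emg_feature):
        arr[is_artifact] = np.nan
    emg_rms = emg_rms.copy()
    emg_rms[is_artifact] = np.nan

    return EpochFeatureTable(
        delta_rms=band_rms["delta"],
        theta_rms=band_rms["theta"],
        alpha_rms=band_rms["alpha"],
        mu_rms=band_rms["mu"],
        beta_rms=band_rms["beta"],
        emg_rms=emg_rms,
        delta=delta,
        theta=theta,
        emg_feature=emg_feature,
        is_artifact=is_artifact,
        epoch_length_s=cfg.epoch_length_s,
    )
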