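"""The two-stage threshold decision tree assigning vigilance states.

Decision 1 (muscle tone): epochs whose exp(EMG_RMS) lies strictly above
the user's EMG threshold are WAKE. Decision 2 (EEG ratios), applied to
the remaining epochs: DELTA strictly below its threshold AND THETA
strictly above its threshold means REMS; everything else is NREMS.
Artifact epochs keep the ARTIFACT code and are excluded from analysis
by downstream consumers.

Equality at any cursor falls through to the default branch (non-WAKE
for the EMG cursor, NREMS for the DELTA/THETA cursors). The EMG
comparison runs in log space (EMG_RMS vs ln(threshold)), which is
identical by monotonicity and immune to exp overflow.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .artifact_detection import apply_mask
from .core import (
    ArtifactMask,
    Channel,
    EpochFeatureTable,
    ScoredMatrix,
    ScoringConfig,
    ScoringThresholds,
    State,
)
from .signal_io import read_signal_vector, write_scored_matrix
from .spectral_features import compute_features

__all__ = ["score_epochs", "score_recording"]

logger = logging.getLogger(__name__)


def score_epochs(
    features: EpochFeatureTable, thr: ScoringThresholds
) -> ScoredMatrix:
    """Assign exactly one state per epoch from the feature table.

    Per epoch: artifact -> ARTIFACT; else exp(EMG_RMS) > emg_thr ->
    WAKE; else DELTA < delta_thr and THETA > theta_thr -> REMS; else
    NREMS. Feature columns (DELTA, THETA, EMG_RMS) are copied into the
    output matrix.
    """
    artifact = np.asarray(features.is_artifact, dtype=bool)
    log_emg_thr = np.log(thr.emg_thr)
    with np.errstate(invalid="ignore"):
        wake = ~artifact & (features.emg_rms > log_emg_thr)
        rems = (
            ~artifact
            & ~wake
            & (features.delta < thr.delta_thr)
            & (features.theta > thr.theta_thr)
        )
    states = np.full(features.n_epochs, State.NREMS.value, dtype=np.int64)
    states[wake] = State.WAKE.value
    states[rems] = State.REMS.value
    states[artifact] = State.ARTIFACT.value
    return ScoredMatrix(
        states=states,
        delta=features.delta,
        theta=features.theta,
        emg_rms=features.emg_rms,
        epoch_length_s=features.epoch_length_s,
    )


def score_recording(
    eeg_path: str | Path,
    emg_path: str | Path,
    cfg: ScoringConfig,
    thr: ScoringThresholds,
    artifact_path: str | Path | None = None,
    emg_is_epoch_rms: bool = False,
    out_dir: str | Path = ".",
    write_output: bool = True,
) -> tuple[ScoredMatrix, Path | None]:
    """Run the full scoring pipeline on text-vector inputs.

    Reads the EEG (and raw or per-epoch-RMS EMG) vectors, applies the
    artifact vector if given (its NaN samples define the mask, applied
    to both channels), computes the feature table, scores every epoch
    and writes the ``_autoscored`` matrix.
    """
    eeg = read_signal_vector(eeg_path, cfg.fs, Channel.EEG)
    emg = read_signal_vector(emg_path, cfg.fs, Channel.EMG)

    if artifact_path is not None:
        labeled = read_signal_vector(
            artifact_path, cfg.fs, Channel.EEG, allow_nan=True
        )
        if len(labeled) != len(eeg):
            raise ValueError(
                f"artifact vector length {len(labeled)} != EEG length {len(eeg)}"
            )
        mask = ArtifactMask(np.isnan(labeled.samples))
        eeg = apply_mask(eeg, mask)
        if not emg_is_epoch_rms:
            if len(emg) != len(eeg):
                raise ValueError(
                    f"EMG length {len(emg)} != EEG length {len(eeg)}"
                )
            emg = apply_mask(emg, mask)

    features = compute_features(eeg, emg, cfg, emg_is_epoch_rms=emg_is_epoch_rms)
    matrix = score_epochs(features, thr)

    counts = matrix.state_counts()
    logger.info(
        "scored %d epochs: WAKE=%d NREMS=%d REMS=%d ARTIFACT=%d",
        matrix.n_epochs,
        counts[State.WAKE],
        counts[State.NREMS],
        counts[State.REMS],
        counts[State.ARTIFACT],
    )

    out_path = None
    if write_output:
        out_path = write_scored_matrix(
            matrix, Path(eeg_path).stem, cfg.file_tag, "_autoscored", out_dir
        )
    return matrix, out_path
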