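"""Plain-text I/O for signal vectors and scored matrices.

Canonical interchange formats:

* signal / artifact vectors — one numeric value per line; artifact
  samples serialized as the literal ``NaN`` (case-insensitive on read);
* scored matrices — four tab-separated columns per epoch in the order
  state code, DELTA, THETA, EMG_RMS, with states encoded as
  WAKE=1, NREMS=2, REMS=3, ARTIFACT=0.

Output files are named ``<stem><file-tag><annex>.txt`` where the annex
identifies the product (``_artifact``, ``_rms``, ``_autoscored``,
``_rescored``).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .core import ArtifactMask, Channel, ScoredMatrix, SignalVector, State

__all__ = [
    "annex_path",
    "read_signal_vector",
    "write_signal_vector",
    "write_artifact_vector",
    "read_scored_matrix",
    "write_scored_matrix",
    "read_edf_signal",
]

_FLOAT_FMT = "%.12g"


def annex_path(
    stem: str, tag: str, annex: str, out_dir: str | Path = "."
) -> Path:
    """Build ``<out_dir>/<stem><tag><annex>.txt``."""
    return Path(out_dir) / f"{stem}{tag}{annex}.txt"


def _parse_line(token: str, path: Path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"{path}: unparsable value {token!r} on line {lineno}"
        ) from None


def read_signal_vector(
    path: str | Path,
    fs: float,
    channel: Channel = Channel.EEG,
    allow_nan: bool = False,
) -> SignalVector:
    """Read a one-value-per-line text vector.

    Raw recordings must be fully finite (``allow_nan=False``, the
    default); artifact-labeled vectors are read with ``allow_nan=True``.
    Blank lines are ignored. A malformed line raises ``ValueError``
    naming the line number.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            token = raw.strip()
            if not token:
                continue
            v = _parse_line(token, path, lineno)
            if math.isnan(v) and not allow_nan:
                raise ValueError(
                    f"{path}: NaN on line {lineno} in a raw signal vector "
                    "(artifact vectors must be read with allow_nan=True)"
                )
            values.append(v)
    if not values:
        raise ValueError(f"{path}: empty signal file")
    return SignalVector(np.array(values, dtype=np.float64), fs=fs, channel=channel)


def write_signal_vector(
    sig: SignalVector,
    stem: str,
    tag: str = "",
    annex: str = "",
    out_dir: str | Path = ".",
) -> Path:
    """Write a signal as one value per line; NaN as the literal ``NaN``."""
    path = annex_path(stem, tag, annex, out_dir)
    with open(path, "w") as fh:
        for v in sig.samples:
            fh.write("NaN\n" if math.isnan(v) else (_FLOAT_FMT % v) + "\n")
    return path


def write_artifact_vector(
    sig: SignalVector,
    mask: ArtifactMask,
    stem: str,
    tag: str = "",
    out_dir: str | Path = ".",
) -> Path:
    """Write the artifact-labeled vector (``_artifact`` annex).

    Masked samples are serialized as ``NaN``; all other samples are
    written unchanged, one per line, preserving order.
    """
    if len(mask) != len(sig):
        raise ValueError(
            f"mask length {len(mask)} != signal length {len(sig)}"
        )
    labeled = sig.samples.copy()
    labeled[mask.flags] = np.nan
    return write_signal_vector(
        sig.with_samples(labeled), stem, tag, "_artifact", out_dir
    )


def write_scored_matrix(
    m: ScoredMatrix,
    stem: str,
    tag: str = "",
    annex: str = "_autoscored",
    out_dir: str | Path = ".",
    states_only: bool = False,
) -> Path:
    """Write a scored matrix as tab-separated text.

    Columns: state code, DELTA, THETA, EMG_RMS. ``states_only`` emits
    just the single state-code column (the minimal rescored vector).
    """
    if annex not in ("_autoscored", "_rescored"):
        raise ValueError(f"unknown matrix annex {annex!r}")
    path = annex_path(stem, tag, annex, out_dir)
    with open(path, "w") as fh:
        for i in range(m.n_epochs):
            if states_only:
                fh.write(f"{m.states[i]}\n")
                continue
            cells = [str(int(m.states[i]))]
            for col in (m.delta, m.theta, m.emg_rms):
                v = col[i]
                cells.append("NaN" if math.isnan(v) else _FLOAT_FMT % v)
            fh.write("\t".join(cells) + "\n")
    return path


def read_scored_matrix(
    path: str | Path, epoch_length_s: float = 4.0
) -> ScoredMatrix:
    """Read a tab-separated four-column scored matrix."""
    path = Path(path)
    states: list[int] = []
    feats: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != 4:
                raise ValueError(
                    f"{path}: expected 4 tab-separated columns on line "
                    f"{lineno}, got {len(cells)}"
                )
            try:
                state = State(int(cells[0]))
            except ValueError:
                raise ValueError(
                    f"{path}: bad state code {cells[0]!r} on line {lineno}"
                ) from None
            states.append(int(state))
            feats.append([_parse_line(c, path, lineno) for c in cells[1:]])
    if not states:
        raise ValueError(f"{path}: empty matrix file")
    arr = np.array(feats, dtype=np.float64)
    return ScoredMatrix(
        states=np.array(states, dtype=np.int64),
        delta=arr[:, 0],
        theta=arr[:, 1],
        emg_rms=arr[:, 2],
        epoch_length_s=epoch_length_s,
    )


def read_edf_signal(
    path: str | Path, channel_name: str, channel: Channel = Channel.EEG
) -> SignalVector:
    """Convenience EDF ingest (requires ``mne``); converts one channel
    to a plain :class:`SignalVector`. Text vectors remain canonical.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("EDF ingest requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), include=[channel_name], verbose="error")
    data = raw.get_data(picks=[channel_name])[0]
    return SignalVector(np.asarray(data, dtype=np.float64), fs=float(raw.info["sfreq"]), channel=channel)
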