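"""Amplitude-threshold (spike) and segment (long-term) artifact masking.

Artifact samples are flagged per sample and materialized as NaN by
:func:`apply_mask`; NaN samples are excluded from all downstream RMS
computations (their containing epoch becomes an ARTIFACT epoch).
"""

from __future__ import annotations

from functools import reduce

import numpy as np

from .core import AmplitudeThresholds, ArtifactMask, SignalVector

__all__ = ["mask_spikes", "mask_segment", "apply_mask", "combine_masks"]


def mask_spikes(sig: SignalVector, thr: AmplitudeThresholds) -> ArtifactMask:
    """Flag every sample strictly above ``max_thr`` or strictly below
    ``min_thr``.

    Samples exactly at a threshold are NOT artifacts. NaN samples
    (already-masked data) compare false to both inequalities, so
    pre-existing masks must be OR-combined with the result rather than
    re-derived from the labeled signal.
    """
    x = sig.samples
    with np.errstate(invalid="ignore"):
        flags = (x > thr.max_thr) | (x < thr.min_thr)
    return ArtifactMask(flags)


def mask_segment(
    sig: SignalVector, start_s: float, end_s: float
) -> ArtifactMask:
    """Flag the half-open sample window ``[start_s*fs, end_s*fs)``.

    Intervals are in seconds from recording start (0-based samples);
    disjoint segments compose by mask union.
    """
    if not 0 <= start_s < end_s:
        raise ValueError(
            f"segment must satisfy 0 <= start < end, got [{start_s}, {end_s}]"
        )
    if end_s > sig.duration_s:
        raise ValueError(
            f"segment end {end_s} s exceeds signal duration "
            f"{sig.duration_s} s"
        )
    i0 = int(np.floor(start_s * sig.fs))
    i1 = int(np.ceil(end_s * sig.fs))
    flags = np.zeros(len(sig), dtype=bool)
    flags[i0:i1] = True
    return ArtifactMask(flags)


def combine_masks(*masks: ArtifactMask) -> ArtifactMask:
    """Union of any number of equal-length masks."""
    if not masks:
        raise ValueError("at least one mask required")
    return reduce(lambda a, b: a | b, masks)


def apply_mask(sig: SignalVector, mask: ArtifactMask) -> SignalVector:
    """Replace masked samples with NaN; unmasked samples are unchanged."""
    if len(mask) != len(sig):
        raise ValueError(
            f"mask length {len(mask)} != signal length {len(sig)}"
        )
    out = sig.samples.copy()
    out[mask.flags] = np.nan
    return sig.with_samples(out)
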