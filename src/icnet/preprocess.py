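"""Signal conditioning: band-pass filtering, average reference, eye-state segmentation.

The pipeline applies these in a fixed order — filter, re-reference, segment —
before spectral estimation. Filtering is zero-phase (forward-backward
Butterworth), because any phase distortion would leak directly into the
imaginary part of the cross-spectrum that the whole analysis is built on.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .errors import InputError
from .recording import ScoutRecording

__all__ = ["bandpass", "average_reference", "segment_eye_state"]

logger = logging.getLogger(__name__)


def bandpass(
    rec: ScoutRecording, low: float = 0.5, high: float = 40.0, order: int = 4
) -> ScoutRecording:
    """Zero-phase Butterworth band-pass filter.

    Default 0.5-40 Hz corner frequencies. Applied forward and backward
    (``sosfiltfilt``), so the net group delay is zero and the effective
    attenuation is twice the single-pass value.
    """
    if not 0 < low < high:
        raise InputError(f"need 0 < low < high, got ({low}, {high})")
    if high >= rec.fs / 2:
        raise InputError(f"high corner {high} Hz >= Nyquist {rec.fs / 2} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=np.ascontiguousarray(filtered))


def average_reference(rec: ScoutRecording) -> ScoutRecording:
    """Subtract the instantaneous mean over scouts from every scout.

    Idempotent, and preserves all pairwise differences exactly.
    """
    if rec.n_scouts < 2:
        raise InputError("average reference needs at least 2 scouts")
    return rec.copy_with(data=rec.data - rec.data.mean(axis=0, keepdims=True))


def segment_eye_state(
    rec: ScoutRecording,
    state: str,
    guard_s: float = 1.0,
    min_duration_s: float = 1.0,
) -> list[ScoutRecording]:
    """Cut out the contiguous stretches annotated with ``state``.

    Parameters
    ----------
    state : "open" or "closed"
    guard_s : float
        Symmetric trim, in seconds, removed from each end of every matching
        interval to suppress eye-transition artifacts.
    min_duration_s : float
        Trimmed segments shorter than this (one spectral window by default)
        are dropped with a warning.

    Returns segments in temporal order; an empty list when nothing matches.
    """
    if state not in ("open", "closed"):
        raise InputError(f"unknown eye state {state!r}")
    if guard_s < 0:
        raise InputError("guard_s must be non-negative")
    segments: list[ScoutRecording] = []
    for start, end, iv_state in sorted(rec.eye_state_intervals):
        if iv_state != state:
            continue
        t0, t1 = start + guard_s, end - guard_s
        if t1 - t0 < min_duration_s:
            logger.warning(
                "dropping %s interval (%.1f, %.1f) s: %.2f s after guard trim "
                "is shorter than %.2f s",
                state, start, end, max(t1 - t0, 0.0), min_duration_s,
            )
            continue
        i0 = int(round(t0 * rec.fs))
        i1 = int(round(t1 * rec.fs))
        segments.append(
            rec.copy_with(
                data=rec.data[:, i0:i1].copy(),
                eye_state_intervals=[(0.0, (i1 - i0) / rec.fs, state)],
            )
        )
    return segments
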