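"""Welch auto- and cross-spectral estimation.

All scout pairs are estimated jointly: every 1-s window (50% overlap,
Hann-tapered, constant-detrended) of every segment is Fourier transformed
once, and the full scouts x scouts cross-spectral matrix is accumulated from
outer products of the window spectra. This gives exactly the same estimate as
pairwise ``scipy.signal.csd`` with matching parameters, but in one pass over
the 62-scout matrix. Windowed segments from separate eyes-closed stretches
are pooled into a single estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from .errors import InputError
from .recording import ScoutRecording

__all__ = ["CrossSpectrum", "welch_cross_spectra"]


@dataclass
class CrossSpectrum:
    """Scout x scout x frequency cross-spectral density matrix.

    ``S[x, x, k]`` is the (real, non-negative) power spectral density of
    scout ``x`` at ``freqs[k]``; ``S[x, y, k]`` the complex cross-spectral
    density. Hermitian in the scout axes. ``n_windows`` is the number of
    averaged windows — kept because the small-sample bias of coherence-type
    estimates scales like 1/sqrt(n_windows).
    """

    freqs: np.ndarray
    S: np.ndarray
    n_windows: int
    scout_names: list[str]

    def __post_init__(self) -> None:
        if self.S.ndim != 3 or self.S.shape[0] != self.S.shape[1]:
            raise InputError("S must have shape (n_scouts, n_scouts, n_freqs)")
        if self.S.shape[2] != len(self.freqs):
            raise InputError("frequency axis mismatch")
        if self.n_windows < 1:
            raise InputError("n_windows must be >= 1")

    @property
    def n_scouts(self) -> int:
        return self.S.shape[0]

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            freqs=self.freqs,
            S=self.S,
            n_windows=self.n_windows,
            scout_names=np.array(self.scout_names),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CrossSpectrum":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                freqs=z["freqs"],
                S=z["S"],
                n_windows=int(z["n_windows"]),
                scout_names=[str(s) for s in z["scout_names"]],
            )


def _window_starts(n_samples: int, nper: int, hop: int) -> np.ndarray:
    if n_samples < nper:
        return np.empty(0, dtype=int)
    return np.arange(0, n_samples - nper + 1, hop)


def welch_cross_spectra(
    segments: list[ScoutRecording] | ScoutRecording,
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> CrossSpectrum:
    """Estimate the pooled cross-spectral matrix of one or more segments.

    Parameters
    ----------
    segments
        Segment(s) sharing sampling rate and scout set. Windows from all
        segments are pooled with equal weight.
    window_s : float
        Window length in seconds (default 1 s -> 1 Hz resolution).
    overlap : float
        Fractional overlap of consecutive windows (default 0.5).

    Returns a one-sided density-scaled :class:`CrossSpectrum`: integrating
    ``S[x, x]`` over frequency recovers the signal variance (Parseval).
    """
    if isinstance(segments, ScoutRecording):
        segments = [segments]
    if not segments:
        raise InputError("no segments given")
    fs = segments[0].fs
    names = segments[0].scout_names
    for seg in segments[1:]:
        if seg.fs != fs:
            raise InputError("segments have mismatched sampling rates")
        if seg.scout_names != names:
            raise InputError("segments have mismatched scout sets")
    if not 0 <= overlap < 1:
        raise InputError(f"overlap must be in [0, 1), got {overlap}")
    nper = int(round(window_s * fs))
    if nper < 2:
        raise InputError("window shorter than 2 samples")
    hop = max(int(round(nper * (1.0 - overlap))), 1)

    taper = signal.get_window("hann", nper, fftbins=True)
    scale = 1.0 / (fs * (taper**2).sum())
    n_freq = nper // 2 + 1
    n_scouts = len(names)

    S = np.zeros((n_scouts, n_scouts, n_freq), dtype=np.complex128)
    n_windows = 0
    for seg in segments:
        starts = _window_starts(seg.n_samples, nper, hop)
        if starts.size == 0:
            continue
        # (n_windows, n_scouts, nper) view of the tapered, detrended windows
        idx = starts[:, None] + np.arange(nper)[None, :]
        wins = seg.data[:, idx]  # (n_scouts, n_win, nper)
        wins = wins - wins.mean(axis=2, keepdims=True)
        X = np.fft.rfft(wins * taper, axis=2)  # (n_scouts, n_win, n_freq)
        # S[x, y] = E[conj(X) Y]: a pure delay of y yields phase -2*pi*f*tau
        S += np.einsum("cwf,dwf->cdf", np.conj(X), X)
        n_windows += starts.size
    if n_windows == 0:
        raise InputError(
            f"no usable windows: every segment is shorter than {window_s} s"
        )
    S *= scale / n_windows
    # one-sided: double all bins except DC (and Nyquist when nper is even)
    last = n_freq - 1 if nper % 2 == 0 else n_freq
    S[:, :, 1:last] *= 2.0
    # the scout-diagonal is real by construction; drop the numerical imag dust
    di = np.arange(n_scouts)
    S[di, di, :] = S[di, di, :].real

    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    return CrossSpectrum(freqs=freqs, S=S, n_windows=n_windows, scout_names=list(names))
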