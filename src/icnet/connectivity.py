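"""Imaginary coherence and band-level connectivity matrices.

The connectivity measure is the absolute imaginary part of coherency,

    IC_xy(f) = | Im( S_xy(f) / sqrt(S_xx(f) S_yy(f)) ) |,

which lies in [0, 1] and is exactly zero for any pair of signals related by
an instantaneous real mixing (volume conduction / source leakage): such
mixing can only produce a real-valued coherency. Non-zero IC therefore
requires genuinely lagged interaction.

Band values are the arithmetic mean of per-frequency IC over the bins inside
the band, taken after the absolute value, and the default alpha band is
8-12 Hz inclusive (five bins at 1 Hz resolution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .spectral import CrossSpectrum, welch_cross_spectra
from .recording import ScoutRecording

__all__ = [
    "ICMatrix",
    "imaginary_coherence",
    "band_ic",
    "scout_aggregate",
    "ic_noise_ceiling",
]

logger = logging.getLogger(__name__)

ALPHA_BAND = (8.0, 12.0)


@dataclass
class ICMatrix:
    """Symmetric scout x scout band imaginary-coherence matrix.

    Diagonal is zero and every entry lies in [0, 1].
    """

    ic: np.ndarray
    band: tuple[float, float]
    scout_names: list[str]
    n_windows: int

    def __post_init__(self) -> None:
        ic = np.asarray(self.ic, dtype=np.float64)
        if ic.ndim != 2 or ic.shape[0] != ic.shape[1]:
            raise InputError("ic must be square")
        if not np.allclose(ic, ic.T, equal_nan=True):
            raise InputError("ic must be symmetric")
        if np.nanmax(ic, initial=0.0) > 1.0 + 1e-9 or np.nanmin(ic, initial=0.0) < 0.0:
            raise InputError("ic entries must lie in [0, 1]")
        if np.any(np.diag(ic) != 0.0):
            raise InputError("ic diagonal must be zero")
        self.ic = ic

    @property
    def n_scouts(self) -> int:
        return self.ic.shape[0]

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: one row per unordered scout pair (i < j)."""
        iu = np.triu_indices(self.n_scouts, k=1)
        return pd.DataFrame(
            {
                "scout_a": [self.scout_names[i] for i in iu[0]],
                "scout_b": [self.scout_names[j] for j in iu[1]],
                "ic": self.ic[iu],
            }
        )

    def save(self, prefix: str | Path) -> None:
        """Write dense CSV plus a long-format CSV next to it."""
        prefix = Path(prefix)
        pd.DataFrame(self.ic, index=self.scout_names, columns=self.scout_names).to_csv(
            prefix.with_suffix(".csv")
        )
        self.to_long_frame().to_csv(
            prefix.with_name(prefix.name + "_long").with_suffix(".csv"), index=False
        )


def imaginary_coherence(cs: CrossSpectrum) -> np.ndarray:
    """Per-frequency absolute imaginary coherence, shape (n, n, n_freqs).

    Bins where an auto-spectrum vanishes are undefined and returned as NaN
    (they are excluded from band aggregation downstream).
    """
    auto = np.einsum("iif->if", cs.S).real  # (n_scouts, n_freq)
    denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    bad = denom <= 0.0
    if bad.any():
        n_bad = int(np.count_nonzero(bad & ~np.eye(cs.n_scouts, dtype=bool)[..., None]))
        if n_bad:
            logger.warning("%d pair-frequency bins have zero auto-spectrum; flagged NaN", n_bad)
    with np.errstate(invalid="ignore", divide="ignore"):
        ic = np.abs(np.imag(cs.S / denom))
    ic[bad] = np.nan
    di = np.arange(cs.n_scouts)
    ic[di, di, :] = 0.0  # auto-coherency is real by construction
    return ic


def band_ic(
    per_freq_ic: np.ndarray,
    freqs: np.ndarray,
    band: tuple[float, float] = ALPHA_BAND,
    scout_names: list[str] | None = None,
    n_windows: int = 1,
) -> ICMatrix:
    """Average per-frequency IC over the bins with f_lo <= f <= f_hi (inclusive).

    NaN-flagged (undefined) bins are excluded from the mean.
    """
    lo, hi = band
    if hi < lo:
        raise InputError(f"empty band ({lo}, {hi})")
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    if not mask.any():
        raise InputError(f"band ({lo}, {hi}) Hz contains no frequency bins")
    with np.errstate(invalid="ignore"):
        band_vals = np.nanmean(per_freq_ic[:, :, mask], axis=2)
    band_vals = np.nan_to_num(band_vals, nan=0.0)
    band_vals = 0.5 * (band_vals + band_vals.T)  # enforce exact symmetry
    np.fill_diagonal(band_vals, 0.0)
    n = band_vals.shape[0]
    names = scout_names if scout_names is not None else [f"scout{i}" for i in range(n)]
    return ICMatrix(ic=band_vals, band=(lo, hi), scout_names=list(names), n_windows=n_windows)


def scout_aggregate(
    vertex_values: np.ndarray, scout_membership: list[list[int]]
) -> np.ndarray:
    """Collapse vertex-level values to scout level by unweighted mean.

    ``scout_membership[k]`` lists the vertex indices of scout ``k``; the lists
    must partition the vertex set. With singleton memberships this is the
    identity (already scout-level input passes through).
    """
    vertex_values = np.asarray(vertex_values, dtype=np.float64)
    n_vertices = vertex_values.shape[0]
    seen: set[int] = set()
    for k, members in enumerate(scout_membership):
        if len(members) == 0:
            raise ConfigurationError(f"scout {k} has no member vertices")
        for v in members:
            if not 0 <= v < n_vertices or v in seen:
                raise ConfigurationError(
                    f"vertex {v} of scout {k} is out of range or assigned twice"
                )
            seen.add(v)
    if len(seen) != n_vertices:
        raise ConfigurationError("membership does not cover every vertex")
    return np.array([vertex_values[members].mean(axis=0) for members in scout_membership])


def ic_noise_ceiling(
    fs: float,
    segment_samples: list[int],
    window_s: float = 1.0,
    overlap: float = 0.5,
    band: tuple[float, float] = ALPHA_BAND,
    n_surrogates: int = 200,
    quantile: float = 0.99,
    seed: int | None = None,
) -> float:
    """Estimate the band-IC noise ceiling for truly unconnected signals.

    Simulates ``n_surrogates`` independent white-noise pairs cut into the
    given segment lengths, runs them through the same Welch / IC / band
    machinery, and returns the requested quantile (default 99%) of the
    resulting null band-IC distribution. IC estimates from finite data are
    positively biased (roughly 1/sqrt(n_windows)), so observed band IC is
    only evidence of lagged coupling when it clears this ceiling.
    """
    rng = np.random.default_rng(seed)
    null_vals = np.empty(n_surrogates)
    for s in range(n_surrogates):
        segs = [
            ScoutRecording(
                data=rng.standard_normal((2, n)), fs=fs, scout_names=["a", "b"]
            )
            for n in segment_samples
        ]
        cs = welch_cross_spectra(segs, window_s=window_s, overlap=overlap)
        icm = band_ic(imaginary_coherence(cs), cs.freqs, band=band, n_windows=cs.n_windows)
        null_vals[s] = icm.ic[0, 1]
    return float(np.quantile(null_vals, quantile))
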