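"""Scout-level recording container and on-disk format.

A :class:`ScoutRecording` holds a scouts x samples amplitude matrix for one
resting-state recording (one subject, one stimulation condition, one
timepoint) together with its sampling rate and an eye-state annotation track.
Recordings are stored as a wide CSV (one column per scout) plus a JSON
sidecar carrying the metadata, so a dataset is plain text end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["ScoutRecording", "read_edf"]

#: canonical condition / timepoint labels used throughout the package
CONDITIONS = ("tRNS", "sham")
TIMEPOINTS = ("pre", "post")


@dataclass
class ScoutRecording:
    """One multi-scout time series with metadata.

    Parameters
    ----------
    data : ndarray, shape (n_scouts, n_samples)
        Amplitudes in arbitrary units.
    fs : float
        Sampling rate in Hz.
    scout_names : list of str
        Unique ordered scout labels, one per row of ``data``.
    subject, condition, timepoint : str or None
        Study-cell labels ("S01", "tRNS"/"sham", "pre"/"post").
    eye_state_intervals : list of (start_s, end_s, state)
        Non-overlapping annotation intervals; ``state`` is "open" or "closed".
    """

    data: np.ndarray
    fs: float
    scout_names: list[str]
    subject: str | None = None
    condition: str | None = None
    timepoint: str | None = None
    eye_state_intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise InputError("data must be a 2-D scouts x samples matrix")
        if self.fs <= 0:
            raise InputError(f"sampling rate must be positive, got {self.fs}")
        if len(self.scout_names) != self.data.shape[0]:
            raise InputError(
                f"{len(self.scout_names)} scout names for {self.data.shape[0]} rows"
            )
        if len(set(self.scout_names)) != len(self.scout_names):
            raise InputError("scout names must be unique")
        self._check_intervals()

    def _check_intervals(self) -> None:
        prev_end = 0.0
        for start, end, state in sorted(self.eye_state_intervals):
            if state not in ("open", "closed"):
                raise InputError(f"unknown eye state {state!r}")
            if start < 0 or end > self.duration + 1e-9 or end <= start:
                raise InputError(
                    f"interval ({start}, {end}) outside recording of {self.duration} s"
                )
            if start < prev_end - 1e-9:
                raise InputError("eye-state intervals overlap")
            prev_end = end

    # -- basic geometry -------------------------------------------------
    @property
    def n_scouts(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs

    def copy_with(self, **changes) -> "ScoutRecording":
        """Return a copy with selected fields replaced (data is not shared)."""
        if "data" not in changes:
            changes["data"] = self.data.copy()
        return replace(self, **changes)

    # -- persistence -----------------------------------------------------
    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.csv`` (samples x scouts) and ``<prefix>.json``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        csv_path = prefix.with_suffix(".csv")
        json_path = prefix.with_suffix(".json")
        pd.DataFrame(self.data.T, columns=self.scout_names).to_csv(
            csv_path, index=False, float_format="%.10g"
        )
        sidecar = {
            "fs": self.fs,
            "scout_names": list(self.scout_names),
            "subject": self.subject,
            "condition": self.condition,
            "timepoint": self.timepoint,
            "eye_state_intervals": [list(iv) for iv in self.eye_state_intervals],
        }
        json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        return csv_path, json_path

    @classmethod
    def load(cls, prefix: str | Path) -> "ScoutRecording":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        frame = pd.read_csv(prefix.with_suffix(".csv"))
        names = meta["scout_names"]
        if list(frame.columns) != names:
            frame = frame[names]
        return cls(
            data=frame.to_numpy().T,
            fs=float(meta["fs"]),
            scout_names=list(names),
            subject=meta.get("subject"),
            condition=meta.get("condition"),
            timepoint=meta.get("timepoint"),
            eye_state_intervals=[tuple(iv) for iv in meta.get("eye_state_intervals", [])],
        )


def read_edf(edf_path: str | Path, sidecar_path: str | Path) -> ScoutRecording:
    """Read a recording from EDF plus a JSON metadata sidecar.

    The sidecar supplies what EDF cannot carry: subject/condition/timepoint
    labels and the eye-state annotation track. Requires ``mne``.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF ingestion requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    meta = json.loads(Path(sidecar_path).read_text())
    return ScoutRecording(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        scout_names=list(raw.ch_names),
        subject=meta.get("subject"),
        condition=meta.get("condition"),
        timepoint=meta.get("timepoint"),
        eye_state_intervals=[tuple(iv) for iv in meta.get("eye_state_intervals", [])],
    )
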