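"""Graph metrics on IC matrices and pre/post x condition change scores.

Weighted node degree (wND) of a scout is the sum of its band-IC values to
every other scout — a hub-ness measure. wND values are z-scored across the
62 scouts of a recording, z-scores are averaged within the left and right
frontal region sets, and change scores are built as

    wND change = (post - pre)_tRNS - (post - pre)_sham,

isolating the stimulation-specific change from session effects. Behavioral
change scores are simply tRNS - sham, since behavior is measured once per
session, during stimulation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ICMatrix
from .errors import ConfigurationError, DegenerateInputError, InputError

__all__ = [
    "Atlas",
    "load_atlas",
    "NetworkMetrics",
    "ChangeTable",
    "weighted_node_degree",
    "z_normalize",
    "region_mean",
    "network_metrics",
    "change_scores",
]

logger = logging.getLogger(__name__)


@dataclass
class Atlas:
    """Scout parcellation with hemisphere/lobe labels and named region sets.

    The default 62-scout atlas mirrors the Mindboggle (DKT) cortical
    parcellation: 31 regions per hemisphere. It ships as an editable JSON
    data file; the ``frontal_left`` / ``frontal_right`` region sets are the
    full frontal lobe of each hemisphere, orbitofrontal scouts included.
    """

    scout_names: list[str]
    hemisphere: dict[str, str]
    lobe: dict[str, str]
    region_sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.scout_names)) != len(self.scout_names):
            raise ConfigurationError("atlas scout names must be unique")
        known = set(self.scout_names)
        for region, members in self.region_sets.items():
            if not members:
                raise ConfigurationError(f"region set {region!r} is empty")
            unknown = [m for m in members if m not in known]
            if unknown:
                raise ConfigurationError(f"region {region!r} names unknown scouts {unknown}")

    @classmethod
    def from_json(cls, path: str | Path) -> "Atlas":
        doc = json.loads(Path(path).read_text())
        return cls(
            scout_names=[s["name"] for s in doc["scouts"]],
            hemisphere={s["name"]: s["hemisphere"] for s in doc["scouts"]},
            lobe={s["name"]: s["lobe"] for s in doc["scouts"]},
            region_sets={k: list(v) for k, v in doc.get("region_sets", {}).items()},
        )


def load_atlas(path: str | Path | None = None) -> Atlas:
    """Load an atlas JSON; with no argument, the bundled 62-scout atlas."""
    if path is not None:
        return Atlas.from_json(path)
    ref = resources.files("icnet.data").joinpath("atlas_mindboggle62.json")
    with resources.as_file(ref) as p:
        return Atlas.from_json(p)


@dataclass
class NetworkMetrics:
    """Per-scout wND, its z-scores, and named region means of z."""

    wnd: pd.Series
    z: pd.Series | None
    region_means: dict[str, float]


@dataclass
class ChangeTable:
    """Per-subject change scores for network metrics and behavior.

    ``wnd_change``: rows (subject, region) with post-pre deltas per condition
    and their tRNS-sham difference. ``behavior_change``: rows
    (subject, task, measure) with the tRNS-sham delta.
    """

    wnd_change: pd.DataFrame
    behavior_change: pd.DataFrame | None = None

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.wnd_change.to_csv(prefix.with_name(prefix.name + "_wnd.csv"), index=False)
        if self.behavior_change is not None:
            self.behavior_change.to_csv(
                prefix.with_name(prefix.name + "_behavior.csv"), index=False
            )


def weighted_node_degree(icm: ICMatrix) -> pd.Series:
    """wND_i = sum_j!=i IC_ij — row sums of the zero-diagonal IC matrix."""
    return pd.Series(icm.ic.sum(axis=1), index=icm.scout_names, name="wnd")


def z_normalize(wnd: pd.Series | np.ndarray, ddof: int = 1) -> pd.Series:
    """Z-score wND across scouts: (wnd - mean) / sd, sample sd (n-1) by default."""
    vals = np.asarray(wnd, dtype=np.float64)
    if vals.size < 2:
        raise InputError("z-normalization needs at least 2 scouts")
    sd = vals.std(ddof=ddof)
    if sd <= 1e-12 * max(np.abs(vals).max(), 1.0):
        raise DegenerateInputError("all wND values equal: z-scores undefined")
    z = (vals - vals.mean()) / sd
    index = wnd.index if isinstance(wnd, pd.Series) else None
    return pd.Series(z, index=index, name="z")


def region_mean(z: pd.Series, atlas: Atlas, region: str) -> float:
    """Unweighted mean of z-scored wND over the scouts of a named region."""
    if region not in atlas.region_sets:
        raise ConfigurationError(
            f"unknown region {region!r}; atlas defines {sorted(atlas.region_sets)}"
        )
    members = atlas.region_sets[region]
    missing = [m for m in members if m not in z.index]
    if missing:
        raise ConfigurationError(f"region {region!r} scouts missing from metrics: {missing}")
    return float(z.loc[members].mean())


def network_metrics(icm: ICMatrix, atlas: Atlas | None = None) -> NetworkMetrics:
    """Convenience: wND -> z -> region means in one call.

    On degenerate (constant) wND the z-scores and region means are recorded
    as missing rather than raising, so one flat recording does not abort a
    whole study analysis.
    """
    wnd = weighted_node_degree(icm)
    try:
        z = z_normalize(wnd)
    except DegenerateInputError:
        logger.warning("constant wND: recording region means as missing")
        return NetworkMetrics(wnd=wnd, z=None, region_means={})
    regions = {}
    if atlas is not None:
        regions = {name: region_mean(z, atlas, name) for name in atlas.region_sets}
    return NetworkMetrics(wnd=wnd, z=z, region_means=regions)


def change_scores(
    metrics: pd.DataFrame,
    behavior: pd.DataFrame | None = None,
    conditions: tuple[str, str] = ("tRNS", "sham"),
    timepoints: tuple[str, str] = ("pre", "post"),
) -> ChangeTable:
    """Build per-subject change scores from tidy per-recording metrics.

    Parameters
    ----------
    metrics : DataFrame with columns (subject, condition, timepoint, region, value)
        Region-mean z-scored wND per recording. Subjects missing any of the
        four condition x timepoint cells for a region are excluded (logged).
    behavior : optional DataFrame with columns (subject, condition, task, measure, value)
        Session-level behavioral scores; subjects missing a condition are
        excluded from the behavioral part.
    """
    active, control = conditions
    pre, post = timepoints
    required = {"subject", "condition", "timepoint", "region", "value"}
    if not required.issubset(metrics.columns):
        raise InputError(f"metrics frame needs columns {sorted(required)}")

    wide = metrics.pivot_table(
        index=["subject", "region"], columns=["condition", "timepoint"],
        values="value", aggfunc="first",
    )
    needed = [(active, pre), (active, post), (control, pre), (control, post)]
    missing_cells = [c for c in needed if c not in wide.columns]
    if missing_cells:
        raise InputError(f"metrics frame lacks cells {missing_cells}")
    complete = wide.dropna(subset=needed)
    dropped = sorted(set(wide.index.get_level_values("subject"))
                     - set(complete.index.get_level_values("subject")))
    if dropped:
        logger.warning("excluding subjects with missing EEG cells: %s", dropped)

    out = pd.DataFrame(
        {
            "subject": complete.index.get_level_values("subject"),
            "region": complete.index.get_level_values("region"),
            "delta_active": (complete[(active, post)] - complete[(active, pre)]).to_numpy(),
            "delta_control": (complete[(control, post)] - complete[(control, pre)]).to_numpy(),
        }
    )
    out["wnd_change"] = out["delta_active"] - out["delta_control"]

    beh_out = None
    if behavior is not None:
        breq = {"subject", "condition", "task", "measure", "value"}
        if not breq.issubset(behavior.columns):
            raise InputError(f"behavior frame needs columns {sorted(breq)}")
        bw = behavior.pivot_table(
            index=["subject", "task", "measure"], columns="condition",
            values="value", aggfunc="first",
        )
        for cond in (active, control):
            if cond not in bw.columns:
                raise InputError(f"behavior frame lacks condition {cond!r}")
        bcomplete = bw.dropna(subset=[active, control])
        bdropped = sorted(set(bw.index.get_level_values("subject"))
                          - set(bcomplete.index.get_level_values("subject")))
        if bdropped:
            logger.warning("excluding subjects with missing behavior: %s", bdropped)
        beh_out = pd.DataFrame(
            {
                "subject": bcomplete.index.get_level_values("subject"),
                "task": bcomplete.index.get_level_values("task"),
                "measure": bcomplete.index.get_level_values("measure"),
                "change": (bcomplete[active] - bcomplete[control]).to_numpy(),
            }
        )
    return ChangeTable(wnd_change=out.reset_index(drop=True), behavior_change=beh_out)
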