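"""End-to-end analysis: recordings -> band IC -> networks -> statistics.

One recording flows through band-pass filter (0.5-40 Hz, zero-phase),
average reference, eyes-closed segmentation (1 s guard trim), pooled Welch
cross-spectra (1 s windows, 50% overlap), per-frequency imaginary coherence
and alpha-band (8-12 Hz) averaging. Study-level statistics are edge-wise
sign-flip permutation t-tests with BH-FDR on the difference of post-pre IC
changes between conditions, baseline paired t-tests on the frontal region
means, and backward regressions of frontal wND change on the behavioral
change scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import ALPHA_BAND, ICMatrix, band_ic, imaginary_coherence
from .errors import ConfigurationError, InputError
from .network import (
    Atlas,
    ChangeTable,
    change_scores,
    network_metrics,
)
from .preprocess import average_reference, bandpass, segment_eye_state
from .recording import CONDITIONS, TIMEPOINTS, ScoutRecording
from .spectral import welch_cross_spectra
from .stats import (
    RegressionResult,
    StatResult,
    backward_regression,
    paired_t,
    perm_paired_edges,
)

__all__ = ["AnalysisConfig", "StudyResults", "recording_band_ic", "analyze_study",
           "generic_atlas"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """All tunable pipeline parameters with their defaults."""

    band: tuple[float, float] = ALPHA_BAND
    bp_low: float = 0.5
    bp_high: float = 40.0
    window_s: float = 1.0
    overlap: float = 0.5
    guard_s: float = 1.0
    reference: bool = True
    eye_state: str = "closed"
    n_perm: int = 5000
    alphas: tuple[float, ...] = (0.05, 0.01)
    removal_p: float = 0.10
    fdr_method: str = "bh"
    flexibility_variant: str = "pairwise"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def generic_atlas(scout_names: list[str]) -> Atlas:
    """A minimal atlas for synthetic scout sets without anatomical labels.

    First half of the scouts is "left", second half "right"; the first half
    of each hemisphere plays the frontal lobe, so ``frontal_left`` /
    ``frontal_right`` region sets always exist.
    """
    n = len(scout_names)
    if n < 4:
        raise ConfigurationError("generic atlas needs at least 4 scouts")
    half = n // 2
    hemi = {s: ("L" if i < half else "R") for i, s in enumerate(scout_names)}
    lobe = {}
    for i, s in enumerate(scout_names):
        pos = i if i < half else i - half
        size = half if i < half else n - half
        lobe[s] = "frontal" if pos < max(size // 2, 1) else "posterior"
    region_sets = {
        "frontal_left": [s for s in scout_names if hemi[s] == "L" and lobe[s] == "frontal"],
        "frontal_right": [s for s in scout_names if hemi[s] == "R" and lobe[s] == "frontal"],
    }
    return Atlas(scout_names=list(scout_names), hemisphere=hemi, lobe=lobe,
                 region_sets=region_sets)


def recording_band_ic(rec: ScoutRecording, cfg: AnalysisConfig | None = None) -> ICMatrix:
    """Preprocess one recording and return its band IC matrix."""
    cfg = cfg or AnalysisConfig()
    rec = bandpass(rec, cfg.bp_low, cfg.bp_high)
    if cfg.reference and rec.n_scouts >= 2:
        rec = average_reference(rec)
    if rec.eye_state_intervals:
        segments = segment_eye_state(
            rec, cfg.eye_state, guard_s=cfg.guard_s, min_duration_s=cfg.window_s
        )
    else:
        segments = [rec]
    if not segments:
        raise InputError(
            f"recording {rec.subject}/{rec.condition}/{rec.timepoint} has no "
            f"usable {cfg.eye_state}-eye segments"
        )
    cs = welch_cross_spectra(segments, window_s=cfg.window_s, overlap=cfg.overlap)
    return band_ic(
        imaginary_coherence(cs), cs.freqs, band=cfg.band,
        scout_names=cs.scout_names, n_windows=cs.n_windows,
    )


@dataclass
class StudyResults:
    """All study-level outputs of :func:`analyze_study`."""

    edge_stats: pd.DataFrame
    metrics: pd.DataFrame
    change_table: ChangeTable
    baseline_tests: dict[str, StatResult]
    regressions: dict[tuple[str, str], RegressionResult]
    simple_regressions: dict[tuple[str, str, str], RegressionResult]
    config: AnalysisConfig
    n_subjects: int

    def summary(self) -> dict:
        """Machine-readable run summary."""
        sig = {}
        for a in self.config.alphas:
            sig[f"edges_p_lt_{a}"] = int((self.edge_stats["p"] < a).sum())
            sig[f"edges_fdr_lt_{a}"] = int((self.edge_stats["p_fdr"] < a).sum())
        regs = {}
        for (task, region), res in self.regressions.items():
            regs[f"{task}:{region}"] = {
                "retained": res.predictors,
                "r_squared": res.r_squared,
                "model_p": res.model_p,
                "beta": {k: float(v) for k, v in res.beta.items()},
            }
        return {
            "version": __version__,
            "config": _jsonable(self.config.to_dict()),
            "n_subjects": self.n_subjects,
            "n_edges": int(len(self.edge_stats)),
            "significant_edges": sig,
            "baseline_tests": {
                k: {"t": r.statistic, "df": r.df, "p": r.p}
                for k, r in self.baseline_tests.items()
            },
            "regressions": regs,
        }

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.edge_stats.to_csv(out_dir / "edge_stats.csv", index=False)
        self.metrics.to_csv(out_dir / "metrics.csv", index=False)
        self.change_table.save(out_dir / "change")
        reg_rows = []
        for (task, region), res in self.regressions.items():
            for pred in res.predictors:
                reg_rows.append(
                    {
                        "task": task, "region": region, "measure": pred,
                        "B": res.coef[pred], "SE_B": res.se[pred],
                        "beta": res.beta[pred], "p": res.pvalues[pred],
                        "model_r_squared": res.r_squared, "model_p": res.model_p,
                        "retained": True,
                    }
                )
            if not res.predictors:
                reg_rows.append(
                    {"task": task, "region": region, "measure": None,
                     "B": np.nan, "SE_B": np.nan, "beta": np.nan, "p": np.nan,
                     "model_r_squared": res.r_squared, "model_p": res.model_p,
                     "retained": False}
                )
        reg_cols = ["task", "region", "measure", "B", "SE_B", "beta", "p",
                    "model_r_squared", "model_p", "retained"]
        pd.DataFrame(reg_rows, columns=reg_cols).to_csv(
            out_dir / "regressions.csv", index=False
        )
        (out_dir / "summary.json").write_text(
            json.dumps(self.summary(), indent=1, sort_keys=True)
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _edge_vectors(ics: dict[tuple[str, str, str], ICMatrix]) -> tuple:
    """Upper-triangle IC vectors per recording, with the shared edge list."""
    any_icm = next(iter(ics.values()))
    names = any_icm.scout_names
    iu = np.triu_indices(len(names), k=1)
    vectors = {}
    for key, icm in ics.items():
        if icm.scout_names != names:
            raise InputError("recordings disagree on the scout set")
        vectors[key] = icm.ic[iu]
    edges = [(names[i], names[j]) for i, j in zip(*iu)]
    return vectors, edges


def analyze_study(
    recordings: list[ScoutRecording],
    atlas: Atlas | None = None,
    behavior: pd.DataFrame | None = None,
    cfg: AnalysisConfig | None = None,
) -> StudyResults:
    """Run the full analysis over a study's recordings.

    Parameters
    ----------
    recordings
        All subject x condition x timepoint recordings (4 per subject).
    atlas
        Scout parcellation; defaults to a generic split when the scouts do
        not match the bundled 62-scout atlas.
    behavior : optional tidy frame (subject, condition, task, measure, value)
        Session-level behavioral scores used for the brain-behavior
        regressions.
    """
    cfg = cfg or AnalysisConfig()
    if not recordings:
        raise InputError("no recordings")
    if atlas is None:
        atlas = generic_atlas(recordings[0].scout_names)
    missing = [s for s in recordings[0].scout_names if s not in set(atlas.scout_names)]
    if missing:
        raise ConfigurationError(f"recordings contain scouts missing from atlas: {missing}")

    ics: dict[tuple[str, str, str], ICMatrix] = {}
    metric_rows = []
    for rec in recordings:
        key = (rec.subject, rec.condition, rec.timepoint)
        if None in key:
            raise InputError("every recording needs subject/condition/timepoint labels")
        if key in ics:
            raise InputError(f"duplicate recording for cell {key}")
        icm = recording_band_ic(rec, cfg)
        ics[key] = icm
        nm = network_metrics(icm, atlas)
        for region, value in nm.region_means.items():
            metric_rows.append(
                {"subject": rec.subject, "condition": rec.condition,
                 "timepoint": rec.timepoint, "region": region, "value": value}
            )
    metrics = pd.DataFrame(metric_rows)

    # edge-wise permutation statistics on the raw IC change difference
    vectors, edges = _edge_vectors(ics)
    subjects = sorted({k[0] for k in ics})
    active, control = CONDITIONS
    pre, post = TIMEPOINTS
    rows_a, rows_c, used_subjects = [], [], []
    for s in subjects:
        cells = [(s, c, t) for c in (active, control) for t in (pre, post)]
        if not all(c in vectors for c in cells):
            logger.warning("subject %s lacks a study cell; excluded from edge stats", s)
            continue
        rows_a.append(vectors[(s, active, post)] - vectors[(s, active, pre)])
        rows_c.append(vectors[(s, control, post)] - vectors[(s, control, pre)])
        used_subjects.append(s)
    if len(used_subjects) < 2:
        raise InputError("fewer than 2 complete subjects")
    edge_stats = perm_paired_edges(
        np.array(rows_a), np.array(rows_c),
        n_perm=cfg.n_perm, seed=cfg.seed, fdr_method=cfg.fdr_method,
    )
    edge_stats.insert(0, "scout_b", [e[1] for e in edges])
    edge_stats.insert(0, "scout_a", [e[0] for e in edges])

    # baseline confound check: active-pre vs control-pre frontal region means
    baseline: dict[str, StatResult] = {}
    for region in atlas.region_sets:
        sub = metrics[metrics["region"] == region].pivot_table(
            index="subject", columns=["condition", "timepoint"], values="value",
            aggfunc="first",
        )
        if (active, pre) in sub.columns and (control, pre) in sub.columns:
            both = sub.dropna(subset=[(active, pre), (control, pre)])
            if len(both) >= 2:
                baseline[region] = paired_t(
                    both[(active, pre)].to_numpy(), both[(control, pre)].to_numpy()
                )

    change = change_scores(metrics, behavior)

    regressions: dict[tuple[str, str], RegressionResult] = {}
    simple: dict[tuple[str, str, str], RegressionResult] = {}
    if change.behavior_change is not None and not change.behavior_change.empty:
        bwide = change.behavior_change.pivot_table(
            index=["subject", "task"], columns="measure", values="change", aggfunc="first"
        ).reset_index()
        for task, tgrp in bwide.groupby("task"):
            for region in atlas.region_sets:
                wsub = change.wnd_change[change.wnd_change["region"] == region]
                merged = wsub.merge(tgrp, on="subject", how="inner").dropna()
                measures = [c for c in ("fluency", "originality", "flexibility")
                            if c in merged.columns]
                if len(merged) < len(measures) + 2:
                    logger.warning("too few subjects for %s/%s regression", task, region)
                    continue
                res = backward_regression(
                    merged["wnd_change"], merged[measures], removal_p=cfg.removal_p
                )
                regressions[(task, region)] = res
                for pred in res.predictors:
                    simple[(task, region, pred)] = backward_regression(
                        merged["wnd_change"], merged[[pred]], removal_p=1.0
                    )

    return StudyResults(
        edge_stats=edge_stats,
        metrics=metrics,
        change_table=change,
        baseline_tests=baseline,
        regressions=regressions,
        simple_regressions=simple,
        config=cfg,
        n_subjects=len(used_subjects),
    )
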