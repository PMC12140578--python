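"""Synthetic scout-level EEG studies and verbal-response datasets.

Everything downstream of raw data acquisition is testable against this
module because it generates data with known ground truth:

* **Oscillators** are band-pass-filtered Gaussian noise carriers. A coupled
  scout pair shares one narrowband analytic carrier; the second scout
  receives a copy rotated by the edge's phase lag (plus an independent
  carrier weighted so the coupling coefficient equals ``strength``). This
  gives direct control over the phase lag that imaginary coherence detects.
* **Source leakage / volume conduction** is an instantaneous real mixing
  matrix applied after coupling — exactly the confound that imaginary
  coherence is designed to reject, so a zero-lag-only world must produce
  null-level IC.
* **Study structure**: n subjects x {tRNS, sham} x {pre, post} resting-state
  recordings with alternating eyes-open/eyes-closed blocks. Effect edges
  perturb coupling only in the tRNS-post cell, with a per-subject random
  magnitude that is recorded as ground truth.
* **Behavior**: answer pools with long-tailed (Zipf) frequencies and a
  clustered embedding geometry. A ``behavior_link`` coefficient couples a
  subject's injected connectivity change to their tRNS-session shift in
  answer rarity (originality) and cluster switching (flexibility); fluency
  stays null. With ``behavior_link = 0`` the population brain-behavior
  correlation is zero by construction.

All randomness flows through one ``numpy`` SeedSequence per study, so equal
seeds give bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .behavior import EmbeddingSpace
from .errors import ConfigurationError, InputError
from .recording import CONDITIONS, TIMEPOINTS, ScoutRecording

__all__ = [
    "CouplingEdge",
    "CouplingSpec",
    "EffectEdge",
    "StudyDesign",
    "StudyData",
    "AnswerPool",
    "default_leakage",
    "default_base_spec",
    "gen_scout_signals",
    "gen_ground_truth",
    "gen_study",
    "gen_behavior",
]


# ---------------------------------------------------------------------------
# coupling specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingEdge:
    """Lagged narrowband coupling between two scouts."""

    scout_i: int
    scout_j: int
    freq_hz: float = 10.0
    strength: float = 0.8
    phase_lag: float = np.pi / 2


@dataclass
class CouplingSpec:
    """Generator configuration for one recording.

    ``noise_sd`` scales the broadband background of each scout;
    ``background_alpha_amp`` adds an *independent* narrowband alpha component
    per scout (an alpha rhythm without any true coupling);
    ``leakage_mix`` (unit diagonal) mixes the finished source signals
    instantaneously.
    """

    edges: list[CouplingEdge] = field(default_factory=list)
    leakage_mix: np.ndarray | None = None
    noise_sd: float | np.ndarray = 1.0
    carrier_amp: float = 2.0
    carrier_bw: float = 2.0
    background_alpha_amp: float = 1.0
    background_alpha_band: tuple[float, float] = (8.0, 12.0)

    def validate(self, n_scouts: int, fs: float) -> None:
        seen = set()
        for e in self.edges:
            for idx in (e.scout_i, e.scout_j):
                if not 0 <= idx < n_scouts:
                    raise ConfigurationError(f"edge scout index {idx} out of range")
            if e.scout_i == e.scout_j:
                raise ConfigurationError("self-coupling edge")
            key = frozenset((e.scout_i, e.scout_j))
            if key in seen:
                raise ConfigurationError(f"duplicate edge {tuple(sorted(key))}")
            seen.add(key)
            if not 0.0 <= e.strength <= 1.0:
                raise ConfigurationError(f"coupling strength {e.strength} outside [0, 1]")
            if e.freq_hz >= fs / 2:
                raise ConfigurationError(
                    f"carrier {e.freq_hz} Hz at or above Nyquist {fs / 2} Hz"
                )
        if self.leakage_mix is not None:
            L = np.asarray(self.leakage_mix, dtype=np.float64)
            if L.shape != (n_scouts, n_scouts):
                raise ConfigurationError("leakage_mix shape does not match scout count")
            if not np.allclose(np.diag(L), 1.0):
                raise ConfigurationError("leakage_mix must have unit diagonal")


def default_leakage(n_scouts: int, strength: float = 0.25, reach: int = 2) -> np.ndarray:
    """Banded instantaneous mixing: neighbours within ``reach`` receive
    ``strength**distance`` of each other's signal. Unit diagonal."""
    L = np.eye(n_scouts)
    for d in range(1, reach + 1):
        off = strength**d
        L += off * (np.eye(n_scouts, k=d) + np.eye(n_scouts, k=-d))
    return L


def default_base_spec(n_scouts: int) -> CouplingSpec:
    """Baseline world shared by every study cell: independent alpha rhythms,
    broadband noise, and banded zero-lag source leakage. No true coupling."""
    return CouplingSpec(edges=[], leakage_mix=default_leakage(n_scouts))


# ---------------------------------------------------------------------------
# signal generation
# ---------------------------------------------------------------------------

def _bandlimited_noise(
    rng: np.random.Generator, shape: tuple, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band`` (zero-phase)."""
    lo, hi = band
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _analytic_carrier(
    rng: np.random.Generator, n: int, fs: float, f0: float, bw: float
) -> np.ndarray:
    """Complex analytic narrowband carrier centred on ``f0``, unit real-part RMS."""
    lo = max(f0 - bw / 2.0, 0.1)
    hi = min(f0 + bw / 2.0, fs / 2.0 - 0.1)
    x = _bandlimited_noise(rng, (n,), fs, (lo, hi))
    return signal.hilbert(x)


def _eye_intervals(duration_s: float, block_s: float) -> list[tuple[float, float, str]]:
    """Alternating eyes-open / eyes-closed blocks, starting open."""
    intervals = []
    t, state = 0.0, "open"
    while t < duration_s - 1e-9:
        end = min(t + block_s, duration_s)
        intervals.append((t, end, state))
        t = end
        state = "closed" if state == "open" else "open"
    return intervals


def gen_scout_signals(
    spec: CouplingSpec,
    n_scouts: int,
    fs: float,
    duration_s: float,
    seed: int | np.random.SeedSequence | np.random.Generator,
    eye_block_s: float = 35.0,
    scout_names: list[str] | None = None,
    subject: str | None = None,
    condition: str | None = None,
    timepoint: str | None = None,
) -> ScoutRecording:
    """Generate one scout-level recording from a coupling specification.

    Coupled pairs share a narrowband analytic carrier; the second scout's
    copy is rotated by the edge's phase lag and diluted with an independent
    carrier so that the shared fraction equals ``strength``. Leakage mixing
    is applied after all coupling. Reproducible under ``seed``.
    """
    if duration_s <= 0:
        raise InputError("duration must be positive")
    n = int(round(fs * duration_s))
    if n < 2 * fs:
        raise InputError("recording must be at least 2 s long")
    spec.validate(n_scouts, fs)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    noise_sd = np.broadcast_to(np.asarray(spec.noise_sd, dtype=float), (n_scouts,))
    X = rng.standard_normal((n_scouts, n)) * noise_sd[:, None]
    if spec.background_alpha_amp > 0:
        X += spec.background_alpha_amp * _bandlimited_noise(
            rng, (n_scouts, n), fs, spec.background_alpha_band
        )
    for e in spec.edges:
        shared = _analytic_carrier(rng, n, fs, e.freq_hz, spec.carrier_bw)
        private = _analytic_carrier(rng, n, fs, e.freq_hz, spec.carrier_bw)
        X[e.scout_i] += spec.carrier_amp * shared.real
        lagged = (shared * np.exp(-1j * e.phase_lag)).real
        X[e.scout_j] += spec.carrier_amp * (
            e.strength * lagged + np.sqrt(1.0 - e.strength**2) * private.real
        )
    if spec.leakage_mix is not None:
        X = np.asarray(spec.leakage_mix, dtype=np.float64) @ X

    names = scout_names or [f"scout{i:02d}" for i in range(n_scouts)]
    return ScoutRecording(
        data=X,
        fs=fs,
        scout_names=names,
        subject=subject,
        condition=condition,
        timepoint=timepoint,
        eye_state_intervals=_eye_intervals(n / fs, eye_block_s),
    )


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectEdge:
    """Coupling increment applied only in the tRNS-post cell."""

    scout_i: int
    scout_j: int
    delta_coupling: float = 0.4
    freq_hz: float = 10.0
    phase_lag: float = np.pi / 2


@dataclass
class StudyDesign:
    """Design of a synthetic stimulation study.

    Defaults mirror the emulated experiment: 40 subjects, two sessions
    (active tRNS vs sham) with 5-min pre- and post-stimulation resting-state
    recordings over 62 scouts, eyes open/closed alternating every 35 s.
    ``behavior_link`` in [0, 1] is the correlation between a subject's
    injected connectivity change and their stimulation-session shift in
    originality / flexibility.
    """

    n_subjects: int = 40
    effect_edges: list[EffectEdge] = field(default_factory=list)
    behavior_link: float = 0.0
    seed: int = 0
    n_scouts: int = 62
    fs: float = 250.0
    duration_s: float = 300.0
    eye_block_s: float = 35.0
    subject_effect_jitter: float = 0.5

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("need at least 2 subjects")
        if not 0.0 <= self.behavior_link <= 1.0:
            raise ConfigurationError("behavior_link must lie in [0, 1]")
        seen = set()
        for e in self.effect_edges:
            for idx in (e.scout_i, e.scout_j):
                if not 0 <= idx < self.n_scouts:
                    raise ConfigurationError(f"effect edge scout {idx} out of range")
            key = frozenset((e.scout_i, e.scout_j))
            if key in seen:
                raise ConfigurationError(f"duplicate effect edge {tuple(sorted(key))}")
            seen.add(key)

    @property
    def subjects(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]


@dataclass
class StudyData:
    """A generated study: recordings plus ground truth."""

    recordings: list[ScoutRecording]
    ground_truth: pd.DataFrame
    ground_truth_edges: pd.DataFrame
    design: StudyDesign

    def save(self, out_dir: str | Path) -> dict:
        """Write recordings, ground truth and a manifest; returns the manifest."""
        out_dir = Path(out_dir)
        (out_dir / "recordings").mkdir(parents=True, exist_ok=True)
        files = []
        for rec in self.recordings:
            prefix = out_dir / "recordings" / f"{rec.subject}_{rec.condition}_{rec.timepoint}"
            rec.save(prefix)
            files.append(prefix.name)
        self.ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
        self.ground_truth_edges.to_csv(out_dir / "ground_truth_edges.csv", index=False)
        manifest = {
            "seed": self.design.seed,
            "n_subjects": self.design.n_subjects,
            "n_scouts": self.design.n_scouts,
            "fs": self.design.fs,
            "duration_s": self.design.duration_s,
            "n_recordings": len(self.recordings),
            "recordings": files,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest


def _study_seeds(design: StudyDesign) -> tuple:
    """Stable seed layout: [effects, behavior, one per recording]."""
    root = np.random.SeedSequence(design.seed)
    children = root.spawn(2 + 4 * design.n_subjects)
    return children[0], children[1], children[2:]


def gen_ground_truth(design: StudyDesign) -> pd.DataFrame:
    """Per-subject injected effect magnitudes (deterministic given the seed).

    ``u`` is the subject's multiplicative effect jitter, drawn uniformly from
    ``1 +/- subject_effect_jitter``; ``connectivity_change`` is the mean
    coupling increment the subject receives over the effect edges (0 for a
    null design).
    """
    design.validate()
    effect_seed, _, _ = _study_seeds(design)
    rng = np.random.default_rng(effect_seed)
    j = design.subject_effect_jitter
    u = rng.uniform(1.0 - j, 1.0 + j, size=design.n_subjects)
    mean_delta = (
        float(np.mean([e.delta_coupling for e in design.effect_edges]))
        if design.effect_edges
        else 0.0
    )
    return pd.DataFrame(
        {
            "subject": design.subjects,
            "u": u,
            "connectivity_change": mean_delta * u if design.effect_edges else 0.0 * u,
        }
    )


def _cell_spec(
    base: CouplingSpec, design: StudyDesign, u_s: float, condition: str, timepoint: str
) -> CouplingSpec:
    """Coupling spec of one study cell; effect edges act only in tRNS-post."""
    if condition != CONDITIONS[0] or timepoint != TIMEPOINTS[1]:
        return base
    edges = {frozenset((e.scout_i, e.scout_j)): e for e in base.edges}
    for eff in design.effect_edges:
        delta = float(np.clip(eff.delta_coupling * u_s, 0.0, 0.95))
        key = frozenset((eff.scout_i, eff.scout_j))
        if key in edges:
            old = edges[key]
            edges[key] = replace(old, strength=float(np.clip(old.strength + delta, 0.0, 0.99)))
        else:
            edges[key] = CouplingEdge(
                eff.scout_i, eff.scout_j, eff.freq_hz, delta, eff.phase_lag
            )
    return replace(base, edges=list(edges.values()))


def gen_study(design: StudyDesign, base_spec: CouplingSpec | None = None) -> StudyData:
    """Generate the full 2x2 study: four recordings per subject.

    The baseline spec applies to every cell; each effect edge's coupling is
    incremented by ``delta_coupling * u_s`` in the tRNS-post cell only, where
    ``u_s`` is the subject's jitter from :func:`gen_ground_truth`.
    """
    design.validate()
    if base_spec is None:
        base_spec = default_base_spec(design.n_scouts)
    base_spec.validate(design.n_scouts, design.fs)
    ground_truth = gen_ground_truth(design)
    _, _, rec_seeds = _study_seeds(design)
    u_by_subject = dict(zip(ground_truth["subject"], ground_truth["u"]))
    scout_names = [f"scout{i:02d}" for i in range(design.n_scouts)]

    recordings: list[ScoutRecording] = []
    edge_rows: list[dict] = []
    k = 0
    for subject in design.subjects:
        for condition in CONDITIONS:
            for timepoint in TIMEPOINTS:
                spec = _cell_spec(base_spec, design, u_by_subject[subject], condition, timepoint)
                recordings.append(
                    gen_scout_signals(
                        spec,
                        design.n_scouts,
                        design.fs,
                        design.duration_s,
                        seed=np.random.default_rng(rec_seeds[k]),
                        eye_block_s=design.eye_block_s,
                        scout_names=scout_names,
                        subject=subject,
                        condition=condition,
                        timepoint=timepoint,
                    )
                )
                k += 1
        for eff in design.effect_edges:
            edge_rows.append(
                {
                    "subject": subject,
                    "scout_i": eff.scout_i,
                    "scout_j": eff.scout_j,
                    "delta_applied": float(
                        np.clip(eff.delta_coupling * u_by_subject[subject], 0.0, 0.95)
                    ),
                }
            )
    edges_frame = pd.DataFrame(
        edge_rows, columns=["subject", "scout_i", "scout_j", "delta_applied"]
    )
    return StudyData(
        recordings=recordings,
        ground_truth=ground_truth,
        ground_truth_edges=edges_frame,
        design=design,
    )


# ---------------------------------------------------------------------------
# behavioral data generation
# ---------------------------------------------------------------------------

_AUT_ITEMS = {
    "set_a": ["sicherheitsnadel", "stuhl", "uhr"],
    "set_b": ["autoreifen", "brille", "holzbleistift"],
}
_AFT_ITEMS = {
    "set_a": ["teppich", "schaf", "tisch"],
    "set_b": ["adler", "haus", "schere"],
}
_COMMON_USES = {
    "sicherheitsnadel": "stoff zusammenhalten",
    "stuhl": "darauf sitzen",
    "uhr": "zeit ablesen",
    "autoreifen": "auto fahren",
    "brille": "besser sehen",
    "holzbleistift": "damit schreiben",
}


@dataclass
class AnswerPool:
    """Answer vocabulary with long-tailed sampling weights and a clustered
    embedding geometry.

    ``items`` maps task -> session set -> 3 prompt items; each item owns a
    rank-ordered ``vocabulary`` with Zipf weights (``weights`` sum to 1 per
    item). Tokens carry a cluster index used for the embedding geometry and
    the flexibility link. ``synonym_groups`` lists surface-form groups that
    share one canonical token (and hence one vector).
    """

    items: dict[str, dict[str, list[str]]]
    vocabulary: dict[str, list[str]]
    weights: dict[str, np.ndarray]
    clusters: dict[str, np.ndarray]
    synonym_groups: list[list[str]] = field(default_factory=list)
    common_uses: dict[str, str] = field(default_factory=dict)
    embedding_dim: int = 50
    n_clusters: int = 8
    mean_fluency: float = 10.0

    def __post_init__(self) -> None:
        for item, w in self.weights.items():
            if len(w) == 0:
                raise ConfigurationError(f"empty vocabulary for item {item!r}")
            if not np.isclose(w.sum(), 1.0):
                raise ConfigurationError(f"weights for item {item!r} do not sum to 1")
        canon_of: dict[str, str] = {}
        for group in self.synonym_groups:
            for tok in group[1:]:
                if tok in canon_of:
                    raise ConfigurationError(f"token {tok!r} in two synonym groups")
                canon_of[tok] = group[0]
        self.synonyms = canon_of

    @classmethod
    def default(
        cls,
        vocab_size: int = 1000,
        zipf_a: float = 1.4,
        n_clusters: int = 8,
        embedding_dim: int = 50,
        synonym_every: int = 50,
        mean_fluency: float = 10.0,
    ) -> "AnswerPool":
        """The stock pool: both tasks, six German prompt items each, 1000
        candidate answers per item with Zipf(1.4) frequencies, 8 semantic
        clusters, one synonym alias per 50 vocabulary ranks."""
        items = {"AUT": dict(_AUT_ITEMS), "AFT": dict(_AFT_ITEMS)}
        vocabulary: dict[str, list[str]] = {}
        weights: dict[str, np.ndarray] = {}
        clusters: dict[str, np.ndarray] = {}
        synonym_groups: list[list[str]] = []
        for task, sets in items.items():
            for item in sets["set_a"] + sets["set_b"]:
                toks = [f"{item}-a{k:03d}" for k in range(vocab_size)]
                w = 1.0 / np.arange(1, vocab_size + 1) ** zipf_a
                vocabulary[item] = toks
                weights[item] = w / w.sum()
                clusters[item] = np.arange(vocab_size) % n_clusters
                for k in range(0, vocab_size, synonym_every):
                    synonym_groups.append([toks[k], f"{toks[k]}-syn"])
        return cls(
            items=items,
            vocabulary=vocabulary,
            weights=weights,
            clusters=clusters,
            synonym_groups=synonym_groups,
            common_uses=dict(_COMMON_USES),
            embedding_dim=embedding_dim,
            n_clusters=n_clusters,
            mean_fluency=mean_fluency,
        )

    def make_embeddings(self, rng: np.random.Generator) -> EmbeddingSpace:
        """Random unit vectors with cluster structure: tokens of one cluster
        scatter around a shared center; synonyms share the canonical vector."""
        vectors: dict[str, np.ndarray] = {}
        for item, toks in self.vocabulary.items():
            centers = rng.standard_normal((self.n_clusters, self.embedding_dim))
            centers /= np.linalg.norm(centers, axis=1, keepdims=True)
            scatter = 0.4 / np.sqrt(self.embedding_dim)
            for tok, cl in zip(toks, self.clusters[item]):
                v = centers[cl] + scatter * rng.standard_normal(self.embedding_dim)
                vectors[tok] = v / np.linalg.norm(v)
        for use in self.common_uses.values():
            for word in use.split():
                if word not in vectors:
                    v = rng.standard_normal(self.embedding_dim)
                    vectors[word] = v / np.linalg.norm(v)
        return EmbeddingSpace(vectors=vectors, synonyms=dict(self.synonyms))


def _sample_answers(
    pool: AnswerPool,
    item: str,
    rng: np.random.Generator,
    n_answers: int,
    rarity_tilt: float,
    p_switch: float,
    common_use_rate: float = 0.02,
    alias_rate: float = 0.3,
    duplicate_rate: float = 0.15,
) -> list[str]:
    """Draw one ordered answer list with ``n_answers`` *distinct* tokens.

    ``rarity_tilt`` in [0, 1] retilts the Zipf weights as w**(1 - 2*tilt):
    0 reproduces the population frequencies, 0.5 samples uniformly, and 1
    inverts the distribution toward the rare tail.
    ``p_switch`` is the probability of hopping to a new semantic
    cluster between consecutive answers. Distinct tokens are drawn without
    replacement, so the valid distinct count — fluency — does not depend on
    either knob; double listings, synonym surface forms and the prompt's
    common use are interleaved at tilt-independent rates to exercise the
    scoring rules.
    """
    toks = pool.vocabulary[item]
    w = pool.weights[item] ** (1.0 - 2.0 * rarity_tilt)
    cl = pool.clusters[item]
    cluster_ids = np.unique(cl)
    current = rng.choice(cluster_ids)
    alias_of = {g[0]: g[1] for g in pool.synonym_groups if len(g) > 1}
    answers: list[str] = []
    used: set[int] = set()
    for k in range(min(n_answers, len(toks))):
        if k > 0 and rng.random() < p_switch:
            current = rng.choice(cluster_ids)
        free = np.flatnonzero((cl == current) & ~np.isin(np.arange(len(toks)), list(used)))
        if free.size == 0:  # cluster exhausted: fall back to any unused token
            free = np.array([i for i in range(len(toks)) if i not in used])
        wk = w[free] / w[free].sum()
        pick = int(free[rng.choice(free.size, p=wk)])
        used.add(pick)
        tok = toks[pick]
        if tok in alias_of and rng.random() < alias_rate:
            tok = alias_of[tok]
        answers.append(tok)
        if rng.random() < duplicate_rate:  # double listing of an earlier answer
            answers.append(answers[int(rng.integers(len(answers)))])
    if item in pool.common_uses and rng.random() < common_use_rate:
        answers.insert(int(rng.integers(len(answers) + 1)), pool.common_uses[item])
    return answers


def gen_behavior(
    pool: AnswerPool,
    design: StudyDesign,
    ground_truth: pd.DataFrame | None = None,
    rarity_base: float = 0.45,
    rarity_gain: float = 0.30,
    switch_base: float = 0.5,
    switch_gain: float = 0.25,
) -> tuple[pd.DataFrame, EmbeddingSpace]:
    """Generate the verbal-response table and its embedding space.

    Each subject answers 3 items per task per session (item set A in the
    tRNS session, set B in sham). In the tRNS session the subject's answer
    rarity and cluster-switching rate are shifted by
    ``behavior_link * z + sqrt(1 - behavior_link^2) * noise``, where ``z``
    is the subject's standardized injected connectivity change — so the
    population correlation between connectivity change and the
    originality / flexibility change scores equals ``behavior_link`` (up to
    sampling attenuation), and is exactly zero for ``behavior_link = 0``.
    Fluency is never linked.
    """
    design.validate()
    if ground_truth is None:
        ground_truth = gen_ground_truth(design)
    _, behavior_seed, _ = _study_seeds(design)
    rng = np.random.default_rng(behavior_seed)
    emb = pool.make_embeddings(rng)

    gt = ground_truth.set_index("subject")["connectivity_change"]
    sd = gt.std(ddof=0)
    z = (gt - gt.mean()) / sd if sd > 0 else gt * 0.0
    link = design.behavior_link
    resid = float(np.sqrt(max(1.0 - link**2, 0.0)))

    rows: list[dict] = []
    for subject in design.subjects:
        shift_orig = link * z[subject] + resid * rng.standard_normal()
        shift_flex = link * z[subject] + resid * rng.standard_normal()
        for condition, item_set in zip(CONDITIONS, ("set_a", "set_b")):
            active = condition == CONDITIONS[0]
            tilt = float(np.clip(rarity_base + (rarity_gain * shift_orig if active else 0.0), 0.0, 1.0))
            p_sw = float(np.clip(switch_base + (switch_gain * shift_flex if active else 0.0), 0.05, 0.95))
            for task in pool.items:
                for item in pool.items[task][item_set]:
                    n_answers = 1 + rng.poisson(pool.mean_fluency - 1.0)
                    for idx, ans in enumerate(
                        _sample_answers(pool, item, rng, n_answers, tilt, p_sw)
                    ):
                        rows.append(
                            {
                                "participant": subject,
                                "condition": condition,
                                "task": task,
                                "item": item,
                                "answer_index": idx,
                                "answer": ans,
                            }
                        )
    return pd.DataFrame(rows), emb
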