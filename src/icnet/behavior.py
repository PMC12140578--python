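"""Divergent-thinking scoring: fluency, flexibility, originality.

Scores verbal responses from the Alternative Uses Task (AUT: unusual uses
for everyday objects) and the Associative Fluency Task (AFT: free
association to target words). Per participant, session and prompt item:

* fluency — number of valid distinct answers (duplicates never count twice;
  for the AUT the prompt's given common use is not a valid answer);
* originality — statistical infrequency: each answer scores
  ``1 - relative frequency`` of that answer in the pool of all participants'
  answers for the item (both sessions pooled), and a participant's item
  score is the mean over their valid answers;
* flexibility — semantic spread: mean pairwise cosine distance between the
  word-embedding vectors of the participant's distinct answers (a
  consecutive-pair variant is available).

Item scores are averaged over the session's three items to give the final
per-session score. Synonymous answers share one canonical token and hence
one embedding vector, so listing synonyms inflates neither flexibility nor
distinct-answer counts.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "EmbeddingSpace",
    "normalize_answer",
    "fluency",
    "originality_table",
    "participant_originality",
    "flexibility",
    "aggregate_session",
    "score_responses",
]

logger = logging.getLogger(__name__)

_PUNCT = re.compile(r"[^\w\s-]", re.UNICODE)
_WS = re.compile(r"\s+")


def normalize_answer(answer: str) -> str:
    """Casefold, strip punctuation, collapse whitespace. No stemming
    (German compounds and umlauts pass through untouched)."""
    s = unicodedata.normalize("NFC", str(answer)).casefold()
    s = _PUNCT.sub(" ", s)
    return _WS.sub(" ", s).strip()


@dataclass
class EmbeddingSpace:
    """Token -> unit-norm vector map with a synonym table.

    ``synonyms`` maps a token to its canonical token; canonical tokens map to
    themselves implicitly. All vectors are L2-normalized on construction.
    """

    vectors: dict[str, np.ndarray]
    synonyms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normed = {}
        for tok, vec in self.vectors.items():
            v = np.asarray(vec, dtype=np.float64)
            n = np.linalg.norm(v)
            if n == 0:
                raise InputError(f"zero embedding vector for token {tok!r}")
            normed[tok] = v / n
        self.vectors = normed
        for alias, canon in self.synonyms.items():
            if canon not in self.vectors and alias in self.vectors:
                raise InputError(f"synonym target {canon!r} has no vector")

    def canonical(self, token: str) -> str:
        return self.synonyms.get(token, token)

    def vector(self, answer: str) -> np.ndarray | None:
        """Embed a (normalized) answer; multi-word answers are averaged over
        their in-vocabulary tokens. Returns None when fully out-of-vocabulary."""
        whole = self.canonical(answer)
        if whole in self.vectors:
            return self.vectors[whole]
        parts = [self.canonical(t) for t in answer.split()]
        hits = [self.vectors[t] for t in parts if t in self.vectors]
        if not hits:
            return None
        v = np.mean(hits, axis=0)
        n = np.linalg.norm(v)
        return v / n if n > 0 else None

    # -- persistence: token,v1..vD CSV plus optional synonym CSV ---------
    def save(self, path: str | Path, synonym_path: str | Path | None = None) -> None:
        dim = len(next(iter(self.vectors.values())))
        frame = pd.DataFrame(
            [[tok, *vec] for tok, vec in self.vectors.items()],
            columns=["token", *[f"v{i + 1}" for i in range(dim)]],
        )
        frame.to_csv(path, index=False, float_format="%.8g")
        if synonym_path is not None:
            pd.DataFrame(
                sorted(self.synonyms.items()), columns=["token", "canonical"]
            ).to_csv(synonym_path, index=False)

    @classmethod
    def load(cls, path: str | Path, synonym_path: str | Path | None = None) -> "EmbeddingSpace":
        frame = pd.read_csv(path)
        vectors = {
            str(row[0]): np.asarray(row[1:], dtype=np.float64)
            for row in frame.itertuples(index=False)
        }
        synonyms = {}
        if synonym_path is not None:
            sf = pd.read_csv(synonym_path)
            synonyms = dict(zip(sf["token"].astype(str), sf["canonical"].astype(str)))
        return cls(vectors=vectors, synonyms=synonyms)


ValidityPredicate = Callable[[str, str], bool]


def _valid_answers(
    answers: Iterable[str],
    item: str = "",
    common_use: str | None = None,
    validity: ValidityPredicate | None = None,
    synonyms: dict[str, str] | None = None,
) -> list[str]:
    """Normalize, canonicalize, apply validity predicate, drop duplicates.

    Order is preserved. The default predicate rejects empty answers and, for
    the AUT, the prompt's given common use (an answer that merely restates
    the common use is not an alternative use).
    """
    syn = synonyms or {}
    norm_common = normalize_answer(common_use) if common_use else None
    seen: set[str] = set()
    out: list[str] = []
    for ans in answers:
        a = normalize_answer(ans)
        if not a:
            continue
        a = syn.get(a, a)
        if norm_common is not None and a == syn.get(norm_common, norm_common):
            continue
        if validity is not None and not validity(a, item):
            continue
        if a in seen:
            continue
        seen.add(a)
        out.append(a)
    return out


def fluency(
    answers: Iterable[str],
    task: str = "AUT",
    item: str = "",
    common_use: str | None = None,
    validity: ValidityPredicate | None = None,
    synonyms: dict[str, str] | None = None,
) -> int:
    """Count of valid distinct answers (double listings excluded).

    For the AFT every non-empty distinct answer is valid; for the AUT the
    item's stated common use is additionally excluded, and a custom
    ``validity(answer, item)`` predicate can tighten the rule further.
    """
    if task == "AFT":
        common_use = None
    return len(_valid_answers(answers, item, common_use, validity, synonyms))


def originality_table(pool: Iterable[str]) -> dict[str, float]:
    """Originality of each answer in a pooled sample: 1 - relative frequency.

    ``pool`` holds every (canonical) answer occurrence for one item across
    all participants and both sessions. An answer given once in a pool of N
    scores 1 - 1/N; an answer that is the whole pool scores 0.
    """
    pool = list(pool)
    if not pool:
        raise InputError("empty answer pool: originality undefined")
    counts = pd.Series(pool).value_counts()
    total = counts.sum()
    return {ans: 1.0 - cnt / total for ans, cnt in counts.items()}


def participant_originality(answers: Iterable[str], table: dict[str, float]) -> float:
    """Mean originality over a participant's valid answers for one item."""
    answers = list(answers)
    if not answers:
        return np.nan
    missing = [a for a in answers if a not in table]
    if missing:
        raise InputError(f"answers missing from the originality pool: {missing}")
    return float(np.mean([table[a] for a in answers]))


def flexibility(
    answers: Iterable[str],
    emb: EmbeddingSpace,
    variant: str = "pairwise",
) -> float:
    """Semantic spread of a distinct answer set.

    ``pairwise`` (default): mean cosine distance ``1 - cos`` over all
    unordered pairs of distinct answer vectors. ``consecutive``: mean
    distance between consecutive answers in response order. Fewer than two
    embeddable distinct answers score 0; an all-out-of-vocabulary answer set
    is a missing value (NaN, logged).
    """
    if variant not in ("pairwise", "consecutive"):
        raise InputError(f"unknown flexibility variant {variant!r}")
    vecs: list[np.ndarray] = []
    seen: set[str] = set()
    n_answers = 0
    for ans in answers:
        n_answers += 1
        canon = emb.canonical(ans)
        if canon in seen:
            continue
        v = emb.vector(ans)
        if v is None:
            continue
        seen.add(canon)
        vecs.append(v)
    if n_answers and not vecs:
        logger.warning("all %d answers out of vocabulary: flexibility missing", n_answers)
        return np.nan
    if len(vecs) < 2:
        return 0.0
    V = np.array(vecs)
    if variant == "consecutive":
        sims = np.sum(V[:-1] * V[1:], axis=1)
        return float(np.mean(1.0 - sims))
    G = V @ V.T
    iu = np.triu_indices(len(vecs), k=1)
    return float(np.mean(1.0 - G[iu]))


def aggregate_session(item_scores: pd.DataFrame) -> pd.DataFrame:
    """Average item-level scores to session level.

    Input: tidy frame with columns (participant, condition, task, item,
    fluency, originality, flexibility). Missing item scores (NaN) are
    excluded from the mean with a warning. Output: one row per
    participant x condition x task x measure.
    """
    measures = ["fluency", "originality", "flexibility"]
    needed = {"participant", "condition", "task", "item", *measures}
    if not needed.issubset(item_scores.columns):
        raise InputError(f"item scores need columns {sorted(needed)}")
    if item_scores[measures].isna().any().any():
        logger.warning("missing item-level scores: session means use available items")
    grouped = (
        item_scores.groupby(["participant", "condition", "task"])[measures]
        .mean()  # NaN-skipping mean over the session's items
        .reset_index()
    )
    return grouped.melt(
        id_vars=["participant", "condition", "task"],
        value_vars=measures,
        var_name="measure",
        value_name="value",
    )


def score_responses(
    responses: pd.DataFrame,
    emb: EmbeddingSpace,
    common_uses: dict[str, str] | None = None,
    validity: ValidityPredicate | None = None,
    flexibility_variant: str = "pairwise",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a full response table.

    Parameters
    ----------
    responses : DataFrame with columns
        (participant, condition, task, item, answer_index, answer).
    emb : EmbeddingSpace
        Embeddings used for flexibility and answer canonicalization.
    common_uses : optional mapping item -> its stated common use (AUT).

    Returns
    -------
    (session_scores, item_scores) : session-level tidy frame from
    :func:`aggregate_session` plus the underlying item-level frame.
    """
    needed = {"participant", "condition", "task", "item", "answer_index", "answer"}
    if not needed.issubset(responses.columns):
        raise InputError(f"response table needs columns {sorted(needed)}")
    common_uses = common_uses or {}
    resp = responses.sort_values("answer_index")

    # valid distinct canonical answers per participant/condition/task/item
    valid: dict[tuple, list[str]] = {}
    for key, grp in resp.groupby(["participant", "condition", "task", "item"]):
        task, item = key[2], key[3]
        valid[key] = _valid_answers(
            grp["answer"],
            item=item,
            common_use=common_uses.get(item) if task == "AUT" else None,
            validity=validity,
            synonyms=emb.synonyms,
        )

    # per-item pools across all participants and both sessions
    pools: dict[tuple, list[str]] = {}
    for (participant, condition, task, item), answers in valid.items():
        pools.setdefault((task, item), []).extend(answers)
    tables = {key: originality_table(pool) for key, pool in pools.items() if pool}

    rows = []
    for (participant, condition, task, item), answers in valid.items():
        table = tables.get((task, item), {})
        rows.append(
            {
                "participant": participant,
                "condition": condition,
                "task": task,
                "item": item,
                "fluency": len(answers),
                "originality": participant_originality(answers, table)
                if answers else np.nan,
                "flexibility": flexibility(answers, emb, variant=flexibility_variant),
            }
        )
    item_scores = pd.DataFrame(rows)
    return aggregate_session(item_scores), item_scores
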