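import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icnet import (
    EmbeddingSpace,
    aggregate_session,
    flexibility,
    fluency,
    normalize_answer,
    originality_table,
    participant_originality,
    score_responses,
)
from icnet.errors import InputError


@pytest.fixture
def emb():
    v = {
        "wolle": [1.0, 0.0, 0.0],
        "wiese": [0.0, 1.0, 0.0],
        "zaun": [0.0, 0.0, 1.0],
        "weide": [0.0, 1.0, 0.0],
    }
    return EmbeddingSpace(vectors=v, synonyms={"schafwolle": "wolle"})


class TestNormalize:
    def test_casefold_punctuation_whitespace(self):
        assert normalize_answer("  Schaf-Wolle!  ") == "schaf-wolle"
        assert normalize_answer("Die   WIESE.") == "die wiese"
        assert normalize_answer("Füße") == "füsse"  # casefold folds ß -> ss
        assert normalize_answer("Bürste") == "bürste"  # no stemming, umlauts kept


class TestFluency:
    def test_aft_double_listings_excluded(self):
        assert fluency(["wolle", "wolle", "wiese"], task="AFT") == 2

    def test_empty_answer_list(self):
        assert fluency([], task="AUT") == 0

    def test_aut_common_use_not_counted(self):
        n = fluency(
            ["zeit ablesen", "sonnenuhr", "armband"],
            task="AUT", item="uhr", common_use="Zeit ablesen",
        )
        assert n == 2

    def test_synonyms_collapse(self):
        n = fluency(["wolle", "schafwolle", "wiese"], task="AFT",
                    synonyms={"schafwolle": "wolle"})
        assert n == 2

    def test_custom_validity_predicate(self):
        valid = lambda answer, item: len(answer) > 3
        assert fluency(["ab", "wolle", "wiese"], task="AUT", validity=valid) == 2


class TestOriginality:
    def test_single_occurrence_in_pool_of_ten(self):
        pool = ["a"] * 9 + ["b"]
        table = originality_table(pool)
        assert table["b"] == pytest.approx(0.9)
        assert table["a"] == pytest.approx(0.1)

    def test_universal_answer_scores_zero(self):
        table = originality_table(["a"] * 7)
        assert table["a"] == 0.0

    def test_equal_counts_equal_scores(self):
        table = originality_table(["a", "b", "a", "b"])
        assert table["a"] == table["b"]

    def test_empty_pool_raises(self):
        with pytest.raises(InputError):
            originality_table([])

    def test_counts_complement_respects_pool_total(self, rng):
        pool = list(rng.choice(["a", "b", "c", "d"], size=50))
        table = originality_table(pool)
        # sum over answers of count * rel_freq = sum of squared proportions
        counts = pd.Series(pool).value_counts()
        recomputed = sum(c * (1 - table[a]) for a, c in counts.items())
        assert recomputed == pytest.approx(sum(c**2 for c in counts) / len(pool))

    @given(st.lists(st.sampled_from(["a", "b", "c"]), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_duplicating_an_answer_never_raises_its_originality(self, pool):
        table = originality_table(pool)
        table2 = originality_table(pool + [pool[0]])
        assert table2[pool[0]] <= table[pool[0]] + 1e-12

    def test_participant_score_is_mean_over_answers(self):
        table = {"a": 0.9, "b": 0.5}
        assert participant_originality(["a", "b"], table) == pytest.approx(0.7)
        assert np.isnan(participant_originality([], table))


class TestFlexibility:
    def test_synonymous_answers_score_zero(self, emb):
        assert flexibility(["wolle", "schafwolle"], emb) == 0.0

    def test_orthogonal_vectors_score_one(self, emb):
        assert flexibility(["wolle", "wiese"], emb) == pytest.approx(1.0)

    def test_matches_pairwise_bruteforce(self, rng):
        vecs = {f"t{i}": rng.standard_normal(6) for i in range(4)}
        space = EmbeddingSpace(vectors=vecs)
        answers = list(vecs)
        expected = []
        for i in range(4):
            for j in range(i + 1, 4):
                vi = space.vectors[f"t{i}"]
                vj = space.vectors[f"t{j}"]
                expected.append(1.0 - float(vi @ vj))
        assert flexibility(answers, space) == pytest.approx(np.mean(expected))

    def test_invariant_to_order_and_synonym_duplication(self, emb):
        base = flexibility(["wolle", "wiese", "zaun"], emb)
        shuffled = flexibility(["zaun", "wolle", "wiese"], emb)
        duplicated = flexibility(["wolle", "schafwolle", "wiese", "zaun"], emb)
        assert base == pytest.approx(shuffled)
        assert base == pytest.approx(duplicated)

    def test_single_answer_scores_zero(self, emb):
        assert flexibility(["wolle"], emb) == 0.0

    def test_all_oov_is_missing(self, emb, caplog):
        with caplog.at_level("WARNING"):
            out = flexibility(["xyz", "qqq"], emb)
        assert np.isnan(out)

    def test_multiword_answers_average_in_vocab_tokens(self, emb):
        # "wolle zaun" embeds as the mean of the two token vectors
        v = (np.array([1.0, 0, 0]) + np.array([0, 0, 1.0])) / 2
        v = v / np.linalg.norm(v)
        expected = 1.0 - float(v @ np.array([0, 1.0, 0]))
        assert flexibility(["wolle zaun", "wiese"], emb) == pytest.approx(expected)

    def test_consecutive_variant(self, emb):
        # wolle->wiese distance 1, wiese->weide distance 0 (same vector)
        out = flexibility(["wolle", "wiese", "weide"], emb, variant="consecutive")
        assert out == pytest.approx(0.5)


class TestAggregateSession:
    def _frame(self, fluencies, originalities=None, flexibilities=None):
        n = len(fluencies)
        return pd.DataFrame(
            {
                "participant": ["P1"] * n,
                "condition": ["tRNS"] * n,
                "task": ["AUT"] * n,
                "item": [f"i{k}" for k in range(n)],
                "fluency": fluencies,
                "originality": originalities or [0.5] * n,
                "flexibility": flexibilities or [0.5] * n,
            }
        )

    def test_mean_over_three_items(self):
        out = aggregate_session(self._frame([4, 6, 8]))
        assert out.set_index("measure")["value"]["fluency"] == pytest.approx(6.0)

    def test_single_item_identity(self):
        out = aggregate_session(self._frame([5]))
        assert out.set_index("measure")["value"]["fluency"] == pytest.approx(5.0)

    def test_missing_item_mean_of_available(self, caplog):
        frame = self._frame([4, 6, 8], flexibilities=[0.2, np.nan, 0.4])
        with caplog.at_level("WARNING"):
            out = aggregate_session(frame)
        assert out.set_index("measure")["value"]["flexibility"] == pytest.approx(0.3)


class TestScoreResponses:
    def test_end_to_end_toy_table(self, emb):
        rows = []
        answers = {
            ("P1", "schaf"): ["wolle", "wiese"],
            ("P2", "schaf"): ["wolle", "wolle", "zaun"],
        }
        for (p, item), ans in answers.items():
            for k, a in enumerate(ans):
                rows.append((p, "tRNS", "AFT", item, k, a))
        responses = pd.DataFrame(
            rows, columns=["participant", "condition", "task", "item",
                           "answer_index", "answer"],
        )
        session, items = score_responses(responses, emb)
        by_p = items.set_index("participant")
        assert by_p.loc["P1", "fluency"] == 2
        assert by_p.loc["P2", "fluency"] == 2  # double listing excluded
        # pool = [wolle, wiese, wolle, zaun]: wolle 0.5, wiese 0.75, zaun 0.75
        assert by_p.loc["P1", "originality"] == pytest.approx((0.5 + 0.75) / 2)
        assert by_p.loc["P2", "originality"] == pytest.approx((0.5 + 0.75) / 2)
        assert set(session["measure"]) == {"fluency", "originality", "flexibility"}

    def test_embedding_roundtrip(self, tmp_path, emb):
        emb.save(tmp_path / "emb.csv", tmp_path / "syn.csv")
        back = EmbeddingSpace.load(tmp_path / "emb.csv", tmp_path / "syn.csv")
        assert set(back.vectors) == set(emb.vectors)
        assert np.allclose(back.vectors["wolle"], emb.vectors["wolle"])
        assert back.synonyms == emb.synonyms
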