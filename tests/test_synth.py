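import numpy as np
import pandas as pd
import pytest

from icnet import (
    AnswerPool,
    CouplingEdge,
    CouplingSpec,
    EffectEdge,
    StudyDesign,
    default_base_spec,
    default_leakage,
    gen_behavior,
    gen_ground_truth,
    gen_scout_signals,
    gen_study,
)
from icnet.connectivity import ic_noise_ceiling
from icnet.errors import ConfigurationError, InputError
from icnet.pipeline import recording_band_ic


class TestGenScoutSignals:
    def test_identical_seed_bit_identical(self):
        spec = CouplingSpec(edges=[CouplingEdge(0, 1)])
        a = gen_scout_signals(spec, 4, 250.0, 10.0, seed=9)
        b = gen_scout_signals(spec, 4, 250.0, 10.0, seed=9)
        assert np.array_equal(a.data, b.data)
        assert a.eye_state_intervals == b.eye_state_intervals

    def test_eye_track_alternates_starting_open(self):
        rec = gen_scout_signals(CouplingSpec(), 2, 100.0, 120.0, seed=0, eye_block_s=35.0)
        states = [s for _, _, s in rec.eye_state_intervals]
        assert states == ["open", "closed", "open", "closed"]
        assert rec.eye_state_intervals[0][:2] == (0.0, 35.0)
        assert rec.eye_state_intervals[-1][1] == pytest.approx(120.0)

    def test_no_edges_pairs_stay_below_noise_ceiling(self):
        rec = gen_scout_signals(CouplingSpec(), 8, 250.0, 120.0, seed=3,
                                eye_block_s=35.0)
        icm = recording_band_ic(rec)
        from icnet.preprocess import average_reference, bandpass, segment_eye_state
        segs = segment_eye_state(average_reference(bandpass(rec)), "closed")
        ceiling = ic_noise_ceiling(
            250.0, [s.n_samples for s in segs], n_surrogates=150, seed=4
        )
        iu = np.triu_indices(8, 1)
        assert (icm.ic[iu] > ceiling).mean() <= 0.05  # 99% ceiling, 28 pairs

    def test_injected_edge_is_maximal_pair(self):
        spec = CouplingSpec(edges=[CouplingEdge(1, 2, 10.0, 0.9, np.pi / 2)])
        rec = gen_scout_signals(spec, 16, 250.0, 60.0, seed=5, eye_block_s=10.0)
        icm = recording_band_ic(rec)
        iu = np.triu_indices(16, 1)
        assert icm.ic[1, 2] == icm.ic[iu].max()

    def test_zero_lag_leakage_alone_produces_null_ic(self):
        # strong instantaneous mixing, no lagged coupling: IC must stay at
        # the independent-noise level on every pair
        rng = np.random.default_rng(6)
        M = np.eye(8) + 0.6 * rng.standard_normal((8, 8)) / np.sqrt(8)
        np.fill_diagonal(M, 1.0)
        rec = gen_scout_signals(CouplingSpec(leakage_mix=M), 8, 250.0, 120.0,
                                seed=7, eye_block_s=35.0)
        icm = recording_band_ic(rec)
        from icnet.preprocess import average_reference, bandpass, segment_eye_state
        segs = segment_eye_state(average_reference(bandpass(rec)), "closed")
        ceiling = ic_noise_ceiling(
            250.0, [s.n_samples for s in segs], n_surrogates=150, seed=8
        )
        iu = np.triu_indices(8, 1)
        assert (icm.ic[iu] > ceiling).mean() <= 0.05

    def test_configuration_errors(self):
        with pytest.raises(ConfigurationError):
            gen_scout_signals(CouplingSpec(edges=[CouplingEdge(0, 9)]), 4, 250.0, 10.0, 0)
        with pytest.raises(ConfigurationError):
            gen_scout_signals(
                CouplingSpec(edges=[CouplingEdge(0, 1, strength=1.5)]), 4, 250.0, 10.0, 0
            )
        with pytest.raises(ConfigurationError):
            gen_scout_signals(
                CouplingSpec(edges=[CouplingEdge(0, 1, freq_hz=200.0)]), 4, 250.0, 10.0, 0
            )
        with pytest.raises(ConfigurationError):
            bad_mix = np.full((4, 4), 0.5)
            gen_scout_signals(CouplingSpec(leakage_mix=bad_mix), 4, 250.0, 10.0, 0)
        with pytest.raises(InputError):
            gen_scout_signals(CouplingSpec(), 4, 250.0, -3.0, 0)


class TestGenStudy:
    def _design(self, **kw):
        base = dict(n_subjects=2, n_scouts=6, fs=100.0, duration_s=10.0,
                    eye_block_s=2.5, seed=77)
        base.update(kw)
        return StudyDesign(**base)

    def test_two_subjects_give_eight_recordings(self):
        study = gen_study(self._design())
        assert len(study.recordings) == 8
        cells = {(r.subject, r.condition, r.timepoint) for r in study.recordings}
        assert len(cells) == 8

    def test_same_seed_identical_dataset(self):
        s1 = gen_study(self._design())
        s2 = gen_study(self._design())
        assert np.array_equal(s1.recordings[0].data, s2.recordings[0].data)
        pd.testing.assert_frame_equal(s1.ground_truth, s2.ground_truth)

    def test_effect_edges_perturb_only_trns_post(self):
        null = gen_study(self._design())
        eff = gen_study(self._design(effect_edges=[EffectEdge(0, 1, 0.5)]))
        for r0, r1 in zip(null.recordings, eff.recordings):
            same = np.array_equal(r0.data, r1.data)
            if (r1.condition, r1.timepoint) == ("tRNS", "post"):
                assert not same
            else:
                assert same

    def test_ground_truth_lists_per_subject_magnitudes(self):
        study = gen_study(self._design(effect_edges=[EffectEdge(0, 1, 0.4),
                                                     EffectEdge(2, 3, 0.4)]))
        assert list(study.ground_truth.columns) == ["subject", "u", "connectivity_change"]
        assert len(study.ground_truth_edges) == 2 * 2  # subjects x edges
        expected = study.ground_truth_edges.groupby("subject")["delta_applied"].mean()
        gt = study.ground_truth.set_index("subject")["connectivity_change"]
        assert np.allclose(gt, expected[gt.index])

    def test_duplicate_effect_edge_rejected(self):
        with pytest.raises(ConfigurationError):
            self._design(
                effect_edges=[EffectEdge(0, 1, 0.4), EffectEdge(1, 0, 0.2)]
            ).validate()

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            self._design(n_subjects=1).validate()

    def test_save_writes_manifest_and_files(self, tmp_path):
        study = gen_study(self._design())
        manifest = study.save(tmp_path)
        assert manifest["n_recordings"] == 8
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "ground_truth.csv").exists()
        assert len(list((tmp_path / "recordings").glob("*.csv"))) == 8

    def test_recording_roundtrip(self, tmp_path):
        from icnet import ScoutRecording
        study = gen_study(self._design())
        rec = study.recordings[0]
        rec.save(tmp_path / "r0")
        back = ScoutRecording.load(tmp_path / "r0")
        assert np.allclose(back.data, rec.data, atol=1e-9)
        assert back.scout_names == rec.scout_names
        assert back.subject == rec.subject
        assert back.eye_state_intervals == rec.eye_state_intervals


class TestGenBehavior:
    def _design(self, **kw):
        base = dict(n_subjects=2, n_scouts=6, fs=100.0, duration_s=10.0,
                    eye_block_s=2.5, seed=77)
        base.update(kw)
        return StudyDesign(**base)

    def test_three_items_per_task_per_session(self):
        design = self._design()
        responses, _ = gen_behavior(AnswerPool.default(), design)
        one = responses[responses["participant"] == "S01"]
        for cond in ("tRNS", "sham"):
            per_cond = one[one["condition"] == cond]
            # 2 tasks x 3 items = 6 scored item-response sets per condition
            assert per_cond.groupby(["task", "item"]).ngroups == 6

    def test_deterministic_under_seed(self):
        design = self._design()
        r1, e1 = gen_behavior(AnswerPool.default(), design)
        r2, e2 = gen_behavior(AnswerPool.default(), design)
        pd.testing.assert_frame_equal(r1, r2)
        assert set(e1.vectors) == set(e2.vectors)
        tok = next(iter(e1.vectors))
        assert np.array_equal(e1.vectors[tok], e2.vectors[tok])

    def test_empty_vocabulary_rejected(self):
        pool = AnswerPool.default()
        pool.weights["stuhl"] = np.array([])
        with pytest.raises(ConfigurationError):
            AnswerPool(
                items=pool.items, vocabulary=pool.vocabulary, weights=pool.weights,
                clusters=pool.clusters,
            )

    def test_null_link_uncorrelated_with_ground_truth(self):
        # with behavior_link = 0 the tilt shifts are pure noise; check that
        # the generator draws them independently of the injected effect
        design = self._design(n_subjects=30, behavior_link=0.0,
                              effect_edges=[EffectEdge(0, 1, 0.4)])
        gt = gen_ground_truth(design)
        responses, emb = gen_behavior(AnswerPool.default(), design, gt)
        from icnet.behavior import score_responses
        session, _ = score_responses(responses, emb)
        aut = session[(session.task == "AUT") & (session.measure == "originality")]
        wide = aut.pivot_table(index="participant", columns="condition", values="value")
        change = wide["tRNS"] - wide["sham"]
        z = gt.set_index("subject")["connectivity_change"].loc[change.index]
        assert abs(np.corrcoef(z, change)[0, 1]) < 0.45  # ~2.4 sigma at n=30


def test_default_leakage_unit_diagonal_banded():
    L = default_leakage(6, strength=0.3, reach=2)
    assert np.allclose(np.diag(L), 1.0)
    assert L[0, 1] == pytest.approx(0.3)
    assert L[0, 2] == pytest.approx(0.09)
    assert L[0, 3] == 0.0
    spec = default_base_spec(6)
    spec.validate(6, 250.0)
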