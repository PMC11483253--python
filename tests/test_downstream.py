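import numpy as np
import pytest

import temporalmatch as tm
from temporalmatch.downstream import (OutcomeHead, _EmbeddingCache,
                                      build_patient_representation)

CODES = tuple(f"w000{i} w000{(i + 1) % 10}" for i in range(10))


@pytest.fixture(scope="module")
def patients():
    cfg = tm.SyntheticPatientConfig(
        n_patients=120, code_vocab=CODES, outcome_kind="binary",
        coefficient_map=((CODES[0], 3.0),), intercept=-1.0, seed=4)
    return tm.generate_patients(cfg)


@pytest.fixture(scope="module")
def regression_patients():
    cfg = tm.SyntheticPatientConfig(
        n_patients=80, code_vocab=CODES, outcome_kind="continuous",
        coefficient_map=((CODES[0], 2.0),), intercept=1.0, noise_sd=0.5,
        seed=5)
    return tm.generate_patients(cfg)


class TestRepresentation:
    def test_length_formula_classification(self, trained_tiny_encoder,
                                           patients):
        cfg = tm.HeadConfig(task="classification", lstm_hidden=8, mlp_hidden=8)
        head = OutcomeHead(cfg, d_embed=16, n_sequences=3, n_static=2)
        rep = build_patient_representation(trained_tiny_encoder, patients[0],
                                           head)
        assert rep.shape == (3 * 8 + 2,)

    def test_length_formula_regression_includes_primary_diagnosis(
            self, trained_tiny_encoder, regression_patients):
        cfg = tm.HeadConfig(task="regression", lstm_hidden=8, mlp_hidden=8)
        head = OutcomeHead(cfg, d_embed=16, n_sequences=3, n_static=2)
        rep = build_patient_representation(trained_tiny_encoder,
                                           regression_patients[0], head)
        assert rep.shape == (3 * 8 + 16 + 2,)

    def test_identical_records_get_identical_representations(
            self, trained_tiny_encoder, patients):
        cfg = tm.HeadConfig(task="classification", lstm_hidden=8, mlp_hidden=8,
                            seed=3)
        head = OutcomeHead(cfg, d_embed=16, n_sequences=3, n_static=2)
        a = build_patient_representation(trained_tiny_encoder, patients[0], head)
        b = build_patient_representation(trained_tiny_encoder, patients[0], head)
        assert np.array_equal(a, b)

    def test_empty_sequence_aggregates_to_zero_vector(self,
                                                      trained_tiny_encoder):
        record = tm.PatientRecord(
            patient_id="p", group="F", static_features=[50.0, 1.0],
            sequences={"previous_diagnoses": [], "current_diagnoses": [CODES[0]],
                       "medications": [CODES[1]]},
            outcome=1.0)
        cfg = tm.HeadConfig(task="classification", lstm_hidden=8, mlp_hidden=8)
        head = OutcomeHead(cfg, d_embed=16, n_sequences=3, n_static=2)
        rep = build_patient_representation(trained_tiny_encoder, record, head)
        # sequences aggregate in sorted name order, so the empty
        # previous_diagnoses occupies the third lstm_hidden block
        assert np.all(rep[16:24] == 0.0)
        assert not np.all(rep[:8] == 0.0)

    def test_single_step_sequence_equals_one_lstm_step(self,
                                                       trained_tiny_encoder):
        cfg = tm.HeadConfig(task="classification", lstm_hidden=8, mlp_hidden=8,
                            seed=1)
        head = OutcomeHead(cfg, d_embed=16, n_sequences=1, n_static=0)
        cache = _EmbeddingCache(trained_tiny_encoder)
        emb = cache(CODES[2])[None, None, :]
        from temporalmatch.nn import Tensor
        from temporalmatch.nn import autodiff as ad
        with ad.no_grad():
            out = head.lstm(Tensor(emb), np.array([[True]])).data
        rec = tm.PatientRecord(patient_id="p", group="M", static_features=[],
                               sequences={"s": [CODES[2]]}, outcome=0.0)
        rep = build_patient_representation(trained_tiny_encoder, rec, head,
                                           _cache=cache)
        np.testing.assert_allclose(rep[:8], out[0], rtol=1e-6)


class TestTrainHead:
    def test_constant_regression_targets_are_fit(self, trained_tiny_encoder,
                                                 regression_patients):
        records = [tm.PatientRecord(r.patient_id, r.group, r.static_features,
                                    r.sequences, 2.0)
                   for r in regression_patients]
        cfg = tm.HeadConfig(task="regression", lstm_hidden=8, mlp_hidden=8,
                            epochs=60, lr=1e-2, seed=0)
        trained = tm.train_outcome_head(trained_tiny_encoder, records, cfg)
        assert trained.history[-1] < 0.05
        preds = trained.scores(trained_tiny_encoder, records[:10])
        assert np.abs(preds - 2.0).max() < 0.5

    def test_encoder_is_frozen_during_training(self, trained_tiny_encoder,
                                               patients):
        before = trained_tiny_encoder.checksum()
        cfg = tm.HeadConfig(task="classification", lstm_hidden=8, mlp_hidden=8,
                            epochs=1, lr=1e-3, seed=0)
        tm.train_outcome_head(trained_tiny_encoder, patients, cfg)
        assert trained_tiny_encoder.checksum() == before

    def test_task_outcome_mismatch_rejected(self, trained_tiny_encoder,
                                            regression_patients):
        cfg = tm.HeadConfig(task="classification", epochs=1)
        with pytest.raises(ValueError, match="binary"):
            tm.train_outcome_head(trained_tiny_encoder, regression_patients,
                                  cfg)

    def test_defaults_follow_task(self):
        assert tm.HeadConfig(task="regression").epochs == 10
        assert tm.HeadConfig(task="regression").lr == pytest.approx(1e-3)
        assert tm.HeadConfig(task="classification").epochs == 4
        assert tm.HeadConfig(task="classification").lr == pytest.approx(1e-5)


class TestEvaluateByGroup:
    def _trained(self, encoder, records, seed=0):
        cfg = tm.HeadConfig(task="classification", lstm_hidden=8, mlp_hidden=8,
                            epochs=2, lr=1e-3, seed=seed)
        return tm.train_outcome_head(encoder, records, cfg)

    def test_single_group_overall_equals_group_metric(self,
                                                      trained_tiny_encoder,
                                                      patients):
        one_group = [tm.PatientRecord(r.patient_id, "F", r.static_features,
                                      r.sequences, r.outcome)
                     for r in patients[:40]]
        if len({r.outcome for r in one_group}) < 2:
            one_group[0] = tm.PatientRecord("px", "F", [50.0, 1.0],
                                            one_group[0].sequences,
                                            1.0 - one_group[0].outcome)
        trained = self._trained(trained_tiny_encoder, one_group)
        report = tm.evaluate_by_group(trained, trained_tiny_encoder, one_group,
                                      n_resamples=50, seed=1)
        assert report.by_group["F"][0] == pytest.approx(report.overall[0])

    def test_group_maes_recombine_to_overall(self, trained_tiny_encoder,
                                             regression_patients):
        cfg = tm.HeadConfig(task="regression", lstm_hidden=8, mlp_hidden=8,
                            epochs=2, lr=1e-3, seed=0)
        trained = tm.train_outcome_head(trained_tiny_encoder,
                                        regression_patients, cfg)
        report = tm.evaluate_by_group(trained, trained_tiny_encoder,
                                      regression_patients, n_resamples=50,
                                      seed=2)
        weighted = sum(report.by_group[g][0] * report.n_by_group[g]
                       for g in report.by_group)
        total = sum(report.n_by_group[g] for g in report.by_group)
        assert report.overall[0] == pytest.approx(weighted / total, rel=1e-9)

    def test_perfect_scores_give_unit_auc_in_every_group(self, patients,
                                                         trained_tiny_encoder):
        trained = self._trained(trained_tiny_encoder, patients)

        class Oracle:
            head = trained.head
            group_map = trained.group_map
            seq_names = trained.seq_names
            static_scale = trained.static_scale

            def scores(self, encoder, records, cache=None):
                return np.array([r.outcome for r in records])

        report = tm.evaluate_by_group(Oracle(), trained_tiny_encoder, patients,
                                      n_resamples=50, seed=3)
        for g, (point, lo, hi) in report.by_group.items():
            assert point == 1.0

    def test_unknown_group_field_rejected(self, trained_tiny_encoder,
                                          patients):
        trained = self._trained(trained_tiny_encoder, patients[:40])
        with pytest.raises(ValueError):
            tm.evaluate_by_group(trained, trained_tiny_encoder, patients[:40],
                                 group_field="ethnicity")
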