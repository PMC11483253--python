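import numpy as np
import pytest

import temporalmatch as tm
from temporalmatch.nn import Adam
from temporalmatch.training import adversarial_step, _train_rngs


@pytest.fixture(scope="module")
def anchor(tiny_corpus, tiny_encoder_config, tiny_tokenizer):
    return tm.train_anchor(tiny_corpus, tiny_encoder_config, epochs=1,
                           tokenizer=tiny_tokenizer, lr=3e-4)


def _params(encoder):
    return [p.data.copy() for p in encoder.parameters()]


class TestDegenerateEquivalence:
    def test_zero_lambdas_reproduce_mlm_baseline_exactly(
            self, tiny_corpus, tiny_encoder_config, tiny_tokenizer):
        cfg = tm.AdversarialTrainConfig(lambda_adv=0.0, lambda_anchor=0.0,
                                        epochs=2, seed=13, batch_size=8,
                                        lr_generator=3e-4, m=6)
        bundle = tm.train_adversarial(tiny_corpus, None, cfg,
                                      encoder_cfg=tiny_encoder_config,
                                      tokenizer=tiny_tokenizer)
        baseline = tm.train_mlm_baseline(tiny_corpus, tiny_encoder_config,
                                         epochs=2, tokenizer=tiny_tokenizer,
                                         batch_size=8, lr=3e-4, seed=13)
        for pg, pb in zip(bundle.generator.parameters(), baseline.parameters()):
            assert np.array_equal(pg.data, pb.data)

    def test_zero_epochs_returns_initialization(self, tiny_corpus,
                                                tiny_encoder_config,
                                                tiny_tokenizer, anchor):
        cfg = tm.AdversarialTrainConfig(epochs=0, seed=1, m=6)
        bundle = tm.train_adversarial(tiny_corpus, anchor, cfg,
                                      encoder_cfg=tiny_encoder_config,
                                      tokenizer=tiny_tokenizer)
        fresh = tm.TransformerEncoder(tiny_encoder_config, tiny_tokenizer)
        for pg, pf in zip(bundle.generator.parameters(), fresh.parameters()):
            assert np.array_equal(pg.data, pf.data)
        assert bundle.history == []


class TestAdversarialStep:
    def test_composite_is_convex_combination_of_logged_terms(
            self, tiny_corpus, tiny_encoder_config, tiny_tokenizer, anchor):
        cfg = tm.AdversarialTrainConfig(lambda_adv=0.3, lambda_anchor=0.3,
                                        epochs=1, seed=5, batch_size=8,
                                        lr_generator=3e-4,
                                        lr_discriminator=3e-4, m=6)
        bundle = tm.train_adversarial(tiny_corpus, anchor, cfg,
                                      encoder_cfg=tiny_encoder_config,
                                      tokenizer=tiny_tokenizer)
        assert len(bundle.history) == 1
        for rec in bundle.history[0]["batches"]:
            expected = (0.4 * rec["mlm"] + 0.3 * rec["adv_flip"]
                        + 0.3 * rec["anchor"])
            assert rec["composite"] == pytest.approx(expected, rel=1e-5)
            for v in rec.values():
                assert np.isfinite(v)

    def test_mlm_weight_follows_lambdas(self):
        cfg = tm.AdversarialTrainConfig(lambda_adv=0.3, lambda_anchor=0.3)
        assert cfg.mlm_weight == pytest.approx(0.4)
        with pytest.raises(ValueError):
            tm.AdversarialTrainConfig(lambda_adv=0.7, lambda_anchor=0.6)

    def test_discriminator_update_reduces_its_loss_on_separable_batch(
            self, tiny_corpus, tiny_encoder_config, tiny_tokenizer, anchor):
        batch = ([d for d in tiny_corpus
                  if d.temporal_label == tm.TemporalLabel.OLD][:4]
                 + [d for d in tiny_corpus
                    if d.temporal_label == tm.TemporalLabel.NEW][:4])
        cfg = tm.AdversarialTrainConfig(lambda_adv=0.3, lambda_anchor=0.3,
                                        epochs=1, seed=5, batch_size=8,
                                        lr_discriminator=1e-2, m=6)
        gen = tm.TransformerEncoder(tiny_encoder_config, tiny_tokenizer)
        disc = tm.TemporalDiscriminator(cfg.m, tiny_encoder_config.hidden_size,
                                        seed=2)
        bundle = tm.AdversarialBundle(generator=gen, discriminator=disc,
                                      anchor=anchor, config=cfg)
        opt_g = Adam(gen.parameters(), lr=0.0)
        opt_d = Adam(disc.parameters(), lr=cfg.lr_discriminator)
        _, mask_rng = _train_rngs(cfg.seed)
        first = adversarial_step(bundle, batch, opt_g, opt_d, mask_rng)
        second = adversarial_step(bundle, batch, opt_g, opt_d, mask_rng)
        assert second["adv"] <= first["adv"] + 1e-6

    def test_unlabeled_document_rejected(self, tiny_corpus,
                                         tiny_encoder_config, tiny_tokenizer,
                                         anchor):
        bad = tm.Document(id="x", year=2014, text="w0001 w0002.")
        bad = tm.segment_sentences(bad)
        cfg = tm.AdversarialTrainConfig(epochs=1, m=6)
        gen = tm.TransformerEncoder(tiny_encoder_config, tiny_tokenizer)
        disc = tm.TemporalDiscriminator(cfg.m, tiny_encoder_config.hidden_size)
        bundle = tm.AdversarialBundle(generator=gen, discriminator=disc,
                                      anchor=anchor, config=cfg)
        with pytest.raises(ValueError, match="temporal label"):
            adversarial_step(bundle, [bad], Adam(gen.parameters()),
                             Adam(disc.parameters()),
                             np.random.default_rng(0))


class TestTrainAdversarial:
    def test_single_temporal_class_rejected(self, tiny_corpus,
                                            tiny_encoder_config,
                                            tiny_tokenizer, anchor):
        only_old = [d for d in tiny_corpus
                    if d.temporal_label == tm.TemporalLabel.OLD]
        cfg = tm.AdversarialTrainConfig(epochs=1, m=6)
        with pytest.raises(ValueError, match="OLD and NEW"):
            tm.train_adversarial(only_old, anchor, cfg,
                                 encoder_cfg=tiny_encoder_config,
                                 tokenizer=tiny_tokenizer)

    def test_missing_anchor_rejected(self, tiny_corpus, tiny_encoder_config,
                                     tiny_tokenizer):
        cfg = tm.AdversarialTrainConfig(lambda_anchor=0.3, epochs=1, m=6)
        with pytest.raises(ValueError, match="anchor"):
            tm.train_adversarial(tiny_corpus, None, cfg,
                                 encoder_cfg=tiny_encoder_config,
                                 tokenizer=tiny_tokenizer)

    def test_seeded_determinism_end_to_end(self, tiny_corpus,
                                           tiny_encoder_config,
                                           tiny_tokenizer, anchor):
        cfg = tm.AdversarialTrainConfig(epochs=1, seed=3, batch_size=8,
                                        lr_generator=3e-4,
                                        lr_discriminator=3e-4, m=6)
        runs = [tm.train_adversarial(tiny_corpus, anchor, cfg,
                                     encoder_cfg=tiny_encoder_config,
                                     tokenizer=tiny_tokenizer)
                for _ in range(2)]
        for pa, pb in zip(runs[0].generator.parameters(),
                          runs[1].generator.parameters()):
            assert np.array_equal(pa.data, pb.data)
        assert (runs[0].history[0]["composite"]
                == runs[1].history[0]["composite"])

    def test_history_length_matches_epochs(self, tiny_corpus,
                                           tiny_encoder_config,
                                           tiny_tokenizer, anchor):
        cfg = tm.AdversarialTrainConfig(epochs=3, seed=3, batch_size=16,
                                        lr_generator=3e-4, m=6)
        bundle = tm.train_adversarial(tiny_corpus, anchor, cfg,
                                      encoder_cfg=tiny_encoder_config,
                                      tokenizer=tiny_tokenizer)
        assert len(bundle.history) == 3


class TestMlmBaseline:
    def test_zero_epochs_identity(self, tiny_corpus, tiny_encoder_config,
                                  tiny_tokenizer):
        enc = tm.train_mlm_baseline(tiny_corpus, tiny_encoder_config, 0,
                                    tokenizer=tiny_tokenizer)
        fresh = tm.TransformerEncoder(tiny_encoder_config, tiny_tokenizer)
        for pa, pb in zip(enc.parameters(), fresh.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_training_loss_decreases_overall(self, tiny_corpus,
                                             tiny_encoder_config,
                                             tiny_tokenizer):
        _, history = tm.train_mlm_baseline(
            tiny_corpus, tiny_encoder_config, 4, tokenizer=tiny_tokenizer,
            lr=3e-4, return_history=True)
        assert history[-1] < history[0]
        for early, late in zip(history, history[1:]):
            assert late <= early * 1.05  # small fluctuation tolerance

    def test_empty_corpus_rejected(self, tiny_encoder_config):
        with pytest.raises(ValueError):
            tm.train_mlm_baseline([], tiny_encoder_config, 1)
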