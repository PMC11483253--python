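import numpy as np
import pytest

import temporalmatch as tm


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small drifted two-period corpus, labeled and segmented."""
    cfg = tm.DriftCorpusConfig(vocab_size=80, n_docs_old=30, n_docs_new=30,
                               sentences_per_doc=(3, 5),
                               tokens_per_sentence=(5, 8), n_topics=4, seed=42)
    docs = tm.generate_drift_corpus(cfg)
    docs = tm.assign_temporal_labels(docs, tm.TemporalSplitConfig())
    return [tm.segment_sentences(d) for d in docs]


@pytest.fixture(scope="session")
def tiny_tokenizer(tiny_corpus):
    return tm.WhitespaceTokenizer.from_texts(d.text for d in tiny_corpus)


@pytest.fixture(scope="session")
def tiny_encoder_config():
    return tm.EncoderConfig(n_layers=2, hidden_size=16, n_heads=2,
                            max_tokens=24, seed=7)


@pytest.fixture(scope="session")
def tiny_encoder(tiny_encoder_config, tiny_tokenizer):
    """Untrained (randomly initialized) encoder over the tiny vocabulary."""
    return tm.TransformerEncoder(tiny_encoder_config, tiny_tokenizer)


@pytest.fixture(scope="session")
def trained_tiny_encoder(tiny_corpus, tiny_encoder_config, tiny_tokenizer):
    """Encoder briefly MLM-trained on the tiny corpus."""
    return tm.train_mlm_baseline(tiny_corpus, tiny_encoder_config, epochs=2,
                                 tokenizer=tiny_tokenizer, lr=3e-4)
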