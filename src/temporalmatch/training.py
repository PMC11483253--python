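"""Joint adversarial training loop (temporal distribution matching) and the
MLM-only baseline trainer.

Each batch performs two sub-updates in order:

1. **Discriminator update** — the linear temporal discriminator is trained
   to separate old from new documents from the current generator's abstract
   embeddings (generator gradients blocked).
2. **Generator update** — the encoder minimizes the composite objective

   ``(1 - lambda_adv - lambda_anchor) * L_MLM
     + lambda_adv * L_adv_flip + lambda_anchor * L_A``

   where ``L_adv_flip`` is binary cross-entropy against *flipped* temporal
   labels (the non-saturating surrogate for maximizing the discriminator
   loss; a negated-BCE mode is available via config) and ``L_A`` is the
   Frobenius distance to the frozen anchor's embedding, summed per document
   and averaged over the batch. Discriminator parameters are frozen during
   this sub-update.

Both components use Adam with a constant learning rate (default 2e-5).
Training is deterministic given the config seed: the shuffle and masking
random streams are derived from it, and all batch operations are ordered.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .adversary import AnchorModel, TemporalDiscriminator
from .corpus import Document, TemporalLabel, segment_sentences
from .encoder import (EncoderConfig, TransformerEncoder, WhitespaceTokenizer,
                      mask_tokens, mlm_loss, pad_batch)
from .nn import Adam, Tensor
from .nn import autodiff as ad


class MlmScope(Enum):
    LABELED_ONLY = "labeled_only"
    ALL = "all"


@dataclass(frozen=True)
class AdversarialTrainConfig:
    """Hyperparameters of the distribution-matching loop.

    ``lambda_adv`` and ``lambda_anchor`` weight the adversarial and anchor
    terms; the MLM weight is ``1 - lambda_adv - lambda_anchor`` and must be
    non-negative. ``period_sample_weights`` (old, new) rescales per-document
    contributions to the adversarial and anchor terms, exposing the
    old-vs-new weighting ablation as a knob; the default 1:1 is neutral.
    """

    lambda_adv: float = 0.3
    lambda_anchor: float = 0.3
    epochs: int = 20
    lr_generator: float = 2e-5
    lr_discriminator: float = 2e-5
    batch_size: int = 16
    seed: int = 0
    mlm_corpus_scope: MlmScope = MlmScope.LABELED_ONLY
    period_sample_weights: tuple[float, float] = (1.0, 1.0)
    mask_rate: float = 0.15
    adversarial_mode: str = "label_flip"  # or "negate"
    m: int = 20

    def __post_init__(self):
        if not (0.0 <= self.lambda_adv <= 1.0 and 0.0 <= self.lambda_anchor <= 1.0):
            raise ValueError("lambda weights must lie in [0, 1]")
        if self.lambda_adv + self.lambda_anchor > 1.0 + 1e-12:
            raise ValueError("lambda_adv + lambda_anchor must not exceed 1")
        if self.adversarial_mode not in ("label_flip", "negate"):
            raise ValueError("adversarial_mode must be 'label_flip' or 'negate'")

    @property
    def mlm_weight(self) -> float:
        return 1.0 - self.lambda_adv - self.lambda_anchor


@dataclass
class AdversarialBundle:
    """Generator + discriminator + frozen anchor with training history."""

    generator: TransformerEncoder
    discriminator: TemporalDiscriminator
    anchor: AnchorModel | None
    config: AdversarialTrainConfig
    history: list[dict] = field(default_factory=list)


# -- internal helpers ------------------------------------------------------

def _train_rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    shuffle_ss, mask_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(shuffle_ss), np.random.default_rng(mask_ss)


def _prepare(docs: list[Document], tokenizer: WhitespaceTokenizer,
             max_tokens: int) -> list[list[np.ndarray]]:
    """Tokenize each document's sentences (segmenting first if needed),
    truncating to ``max_tokens`` so masking positions stay valid."""
    prepared = []
    for doc in docs:
        if not doc.sentences:
            doc = segment_sentences(doc)
        seqs = []
        for sent in doc.sentences:
            ids = tokenizer.encode(sent)
            if len(ids) > max_tokens:
                ids = np.concatenate([ids[: max_tokens - 1], ids[-1:]])
            seqs.append(ids)
        prepared.append(seqs)
    return prepared


def _mlm_batch_loss(encoder: TransformerEncoder, seq_lists: list[list[np.ndarray]],
                    mask_rate: float, rng: np.random.Generator) -> Tensor:
    """Corrupt every sentence of the batch docs and return the MLM loss."""
    corrupted, rows, cols, targets = [], [], [], []
    for seqs in seq_lists:
        for seq in seqs:
            corr, pos, tgt = mask_tokens(seq, mask_rate, rng,
                                         encoder.tokenizer.vocab_size)
            idx = len(corrupted)
            corrupted.append(corr)
            rows.extend([idx] * len(pos))
            cols.extend(pos.tolist())
            targets.extend(tgt.tolist())
    ids, attn = pad_batch(corrupted, encoder.config.max_tokens)
    positions = (np.asarray(rows, dtype=np.int64), np.asarray(cols, dtype=np.int64))
    return mlm_loss(encoder, ids, attn, positions, np.asarray(targets, dtype=np.int64))


def _abstract_flat_batch(encoder: TransformerEncoder,
                         seq_lists: list[list[np.ndarray]], m: int) -> Tensor:
    """Differentiable [B, m*d] flattened abstract embeddings for batch docs.

    Only the first ``m`` sentences per document are embedded; missing rows
    point at an all-zero row, reproducing zero padding inside the graph.
    """
    d = encoder.config.hidden_size
    flat_seqs: list[np.ndarray] = []
    counts = []
    for seqs in seq_lists:
        take = seqs[:m]
        counts.append(len(take))
        flat_seqs.extend(take)
    ids, attn = pad_batch(flat_seqs, encoder.config.max_tokens)
    hidden = encoder.hidden_states(ids, attn)
    pooled = encoder.pool(hidden, ids)  # [n_sent, d]
    zero_row = Tensor(np.zeros((1, d), dtype=np.float32))
    table = ad.concat([pooled, zero_row], axis=0)
    n_total = len(flat_seqs)
    index = np.full((len(seq_lists), m), n_total, dtype=np.int64)
    offset = 0
    for i, k in enumerate(counts):
        index[i, :k] = np.arange(offset, offset + k)
        offset += k
    gathered = ad.gather_rows(table, index)  # [B, m, d]
    return ad.reshape(gathered, (len(seq_lists), m * d))


def _anchor_flats(anchor: AnchorModel, docs: list[Document],
                  tokenizer: WhitespaceTokenizer, m: int,
                  chunk: int = 64) -> dict[str, np.ndarray]:
    """Precompute frozen-anchor flattened embeddings for every document."""
    flats: dict[str, np.ndarray] = {}
    with ad.no_grad():
        for start in range(0, len(docs), chunk):
            sub = docs[start:start + chunk]
            seq_lists = _prepare(sub, tokenizer, anchor.encoder.config.max_tokens)
            flat = _abstract_flat_batch(anchor.encoder, seq_lists, m)
            for doc, row in zip(sub, flat.data):
                flats[doc.id] = row.copy()
    return flats


def _frobenius_term(gen_flat: Tensor, anchor_flat: np.ndarray,
                    weights: np.ndarray | None) -> Tensor:
    """Per-document Frobenius distance to the anchor, averaged over batch."""
    diff = gen_flat - Tensor(anchor_flat)
    sq = ad.tsum(diff * diff, axis=1)
    frob = ad.power(sq + Tensor(np.float32(1e-12)), 0.5)
    if weights is not None:
        w = weights / weights.mean()
        frob = frob * Tensor(w.astype(np.float32))
    return ad.tmean(frob)


def _clone_encoder(enc: TransformerEncoder) -> TransformerEncoder:
    new = TransformerEncoder(enc.config, enc.tokenizer)
    for p_new, p_old in zip(new.parameters(), enc.parameters()):
        p_new.data = p_old.data.copy()
    return new


# -- spec operations -------------------------------------------------------

def adversarial_step(bundle: AdversarialBundle, batch: list[Document],
                     opt_gen: Adam, opt_disc: Adam,
                     mask_rng: np.random.Generator,
                     anchor_flats: dict[str, np.ndarray] | None = None,
                     seq_lists: list[list[np.ndarray]] | None = None) -> dict:
    """One joint training step on a batch of temporally labeled documents.

    Returns the per-batch loss components ``{"mlm", "adv", "adv_flip",
    "anchor", "composite"}`` (absent terms recorded as 0.0).
    """
    cfg = bundle.config
    gen = bundle.generator
    for doc in batch:
        if doc.temporal_label == TemporalLabel.UNLABELED:
            raise ValueError(f"document {doc.id!r} has no temporal label")
    if seq_lists is None:
        seq_lists = _prepare(batch, gen.tokenizer, gen.config.max_tokens)
    labels = np.array([doc.temporal_label.value for doc in batch], dtype=np.float32)
    w_old, w_new = cfg.period_sample_weights
    doc_weights = np.where(labels == 0.0, w_old, w_new).astype(np.float32)
    if w_old == w_new == 1.0:
        doc_weights_or_none = None
    else:
        doc_weights_or_none = doc_weights

    use_adv = cfg.lambda_adv > 0.0
    use_anchor = cfg.lambda_anchor > 0.0
    record = {"mlm": 0.0, "adv": 0.0, "adv_flip": 0.0, "anchor": 0.0}

    gen_flat = None
    if use_adv or use_anchor:
        gen_flat = _abstract_flat_batch(gen, seq_lists, cfg.m)

    # 1) discriminator sub-update (generator gradients blocked via .data)
    if use_adv:
        disc_in = Tensor(gen_flat.data)
        logits = bundle.discriminator.logits(disc_in)
        disc_loss = ad.bce_with_logits(logits, labels, doc_weights_or_none)
        opt_disc.zero_grad()
        disc_loss.backward()
        opt_disc.step()
        record["adv"] = disc_loss.item()

    # 2) generator sub-update against the updated, frozen discriminator
    terms = []
    mlm = _mlm_batch_loss(gen, seq_lists, cfg.mask_rate, mask_rng)
    record["mlm"] = mlm.item()
    if cfg.mlm_weight > 0.0:
        terms.append(Tensor(np.float32(cfg.mlm_weight)) * mlm)
    if use_adv:
        for p in bundle.discriminator.parameters():
            p.requires_grad = False
        logits = bundle.discriminator.logits(gen_flat)
        if cfg.adversarial_mode == "label_flip":
            adv_term = ad.bce_with_logits(logits, 1.0 - labels, doc_weights_or_none)
        else:
            adv_term = Tensor(np.float32(-1.0)) * ad.bce_with_logits(
                logits, labels, doc_weights_or_none)
        record["adv_flip"] = adv_term.item()
        terms.append(Tensor(np.float32(cfg.lambda_adv)) * adv_term)
    if use_anchor:
        if anchor_flats is None:
            anchor_flats = _anchor_flats(bundle.anchor, batch, gen.tokenizer, cfg.m)
        anc = np.stack([anchor_flats[doc.id] for doc in batch])
        anchor_term = _frobenius_term(gen_flat, anc, doc_weights_or_none)
        record["anchor"] = anchor_term.item()
        terms.append(Tensor(np.float32(cfg.lambda_anchor)) * anchor_term)

    composite = terms[0]
    for t in terms[1:]:
        composite = composite + t
    opt_gen.zero_grad()
    composite.backward()
    opt_gen.step()
    if use_adv:
        for p in bundle.discriminator.parameters():
            p.requires_grad = True
    record["composite"] = composite.item()
    return record


def train_adversarial(corpus: list[Document], anchor: AnchorModel | None,
                      cfg: AdversarialTrainConfig,
                      encoder_cfg: EncoderConfig | None = None,
                      tokenizer: WhitespaceTokenizer | None = None,
                      generator_init: TransformerEncoder | None = None,
                      ) -> AdversarialBundle:
    """Train a temporally matched encoder on a labeled corpus.

    ``corpus`` must contain at least one OLD and one NEW document unless
    both adversarial weights are zero. The generator starts from
    ``generator_init`` (copied) or a fresh seeded encoder. The anchor is
    required when ``lambda_anchor > 0`` and must share the generator's
    architecture and tokenizer.
    """
    labeled = [d for d in corpus if d.temporal_label != TemporalLabel.UNLABELED]
    n_old = sum(d.temporal_label == TemporalLabel.OLD for d in labeled)
    n_new = len(labeled) - n_old
    if cfg.lambda_adv > 0.0 and (n_old == 0 or n_new == 0):
        raise ValueError("adversarial training needs both OLD and NEW documents")
    if cfg.lambda_anchor > 0.0 and anchor is None:
        raise ValueError("lambda_anchor > 0 requires an anchor model")

    if generator_init is not None:
        generator = _clone_encoder(generator_init)
    else:
        if tokenizer is None:
            if anchor is not None:
                tokenizer = anchor.encoder.tokenizer
            else:
                tokenizer = WhitespaceTokenizer.from_texts(d.text for d in corpus)
        if encoder_cfg is None:
            encoder_cfg = anchor.encoder.config if anchor is not None else EncoderConfig()
        generator = TransformerEncoder(encoder_cfg, tokenizer)
    gcfg = generator.config
    if anchor is not None and anchor.encoder.config.hidden_size != gcfg.hidden_size:
        raise ValueError("anchor and generator hidden sizes differ")

    disc = TemporalDiscriminator(cfg.m, gcfg.hidden_size, seed=cfg.seed)
    bundle = AdversarialBundle(generator=generator, discriminator=disc,
                               anchor=anchor, config=cfg, history=[])
    opt_gen = Adam(generator.parameters(), lr=cfg.lr_generator)
    opt_disc = Adam(disc.parameters(), lr=cfg.lr_discriminator)

    scope_docs = labeled if cfg.mlm_corpus_scope == MlmScope.LABELED_ONLY else list(corpus)
    seq_lists = _prepare(scope_docs, generator.tokenizer, gcfg.max_tokens)
    anchor_flats = None
    if cfg.lambda_anchor > 0.0:
        anchor.verify_frozen()
        anchor_flats = _anchor_flats(anchor, scope_docs, generator.tokenizer, cfg.m)

    shuffle_rng, mask_rng = _train_rngs(cfg.seed)
    n = len(scope_docs)
    for _epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        batch_records = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = [scope_docs[i] for i in idx]
            batch_seqs = [seq_lists[i] for i in idx]
            if cfg.lambda_adv == 0.0 and cfg.lambda_anchor == 0.0:
                rec = _mlm_only_step(generator, batch_seqs, cfg.mask_rate,
                                     mask_rng, opt_gen)
            else:
                rec = adversarial_step(bundle, batch, opt_gen, opt_disc,
                                       mask_rng, anchor_flats, batch_seqs)
            batch_records.append(rec)
        bundle.history.append(_summarize_epoch(batch_records))
    return bundle


def _mlm_only_step(encoder: TransformerEncoder, seq_lists, mask_rate: float,
                   mask_rng: np.random.Generator, opt: Adam) -> dict:
    loss = _mlm_batch_loss(encoder, seq_lists, mask_rate, mask_rng)
    opt.zero_grad()
    loss.backward()
    opt.step()
    value = loss.item()
    return {"mlm": value, "adv": 0.0, "adv_flip": 0.0, "anchor": 0.0,
            "composite": value}


def _summarize_epoch(batch_records: list[dict]) -> dict:
    keys = ("mlm", "adv", "adv_flip", "anchor", "composite")
    summary = {k: float(np.mean([r[k] for r in batch_records])) for k in keys}
    summary["batches"] = batch_records
    return summary


def train_mlm_baseline(corpus: list[Document], cfg: EncoderConfig, epochs: int,
                       tokenizer: WhitespaceTokenizer | None = None,
                       batch_size: int = 16, lr: float = 2e-5,
                       mask_rate: float = 0.15, seed: int | None = None,
                       return_history: bool = False):
    """Masked-language-model-only training over all documents (labels ignored).

    Shares the batch iteration, masking stream, and optimizer with the
    adversarial trainer, so an adversarial run with both lambda weights at
    zero reproduces this trainer exactly under a matched seed.
    """
    if not corpus:
        raise ValueError("training requires a non-empty corpus")
    if tokenizer is None:
        tokenizer = WhitespaceTokenizer.from_texts(d.text for d in corpus)
    if seed is None:
        seed = cfg.seed
    encoder = TransformerEncoder(cfg, tokenizer)
    opt = Adam(encoder.parameters(), lr=lr)
    seq_lists = _prepare(corpus, tokenizer, cfg.max_tokens)
    shuffle_rng, mask_rng = _train_rngs(seed)
    n = len(corpus)
    history = []
    for _epoch in range(epochs):
        order = shuffle_rng.permutation(n)
        records = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            records.append(_mlm_only_step(encoder, [seq_lists[i] for i in idx],
                                          mask_rate, mask_rng, opt))
        history.append(float(np.mean([r["mlm"] for r in records])))
    if return_history:
        return encoder, history
    return encoder
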