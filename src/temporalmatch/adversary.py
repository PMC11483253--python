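"""Temporal discriminator and frozen anchor model.

The discriminator is a linear classifier over the flattened m x d abstract
embedding (d*m + 1 parameters including the bias); it predicts whether an
embedding comes from an old-period (label 0) or new-period (label 1)
document. The anchor is an encoder of identical architecture trained with
masked language modeling only; during adversarial training the generator is
penalized by the Frobenius distance between its abstract embedding and the
anchor's, which keeps the embeddings semantically grounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Document
from .encoder import (AbstractEmbedding, EncoderConfig, TransformerEncoder,
                      WhitespaceTokenizer)
from .nn import Tensor
from .nn import autodiff as ad

PROB_EPS = 1e-7  # probability clipping before logs

# Label convention, recorded so probe/report directions stay unambiguous.
LABEL_OLD, LABEL_NEW = 0, 1


class TemporalDiscriminator:
    """Linear old-vs-new classifier over flattened abstract embeddings."""

    def __init__(self, m: int, d: int, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.m = m
        self.d = d
        self.weights = Tensor(
            rng.normal(0.0, 1.0 / np.sqrt(m * d), size=(m * d, 1)).astype(np.float32),
            requires_grad=True)
        self.bias = Tensor(np.zeros(1, dtype=np.float32), requires_grad=True)

    @property
    def n_parameters(self) -> int:
        return self.d * self.m + 1

    def parameters(self) -> list[Tensor]:
        return [self.weights, self.bias]

    def logits(self, flat: Tensor) -> Tensor:
        """Differentiable logits for a [B, m*d] batch of flat embeddings."""
        return ad.matmul(flat, self.weights) + self.bias


def discriminate(disc: TemporalDiscriminator, emb: AbstractEmbedding) -> float:
    """p = sigmoid(w . flatten(emb) + b), the probability of the NEW period."""
    flat = emb.flatten()
    if flat.shape[0] != disc.m * disc.d:
        raise ValueError(
            f"embedding size {flat.shape[0]} does not match discriminator "
            f"input size {disc.m * disc.d}")
    z = float(flat @ disc.weights.data[:, 0] + disc.bias.data[0])
    return float(1.0 / (1.0 + np.exp(-z)))


def adversarial_loss(probs, labels) -> float:
    """Mean binary cross-entropy of predicted NEW-probabilities vs labels.

    Probabilities are clipped to [eps, 1-eps] so the loss is always finite.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if probs.size == 0:
        raise ValueError("empty batch")
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have equal length")
    if not np.all(np.isin(labels, (0.0, 1.0))):
        raise ValueError("labels must be binary (OLD=0, NEW=1)")
    p = np.clip(probs, PROB_EPS, 1.0 - PROB_EPS)
    return float(-(labels * np.log(p) + (1.0 - labels) * np.log1p(-p)).mean())


def anchor_loss(gen_emb: AbstractEmbedding, anc_emb: AbstractEmbedding) -> float:
    """Frobenius norm of the generator-minus-anchor embedding difference.

    Padded (masked-out) rows are zero in both matrices and contribute
    nothing.
    """
    if gen_emb.matrix.shape != anc_emb.matrix.shape:
        raise ValueError("embedding shapes differ")
    if not np.array_equal(gen_emb.mask, anc_emb.mask):
        raise ValueError("embedding masks differ")
    diff = gen_emb.matrix.astype(np.float64) - anc_emb.matrix.astype(np.float64)
    return float(np.sqrt((diff * diff).sum()))


@dataclass
class AnchorModel:
    """Frozen MLM-trained encoder used as the semantic anchor."""

    encoder: TransformerEncoder
    provenance: dict = field(default_factory=dict)
    _checksum: float = 0.0

    def __post_init__(self):
        self._checksum = self.encoder.checksum()

    def verify_frozen(self) -> None:
        if abs(self.encoder.checksum() - self._checksum) > 0:
            raise RuntimeError("anchor model weights changed after construction")


def train_anchor(corpus: list[Document], cfg: EncoderConfig, epochs: int,
                 tokenizer: WhitespaceTokenizer | None = None,
                 batch_size: int = 16, lr: float = 2e-5,
                 mask_rate: float = 0.15, seed: int | None = None) -> AnchorModel:
    """Train a frozen anchor by masked language modeling on all documents.

    Temporal labels are ignored: every document participates. The returned
    model records its training provenance (corpus size, epochs, seed).
    """
    from .training import train_mlm_baseline

    if not corpus:
        raise ValueError("anchor training requires a non-empty corpus")
    encoder, history = train_mlm_baseline(
        corpus, cfg, epochs, tokenizer=tokenizer, batch_size=batch_size,
        lr=lr, mask_rate=mask_rate, seed=seed, return_history=True)
    return AnchorModel(encoder=encoder, provenance={
        "n_docs": len(corpus), "epochs": epochs,
        "seed": cfg.seed if seed is None else seed,
        "objective": "mlm-only", "history": history})
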