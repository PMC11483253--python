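"""The generator encoder: a small transformer with a masked-token prediction
head, producing sentence embeddings and zero-padded abstract embeddings.

The architecture follows the compact BERT recipe — token + learned position
embeddings, post-norm transformer blocks, and a dense/layer-norm/projection
MLM head — at a configurable depth and width (defaults: 2 layers, hidden
size 128). Sentences are embedded by pooling final-layer hidden states; a
document ("abstract") embedding stacks the first ``m`` sentence embeddings
into an m x d matrix, zero-padding when the document is shorter.

The tokenizer is a closed-vocabulary whitespace/punctuation tokenizer built
from a corpus; synthetic corpora have closed vocabularies so no sub-word
model is needed (a word-piece tokenizer can be substituted, the encoder only
consumes integer ids).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .corpus import Document
from .nn import autodiff as ad
from .nn.autodiff import Tensor

PAD, UNK, CLS, SEP, MASK = 0, 1, 2, 3, 4
SPECIAL_TOKENS = ["[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]"]
_POOL_EXCLUDE = (PAD, CLS, SEP, MASK)  # UNK is a content token

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


class WhitespaceTokenizer:
    """Closed-vocabulary tokenizer: lowercased words and punctuation marks."""

    def __init__(self, vocab: list[str]):
        self.itos = SPECIAL_TOKENS + list(vocab)
        self.stoi = {tok: i for i, tok in enumerate(self.itos)}

    @classmethod
    def from_texts(cls, texts) -> "WhitespaceTokenizer":
        seen: set[str] = set()
        for text in texts:
            seen.update(_TOKEN_RE.findall(text.lower()))
        return cls(sorted(seen))

    @property
    def vocab_size(self) -> int:
        return len(self.itos)

    def encode(self, text: str, add_special: bool = True) -> np.ndarray:
        ids = [self.stoi.get(tok, UNK) for tok in _TOKEN_RE.findall(text.lower())]
        if add_special:
            ids = [CLS] + ids + [SEP]
        return np.asarray(ids, dtype=np.int64)


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of the generator (and anchor) encoder.

    ``hidden_size`` is the sentence-embedding width d; ``pooling`` selects
    how token states become a sentence vector (mean over non-special tokens,
    or the CLS state).
    """

    n_layers: int = 2
    hidden_size: int = 128
    n_heads: int = 2
    d_ff: int | None = None
    max_tokens: int = 512
    pooling: str = "mean"
    seed: int = 0

    def __post_init__(self):
        if self.hidden_size % self.n_heads != 0:
            raise ValueError("hidden_size must be divisible by n_heads")
        if self.pooling not in ("mean", "cls"):
            raise ValueError("pooling must be 'mean' or 'cls'")

    @property
    def ffn_size(self) -> int:
        return self.d_ff if self.d_ff is not None else 4 * self.hidden_size


@dataclass
class AbstractEmbedding:
    """m x d matrix of sentence embeddings; rows beyond the document's
    sentence count are exactly zero and flagged False in ``mask``."""

    matrix: np.ndarray
    mask: np.ndarray
    doc_id: str

    def __post_init__(self):
        if self.matrix.shape[0] != self.mask.shape[0]:
            raise ValueError("mask length must equal number of rows")

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def flatten(self) -> np.ndarray:
        return self.matrix.reshape(-1)


class TransformerEncoder(nn.Module):
    def __init__(self, config: EncoderConfig, tokenizer: WhitespaceTokenizer):
        self.config = config
        self.tokenizer = tokenizer
        d = config.hidden_size
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        self.token_emb = nn.Embedding(tokenizer.vocab_size, d, rng)
        self.pos_emb = nn.Embedding(config.max_tokens, d, rng)
        self.emb_ln = nn.LayerNorm(d)
        self.blocks = [nn.TransformerLayer(d, config.n_heads, config.ffn_size, rng)
                       for _ in range(config.n_layers)]
        self.mlm_dense = nn.Linear(d, d, rng)
        self.mlm_ln = nn.LayerNorm(d)
        self.mlm_out = nn.Linear(d, tokenizer.vocab_size, rng)

    # -- forward pieces ----------------------------------------------------
    def hidden_states(self, ids: np.ndarray, attn_mask: np.ndarray) -> Tensor:
        """Final-layer hidden states for a padded id batch [B, L]."""
        positions = np.broadcast_to(np.arange(ids.shape[1]), ids.shape)
        x = self.token_emb(ids) + self.pos_emb(positions)
        x = self.emb_ln(x)
        for block in self.blocks:
            x = block(x, attn_mask)
        return x

    def mlm_logits(self, hidden_rows: Tensor) -> Tensor:
        """MLM head applied to a [N, d] stack of target-position states."""
        h = self.mlm_ln(ad.gelu(self.mlm_dense(hidden_rows)))
        return self.mlm_out(h)

    def pool(self, hidden: Tensor, ids: np.ndarray) -> Tensor:
        """Sentence vectors [B, d] from hidden states [B, L, d]."""
        if self.config.pooling == "cls":
            from .nn.layers import _slice_t

            return _slice_t(hidden, 0)
        content = ~np.isin(ids, _POOL_EXCLUDE)
        counts = content.sum(axis=1, keepdims=True)
        if np.any(counts == 0):
            raise ValueError("sentence with no content tokens cannot be pooled")
        w = (content / counts).astype(np.float32)  # [B, L]
        return ad.reshape(ad.matmul(ad.swapaxes(hidden, 1, 2),
                                    Tensor(w[:, :, None])), hidden.shape[::2])


# -- batching helpers ------------------------------------------------------

def pad_batch(id_seqs: list[np.ndarray], max_tokens: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length id sequences into [B, L] with an attention mask."""
    clipped = []
    for seq in id_seqs:
        if len(seq) > max_tokens:
            warnings.warn("sequence truncated to max_tokens", stacklevel=2)
            seq = np.concatenate([seq[: max_tokens - 1], seq[-1:]])
        clipped.append(seq)
    length = max(len(s) for s in clipped)
    ids = np.full((len(clipped), length), PAD, dtype=np.int64)
    mask = np.zeros((len(clipped), length), dtype=bool)
    for i, seq in enumerate(clipped):
        ids[i, : len(seq)] = seq
        mask[i, : len(seq)] = True
    return ids, mask


def encode_sentence_batch(encoder: TransformerEncoder,
                          sentences: list[str]) -> Tensor:
    """Differentiable [n_sentences, d] sentence-embedding batch."""
    seqs = [encoder.tokenizer.encode(s) for s in sentences]
    ids, mask = pad_batch(seqs, encoder.config.max_tokens)
    hidden = encoder.hidden_states(ids, mask)
    return encoder.pool(hidden, ids)


# -- spec operations -------------------------------------------------------

def mask_tokens(token_ids: np.ndarray, mask_rate: float,
                rng: np.random.Generator, vocab_size: int,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Corrupt a token-id sequence for masked-token prediction.

    Selects ``ceil(mask_rate * n_eligible)`` non-special positions; each is
    replaced by [MASK] (80%), a random content token (10%), or kept (10%).
    Returns (corrupted ids, selected positions, original ids at positions).
    """
    if not 0.0 < mask_rate < 1.0:
        raise ValueError("mask_rate must lie strictly between 0 and 1")
    token_ids = np.asarray(token_ids)
    if token_ids.size == 0:
        raise ValueError("cannot mask an empty sequence")
    eligible = np.flatnonzero(token_ids >= len(SPECIAL_TOKENS))
    n_sel = math.ceil(mask_rate * eligible.size)
    positions = np.sort(rng.choice(eligible, size=n_sel, replace=False))
    targets = token_ids[positions].copy()
    corrupted = token_ids.copy()
    u = rng.random(n_sel)
    replace_random = (u >= 0.8) & (u < 0.9)
    corrupted[positions[u < 0.8]] = MASK
    if replace_random.any():
        corrupted[positions[replace_random]] = rng.integers(
            len(SPECIAL_TOKENS), vocab_size, size=int(replace_random.sum()))
    return corrupted, positions, targets


def mlm_loss(encoder: TransformerEncoder, corrupted: np.ndarray,
             attn_mask: np.ndarray, positions: tuple[np.ndarray, np.ndarray],
             targets: np.ndarray) -> Tensor:
    """Mean cross-entropy over masked positions of a corrupted batch.

    ``positions`` is a (row_indices, col_indices) pair addressing the target
    positions inside the [B, L] batch.
    """
    if np.asarray(targets).size == 0:
        raise ValueError("batch has no masked target positions")
    hidden = encoder.hidden_states(corrupted, attn_mask)
    b, length, d = hidden.shape
    flat = ad.reshape(hidden, (b * length, d))
    rows = positions[0] * length + positions[1]
    logits = encoder.mlm_logits(ad.gather_rows(flat, rows))
    return ad.softmax_cross_entropy(logits, targets)


def embed_sentence(encoder: TransformerEncoder, sentence: str) -> np.ndarray:
    """Pooled d-vector for one sentence (inference mode, deterministic)."""
    if not sentence or not sentence.strip():
        raise ValueError("cannot embed an empty sentence")
    with ad.no_grad():
        return encode_sentence_batch(encoder, [sentence]).data[0].copy()


def embed_abstract(encoder: TransformerEncoder, doc: Document,
                   m: int = 20) -> AbstractEmbedding:
    """m x d abstract embedding: first ``m`` sentence embeddings, zero-padded."""
    if m <= 0:
        raise ValueError("m must be positive")
    if not doc.sentences:
        raise ValueError(f"document {doc.id!r} has no segmented sentences")
    sentences = doc.sentences[:m]
    d = encoder.config.hidden_size
    with ad.no_grad():
        vectors = encode_sentence_batch(encoder, sentences).data
    matrix = np.zeros((m, d), dtype=np.float32)
    matrix[: len(sentences)] = vectors
    mask = np.zeros(m, dtype=bool)
    mask[: len(sentences)] = True
    return AbstractEmbedding(matrix=matrix, mask=mask, doc_id=doc.id)


# -- checkpointing ---------------------------------------------------------

def save_encoder(encoder: TransformerEncoder, path) -> None:
    arrays = {f"p{i}": a for i, a in enumerate(encoder.state_arrays())}
    np.savez(path, vocab=np.array(encoder.tokenizer.itos[len(SPECIAL_TOKENS):]),
             config=np.array([encoder.config.n_layers, encoder.config.hidden_size,
                              encoder.config.n_heads, encoder.config.ffn_size,
                              encoder.config.max_tokens,
                              0 if encoder.config.pooling == "mean" else 1,
                              encoder.config.seed], dtype=np.int64),
             **arrays)


def load_encoder(path) -> TransformerEncoder:
    with np.load(path, allow_pickle=False) as data:
        cfg_arr = data["config"]
        config = EncoderConfig(
            n_layers=int(cfg_arr[0]), hidden_size=int(cfg_arr[1]),
            n_heads=int(cfg_arr[2]), d_ff=int(cfg_arr[3]),
            max_tokens=int(cfg_arr[4]),
            pooling="mean" if cfg_arr[5] == 0 else "cls", seed=int(cfg_arr[6]))
        tokenizer = WhitespaceTokenizer([str(t) for t in data["vocab"]])
        enc = TransformerEncoder(config, tokenizer)
        for i, p in enumerate(enc.parameters()):
            p.data = data[f"p{i}"].astype(np.float32)
    return enc
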