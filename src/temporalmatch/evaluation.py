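"""Intrinsic evaluations of a trained encoder: held-out MLM loss, the
temporal probe, concept-pair similarity and future-relatedness rank
correlation, and the lambda grid search.

The temporal probe measures how much period information remains linearly
recoverable from frozen abstract embeddings: a fresh logistic-regression
classifier is trained on a seeded 70/30 split and scored on the held-out
30%. Successful distribution matching lowers probe accuracy toward the
majority-class rate.

The future-relatedness evaluation ranks concept pairs by embedding cosine
similarity and compares the ranking (Spearman) to that of a reference model
trained only on new-period text — the synthetic stand-in for a model trained
on later-year documents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .adversary import AnchorModel
from .corpus import Document, TemporalLabel
from .encoder import TransformerEncoder, embed_sentence
from .synthetic import ConceptPair
from .training import (AdversarialTrainConfig, _abstract_flat_batch, _prepare,
                       train_adversarial)
from .nn import autodiff as ad


@dataclass(frozen=True)
class ProbeResult:
    accuracy: float
    n_train: int
    n_test: int
    seed: int


@dataclass
class RelatednessReport:
    pair_ids: list[str]
    similarities: list[float]
    rank_correlation: float | None = None
    reference_tag: str = ""
    excluded: list[str] = field(default_factory=list)


def heldout_mlm_loss(encoder: TransformerEncoder, test_docs: list[Document],
                     seed: int, mask_rate: float = 0.15,
                     batch_size: int = 64) -> float:
    """Masked-prediction cross-entropy on held-out documents.

    The corruption stream is derived from ``seed`` only, so every model
    evaluated with the same seed sees identical corruptions. The returned
    value is the mean over all target positions.
    """
    from .encoder import mask_tokens, mlm_loss, pad_batch

    if not test_docs:
        raise ValueError("empty test set")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    seq_lists = _prepare(test_docs, encoder.tokenizer, encoder.config.max_tokens)
    all_seqs = [seq for seqs in seq_lists for seq in seqs]
    total_loss, total_targets = 0.0, 0
    with ad.no_grad():
        for start in range(0, len(all_seqs), batch_size):
            chunk = all_seqs[start:start + batch_size]
            corrupted, rows, cols, targets = [], [], [], []
            for seq in chunk:
                corr, pos, tgt = mask_tokens(seq, mask_rate, rng,
                                             encoder.tokenizer.vocab_size)
                idx = len(corrupted)
                corrupted.append(corr)
                rows.extend([idx] * len(pos))
                cols.extend(pos.tolist())
                targets.extend(tgt.tolist())
            if not targets:
                continue
            ids, attn = pad_batch(corrupted, encoder.config.max_tokens)
            loss = mlm_loss(encoder, ids, attn,
                            (np.asarray(rows), np.asarray(cols)),
                            np.asarray(targets))
            total_loss += loss.item() * len(targets)
            total_targets += len(targets)
    if total_targets == 0:
        raise ValueError("no maskable tokens in the test set")
    return total_loss / total_targets


def _flat_embeddings(encoder: TransformerEncoder, docs: list[Document],
                     m: int, chunk: int = 64) -> np.ndarray:
    out = np.empty((len(docs), m * encoder.config.hidden_size), dtype=np.float32)
    with ad.no_grad():
        for start in range(0, len(docs), chunk):
            sub = docs[start:start + chunk]
            seq_lists = _prepare(sub, encoder.tokenizer, encoder.config.max_tokens)
            out[start:start + len(sub)] = _abstract_flat_batch(
                encoder, seq_lists, m).data
    return out


def temporal_probe(encoder: TransformerEncoder, labeled_docs: list[Document],
                   split_seed: int, m: int = 20) -> ProbeResult:
    """Held-out accuracy of a linear old-vs-new probe on frozen embeddings."""
    docs = [d for d in labeled_docs if d.temporal_label != TemporalLabel.UNLABELED]
    y = np.array([d.temporal_label.value for d in docs])
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("probe requires at least 2 documents per class")
    x = _flat_embeddings(encoder, docs, m)
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=0.3, random_state=split_seed, stratify=y)
    clf = LogisticRegression(max_iter=2000, random_state=split_seed)
    clf.fit(x_tr, y_tr)
    return ProbeResult(accuracy=float(clf.score(x_te, y_te)),
                       n_train=len(y_tr), n_test=len(y_te), seed=split_seed)


def concept_similarity(encoder: TransformerEncoder, pairs: list[ConceptPair],
                       reference_tag: str = "") -> RelatednessReport:
    """Cosine similarity of each pair's concept embeddings.

    Concepts are embedded as standalone single-token sentences. Pairs with a
    zero-norm embedding are excluded with a warning and recorded in
    ``excluded``.
    """
    pair_ids, sims, excluded = [], [], []
    for pair in pairs:
        pid = f"{pair.concept_a}|{pair.concept_b}"
        va = embed_sentence(encoder, pair.concept_a)
        vb = embed_sentence(encoder, pair.concept_b)
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0.0 or nb == 0.0:
            warnings.warn(f"zero-norm embedding for pair {pid}; excluded",
                          stacklevel=2)
            excluded.append(pid)
            continue
        pair_ids.append(pid)
        sims.append(float(va @ vb / (na * nb)))
    return RelatednessReport(pair_ids=pair_ids, similarities=sims,
                             reference_tag=reference_tag, excluded=excluded)


def future_relatedness_correlation(candidate: RelatednessReport,
                                   reference: RelatednessReport) -> float:
    """Spearman rank correlation between two similarity reports.

    Both reports must cover the same pairs; ties receive average ranks.
    """
    if candidate.pair_ids != reference.pair_ids:
        common = [p for p in candidate.pair_ids if p in set(reference.pair_ids)]
        if len(common) < 2:
            raise ValueError("fewer than 2 shared pairs between reports")
        cand = [candidate.similarities[candidate.pair_ids.index(p)] for p in common]
        ref = [reference.similarities[reference.pair_ids.index(p)] for p in common]
    else:
        if len(candidate.pair_ids) < 2:
            raise ValueError("need at least 2 pairs for a rank correlation")
        cand, ref = candidate.similarities, reference.similarities
    rho = spearmanr(cand, ref).statistic
    return float(rho)


def lambda_grid_search(corpus: list[Document], anchor: AnchorModel,
                       grid: list[tuple[float, float]],
                       pairs: list[ConceptPair],
                       reference: RelatednessReport, seed: int,
                       base_config: AdversarialTrainConfig | None = None,
                       **train_kwargs) -> dict:
    """Train one model per (lambda_adv, lambda_anchor) grid point and pick
    the one with the highest future-relatedness correlation.

    Ties are broken toward smaller lambda_adv, then smaller lambda_anchor.
    Returns ``{"table": [(la, lA, corr), ...], "best": (la, lA)}``.
    """
    if not grid:
        raise ValueError("empty lambda grid")
    for la, lA in grid:
        if la + lA > 1.0 + 1e-12:
            raise ValueError(f"grid point ({la}, {lA}) violates la + lA <= 1")
    base = base_config or AdversarialTrainConfig()
    table = []
    for la, lA in grid:
        cfg = AdversarialTrainConfig(
            lambda_adv=la, lambda_anchor=lA, epochs=base.epochs,
            lr_generator=base.lr_generator, lr_discriminator=base.lr_discriminator,
            batch_size=base.batch_size, seed=seed,
            mlm_corpus_scope=base.mlm_corpus_scope,
            period_sample_weights=base.period_sample_weights,
            mask_rate=base.mask_rate, adversarial_mode=base.adversarial_mode,
            m=base.m)
        bundle = train_adversarial(corpus, anchor, cfg, **train_kwargs)
        report = concept_similarity(bundle.generator, pairs)
        corr = future_relatedness_correlation(report, reference)
        table.append((la, lA, corr))
    best = max(table, key=lambda row: (row[2], -row[0], -row[1]))
    return {"table": table, "best": (best[0], best[1])}


def default_lambda_grid(step: float = 0.1, top: float = 0.6,
                        ) -> list[tuple[float, float]]:
    """All (lambda_adv, lambda_anchor) pairs on a {0, step, ..., top} grid
    with lambda_adv + lambda_anchor <= 1."""
    values = np.round(np.arange(0.0, top + step / 2, step), 10)
    return [(float(a), float(b)) for a in values for b in values
            if a + b <= 1.0 + 1e-12]
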