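"""Synthetic temporal-drift corpora, planted concept pairs, and synthetic
patient cohorts.

The corpus generator emulates the structure the method needs from a real
diachronic corpus — multi-sentence documents with calendar years, two
labeled periods separated by a gap, and a controllable distributional drift
between the periods — without imitating clinical language. Documents are
drawn from a topic mixture: every sentence samples a topic and then tokens
from that topic's word distribution. A designated fraction of the
vocabulary "drifts": those words have different topic affinities in an old
and a new word table, and new-period documents sample from the old table
interpolated toward the new table with weight ``drift_strength`` (delta).
At delta = 0 the two periods are identically distributed by construction.

Concept pairs plant a ground truth for the future-relatedness evaluation:
each pair of reserved concept tokens is co-injected into the same sentence
at a rate proportional to a per-period relatedness, so sentence-level
co-occurrence — the signal MLM-trained similarity tracks — differs between
periods in a known, strictly ranked way.

Patient generation emulates code-sequence clinical records with a
group-dependent outcome signal for the downstream harness.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import Document
from .downstream import PatientRecord


@dataclass(frozen=True)
class DriftCorpusConfig:
    vocab_size: int = 500
    n_docs_old: int = 1000
    n_docs_new: int = 1000
    sentences_per_doc: tuple[int, int] = (4, 8)
    tokens_per_sentence: tuple[int, int] = (6, 12)
    n_topics: int = 8
    drift_strength: float = 0.8
    drifting_word_fraction: float = 0.2
    old_years: tuple[int, int] = (2010, 2013)
    new_years: tuple[int, int] = (2016, 2018)
    concept_mention_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.drift_strength <= 1.0:
            raise ValueError("drift_strength must lie in [0, 1]")
        if not 0.0 <= self.drifting_word_fraction <= 1.0:
            raise ValueError("drifting_word_fraction must lie in [0, 1]")
        if self.vocab_size < self.n_topics:
            raise ValueError("vocab_size must be at least n_topics")


@dataclass(frozen=True)
class ConceptPair:
    concept_a: str
    concept_b: str
    relatedness_old: float
    relatedness_new: float

    @property
    def drifting(self) -> bool:
        return self.relatedness_old != self.relatedness_new


def _word(i: int) -> str:
    return f"w{i:04d}"


def _topic_tables(cfg: DriftCorpusConfig, n_words: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Old- and new-period topic-word probability tables [n_topics, n_words].

    Every word has a home topic where its weight is boosted; drifting words
    get a different home topic in the new table.
    """
    home_old = rng.integers(0, cfg.n_topics, size=n_words)
    home_new = home_old.copy()
    n_drift = int(round(cfg.drifting_word_fraction * n_words))
    drift_idx = rng.choice(n_words, size=n_drift, replace=False)
    # drifting words change both topic affinity and overall frequency:
    # the home topic moves, and the base rate rises or falls 4-fold, so the
    # drift is visible to co-occurrence models and to bag-of-words models
    shift = rng.integers(1, cfg.n_topics, size=n_drift)
    home_new[drift_idx] = (home_old[drift_idx] + shift) % cfg.n_topics
    base_old = rng.uniform(0.5, 1.5, size=n_words)
    base_new = base_old.copy()
    factor = np.where(rng.random(n_drift) < 0.5, 4.0, 0.25)
    base_new[drift_idx] *= factor
    boost = 9.0

    def table(base: np.ndarray, home: np.ndarray) -> np.ndarray:
        t = np.tile(base, (cfg.n_topics, 1))
        t[home, np.arange(n_words)] *= 1.0 + boost
        return t / t.sum(axis=1, keepdims=True)

    return table(base_old, home_old), table(base_new, home_new)


def generate_drift_corpus(cfg: DriftCorpusConfig,
                          pairs: list[ConceptPair] | None = None,
                          ) -> list[Document]:
    """Generate a two-period corpus with a planted distributional drift.

    Old-period documents sample tokens from the old topic table; new-period
    documents from ``(1 - delta) * old + delta * new``. If concept ``pairs``
    are supplied their tokens are injected with period-dependent sentence
    co-occurrence rates. Reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n_concept = 2 * len(pairs) if pairs else 0
    n_words = cfg.vocab_size - n_concept
    if n_words < cfg.n_topics:
        raise ValueError("vocabulary too small for the requested concept pairs")
    words = [_word(i) for i in range(n_words)]
    t_old, t_new = _topic_tables(cfg, n_words, rng)
    delta = cfg.drift_strength
    t_interp = (1.0 - delta) * t_old + delta * t_new

    docs: list[Document] = []
    total = cfg.n_docs_old + cfg.n_docs_new
    for i in range(total):
        is_new = i >= cfg.n_docs_old
        table = t_interp if is_new else t_old
        lo, hi = cfg.sentences_per_doc
        n_sent = int(rng.integers(lo, hi + 1))
        sentences = []
        for _ in range(n_sent):
            topic = int(rng.integers(cfg.n_topics))
            t_lo, t_hi = cfg.tokens_per_sentence
            n_tok = int(rng.integers(t_lo, t_hi + 1))
            token_ids = rng.choice(n_words, size=n_tok, p=table[topic])
            sentences.append([words[t] for t in token_ids])
        if pairs:
            _inject_concepts(sentences, pairs, is_new, cfg.concept_mention_rate, rng)
        year_lo, year_hi = cfg.new_years if is_new else cfg.old_years
        year = int(rng.integers(year_lo, year_hi + 1))
        text = " ".join(" ".join(s) + "." for s in sentences)
        docs.append(Document(id=f"doc{i:05d}", year=year, text=text))
    return docs


def _inject_concepts(sentences: list[list[str]], pairs: list[ConceptPair],
                     is_new: bool, mention_rate: float,
                     rng: np.random.Generator) -> None:
    """Insert concept mentions; with probability = the period's relatedness
    the partner concept lands adjacent in the same sentence (a tight
    co-occurrence the masked-token objective can learn), otherwise in a
    different sentence of the document."""
    n_sent = len(sentences)
    for pair in pairs:
        if rng.random() >= mention_rate:
            continue
        rel = pair.relatedness_new if is_new else pair.relatedness_old
        sent_a = int(rng.integers(n_sent))
        pos_a = int(rng.integers(len(sentences[sent_a]) + 1))
        if rng.random() < rel or n_sent == 1:
            sentences[sent_a][pos_a:pos_a] = [pair.concept_a, pair.concept_b]
        else:
            sentences[sent_a].insert(pos_a, pair.concept_a)
            sent_b = int((sent_a + 1 + rng.integers(n_sent - 1)) % n_sent)
            sentences[sent_b].insert(
                int(rng.integers(len(sentences[sent_b]) + 1)), pair.concept_b)


def generate_concept_pairs(cfg: DriftCorpusConfig, n_pairs: int) -> list[ConceptPair]:
    """Plant ``n_pairs`` concept pairs with strict, period-specific rankings.

    The new-period relatedness decreases strictly across pairs while the
    old-period relatedness is its reverse, so the two ground-truth rankings
    are both strict and maximally different — the planted analogue of
    concept relations that reorder over time. Pair tokens are reserved at
    the top of the vocabulary (2 per pair).
    """
    if 2 * n_pairs > cfg.vocab_size - cfg.n_topics:
        raise ValueError("vocabulary too small to reserve concept tokens")
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs for a ranking")
    rel_new = np.linspace(0.95, 0.05, n_pairs)
    rel_old = rel_new[::-1]
    pairs = []
    for i in range(n_pairs):
        pairs.append(ConceptPair(
            concept_a=f"c{i:03d}a", concept_b=f"c{i:03d}b",
            relatedness_old=float(rel_old[i]), relatedness_new=float(rel_new[i])))
    return pairs


# -- synthetic patients ----------------------------------------------------

@dataclass(frozen=True)
class SyntheticPatientConfig:
    n_patients: int = 2000
    female_fraction: float = 0.44
    code_vocab: tuple[str, ...] = ()
    sequence_length: tuple[int, int] = (2, 6)
    outcome_kind: str = "binary"  # or "continuous"
    coefficient_map: tuple[tuple[str, float], ...] = ()
    group_interaction: float = 0.0
    intercept: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.code_vocab:
            raise ValueError("code_vocab must be non-empty")
        if not 0.0 < self.female_fraction < 1.0:
            raise ValueError("female_fraction must lie strictly in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.outcome_kind not in ("binary", "continuous"):
            raise ValueError("outcome_kind must be 'binary' or 'continuous'")
        unknown = [c for c, _ in self.coefficient_map if c not in self.code_vocab]
        if unknown:
            raise ValueError(f"coefficients for codes outside code_vocab: {unknown}")


SEQUENCE_NAMES = ("previous_diagnoses", "current_diagnoses", "medications")


def generate_patients(cfg: SyntheticPatientConfig) -> list[PatientRecord]:
    """Generate code-sequence patients with a group-dependent outcome signal.

    The linear predictor is ``intercept + sum(coef[code] * present(code))
    + group_interaction * female * any_signal_code_present``; continuous
    outcomes add Gaussian noise, binary outcomes are Bernoulli(sigmoid).
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    coef = dict(cfg.coefficient_map)
    signal_codes = {c for c, v in coef.items() if v != 0.0}
    n_female = int(round(cfg.female_fraction * cfg.n_patients))
    female_flags = np.zeros(cfg.n_patients, dtype=bool)
    female_flags[:n_female] = True
    female_flags = rng.permutation(female_flags)
    records: list[PatientRecord] = []
    for i in range(cfg.n_patients):
        female = bool(female_flags[i])
        age = float(np.clip(rng.normal(60.0, 15.0), 18.0, 100.0))
        sequences: dict[str, list[str]] = {}
        present: set[str] = set()
        for name in SEQUENCE_NAMES:
            lo, hi = cfg.sequence_length
            n_codes = int(rng.integers(lo, hi + 1))
            codes = [cfg.code_vocab[int(k)]
                     for k in rng.integers(0, len(cfg.code_vocab), size=n_codes)]
            sequences[name] = codes
            present.update(codes)
        lp = cfg.intercept + sum(coef.get(c, 0.0) for c in present)
        if cfg.group_interaction and female and (present & signal_codes):
            lp += cfg.group_interaction
        if cfg.outcome_kind == "continuous":
            outcome = float(lp + rng.normal(0.0, cfg.noise_sd))
        else:
            outcome = float(rng.random() < 1.0 / (1.0 + np.exp(-lp)))
        records.append(PatientRecord(
            patient_id=f"p{i:05d}", group="F" if female else "M",
            static_features=[age, float(len(present))],
            sequences=sequences, outcome=outcome))
    return records


# -- writers ---------------------------------------------------------------

def write_pairs_csv(pairs: list[ConceptPair], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["concept_a", "concept_b", "relatedness_old", "relatedness_new"])
        for p in pairs:
            writer.writerow([p.concept_a, p.concept_b, p.relatedness_old,
                             p.relatedness_new])


def write_patients_jsonl(records: list[PatientRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for r in records:
            fh.write(json.dumps({
                "patient_id": r.patient_id, "group": r.group,
                "static_features": list(r.static_features),
                "sequences": r.sequences, "outcome": r.outcome}) + "\n")
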