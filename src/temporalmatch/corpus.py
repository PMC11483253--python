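"""Document corpora: JSONL reading, temporal labeling, sentence segmentation,
train/test splitting.

A corpus is a list of :class:`Document` records, each carrying a calendar
year. Documents are assigned to an OLD or NEW period by year range (with a
deliberate gap between the periods so the discriminator task is
well-separated); documents in the gap or outside both ranges stay UNLABELED
and are retained.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path


class TemporalLabel(Enum):
    OLD = 0
    NEW = 1
    UNLABELED = 2


@dataclass
class Document:
    """One timestamped text with an optional temporal period label."""

    id: str
    year: int
    text: str
    sentences: list[str] = field(default_factory=list)
    temporal_label: TemporalLabel = TemporalLabel.UNLABELED

    def __post_init__(self):
        if self.year < 0:
            raise ValueError(f"document {self.id!r}: year must be >= 0")


@dataclass(frozen=True)
class TemporalSplitConfig:
    """Inclusive year ranges defining the old and new periods.

    Defaults mirror a 2010-2013 old period and a 2016-2018 new period with a
    two-year gap; any disjoint ranges with max(old) < min(new) are valid.
    """

    old_years: tuple[int, int] = (2010, 2013)
    new_years: tuple[int, int] = (2016, 2018)

    def __post_init__(self):
        o_lo, o_hi = self.old_years
        n_lo, n_hi = self.new_years
        if o_lo > o_hi or n_lo > n_hi:
            raise ValueError("year ranges must be non-empty (lo <= hi)")
        if o_hi >= n_lo:
            raise ValueError("old range must end before new range begins")


@dataclass(frozen=True)
class CorpusSplit:
    train: list[str]
    test: list[str]
    seed: int


def read_corpus(path: str | Path) -> list[Document]:
    """Read a JSONL corpus (one ``{id, year, text}`` object per line).

    Raises ``ValueError`` naming the offending line for malformed JSON or
    missing fields, and for duplicate document ids.
    """
    path = Path(path)
    docs: list[Document] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            for key in ("id", "year", "text"):
                if key not in obj:
                    raise ValueError(f"{path}: line {lineno} missing field {key!r}")
            doc_id = str(obj["id"])
            if doc_id in seen:
                raise ValueError(f"{path}: duplicate document id {doc_id!r} on line {lineno}")
            seen.add(doc_id)
            docs.append(Document(id=doc_id, year=int(obj["year"]), text=str(obj["text"])))
    return docs


def write_corpus(docs: list[Document], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps({"id": doc.id, "year": doc.year, "text": doc.text}) + "\n")


def assign_temporal_labels(docs: list[Document],
                           cfg: TemporalSplitConfig) -> list[Document]:
    """Label each document OLD/NEW by its year; gap years stay UNLABELED.

    Labeling is total and idempotent; no document is dropped.
    """
    out = []
    for doc in docs:
        if cfg.old_years[0] <= doc.year <= cfg.old_years[1]:
            label = TemporalLabel.OLD
        elif cfg.new_years[0] <= doc.year <= cfg.new_years[1]:
            label = TemporalLabel.NEW
        else:
            label = TemporalLabel.UNLABELED
        out.append(replace(doc, temporal_label=label))
    return out


_SENTENCE_BOUNDARY = re.compile(r"(?<=[.!?])\s+")

SEGMENTER_NAME = "regex-punctuation-v1"


def segment_sentences(doc: Document) -> Document:
    """Split ``doc.text`` into sentences at terminal punctuation.

    Uses a deterministic punctuation-based boundary detector (split after
    ``.``, ``!`` or ``?`` followed by whitespace). The sentences concatenate
    back to the text up to whitespace normalization.
    """
    text = doc.text.strip()
    if not text:
        raise ValueError(f"document {doc.id!r}: cannot segment empty text")
    sentences = [s for s in _SENTENCE_BOUNDARY.split(text) if s.strip()]
    return replace(doc, sentences=sentences)


def split_train_test(docs: list[Document], train_fraction: float,
                     seed: int) -> CorpusSplit:
    """Seeded random split by document id; |train| = round(fraction * N)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if len(docs) < 2:
        raise ValueError("need at least 2 documents to split")
    import numpy as np

    ids = [doc.id for doc in docs]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    train = sorted(ids[i] for i in order[:n_train])
    test = sorted(ids[i] for i in order[n_train:])
    return CorpusSplit(train=train, test=test, seed=seed)
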