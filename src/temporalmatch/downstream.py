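"""Downstream clinical-prediction harness over a frozen embedder.

Two task heads mirror common clinical benchmarks: a continuous-outcome
regression (length-of-stay-like, mean-squared-error loss) and a binary
classification (ICU-readmission-like, cross-entropy loss). In both, each
code description in a patient's ordered sequences is embedded by the frozen
text encoder, every sequence is aggregated by an LSTM whose weights are
shared across sequences, the aggregated vectors are concatenated with the
patient's static features (for regression, additionally the current
primary-diagnosis embedding), and a 2-layer feed-forward head produces the
prediction. Only the head (LSTM + MLP) trains; the encoder checksum is
asserted unchanged.

Evaluation is group-wise: AUC (classification) or MAE (regression) per
group with subject-level bootstrap confidence intervals and pairwise gaps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import LSTM, Adam, Linear, Module, Tensor
from .nn import autodiff as ad


@dataclass
class PatientRecord:
    """One patient: group label, static features, ordered code-description
    sequences, and an outcome (binary or continuous)."""

    patient_id: str
    group: str
    static_features: list[float]
    sequences: dict[str, list[str]]
    outcome: float

    def __post_init__(self):
        if not self.group:
            raise ValueError(f"patient {self.patient_id!r}: group is required")
        if not self.static_features and not any(self.sequences.values()):
            raise ValueError(
                f"patient {self.patient_id!r}: needs static features or a "
                "non-empty sequence")
        if not 1 <= len(self.sequences) <= 3:
            raise ValueError("patients carry 1-3 named sequences")


def read_patients_jsonl(path: str | Path) -> list[PatientRecord]:
    records = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON on line {lineno}") from exc
            records.append(PatientRecord(
                patient_id=str(obj["patient_id"]), group=str(obj["group"]),
                static_features=[float(v) for v in obj.get("static_features", [])],
                sequences={k: list(v) for k, v in obj["sequences"].items()},
                outcome=float(obj["outcome"])))
    return records


@dataclass(frozen=True)
class HeadConfig:
    """Per-task head hyperparameters; epoch/learning-rate defaults follow
    the regression (10 epochs, lr 1e-3) and classification (4 epochs,
    lr 1e-5) task settings."""

    task: str  # "regression" or "classification"
    lstm_hidden: int = 64
    mlp_hidden: int = 64
    epochs: int | None = None
    lr: float | None = None
    batch_size: int = 32
    include_group_feature: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("regression", "classification"):
            raise ValueError("task must be 'regression' or 'classification'")
        if self.lstm_hidden <= 0 or self.mlp_hidden <= 0:
            raise ValueError("hidden sizes must be positive")
        if self.epochs is None:
            object.__setattr__(self, "epochs",
                               10 if self.task == "regression" else 4)
        if self.lr is None:
            object.__setattr__(self, "lr",
                               1e-3 if self.task == "regression" else 1e-5)


class OutcomeHead(Module):
    """Shared-weight LSTM sequence aggregator + 2-layer feed-forward head."""

    def __init__(self, cfg: HeadConfig, d_embed: int, n_sequences: int,
                 n_static: int):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        self.cfg = cfg
        self.d_embed = d_embed
        self.n_sequences = n_sequences
        rep_dim = n_sequences * cfg.lstm_hidden + n_static
        if cfg.task == "regression":
            rep_dim += d_embed  # current primary-diagnosis embedding concat
        self.rep_dim = rep_dim
        self.lstm = LSTM(d_embed, cfg.lstm_hidden, rng)
        self.fc1 = Linear(rep_dim, cfg.mlp_hidden, rng)
        self.fc2 = Linear(cfg.mlp_hidden, 1, rng)

    def predict_scores(self, reps: np.ndarray) -> np.ndarray:
        with ad.no_grad():
            out = self.fc2(ad.relu(self.fc1(Tensor(reps.astype(np.float32)))))
            z = out.data[:, 0]
        if self.cfg.task == "classification":
            return 1.0 / (1.0 + np.exp(-z))
        return z.astype(np.float64)


class _EmbeddingCache:
    """Frozen-encoder embeddings of code descriptions, computed once."""

    def __init__(self, encoder):
        from .encoder import embed_sentence

        self._embed = lambda text: embed_sentence(encoder, text)
        self._cache: dict[str, np.ndarray] = {}
        self.d = encoder.config.hidden_size

    def __call__(self, code: str) -> np.ndarray:
        if code not in self._cache:
            self._cache[code] = self._embed(code)
        return self._cache[code]


def _sequence_batch(records: list[PatientRecord], seq_name: str,
                    cache: _EmbeddingCache) -> tuple[np.ndarray, np.ndarray]:
    """[B, T, d] embedded code sequences with mask; empty sequences give an
    all-False mask (aggregated to a zero vector)."""
    lengths = [len(r.sequences.get(seq_name, [])) for r in records]
    t = max(max(lengths), 1)
    x = np.zeros((len(records), t, cache.d), dtype=np.float32)
    mask = np.zeros((len(records), t), dtype=bool)
    for i, r in enumerate(records):
        for j, code in enumerate(r.sequences.get(seq_name, [])):
            x[i, j] = cache(code)
            mask[i, j] = True
    return x, mask


def build_patient_representation(encoder, record: PatientRecord,
                                 head: OutcomeHead,
                                 _cache: _EmbeddingCache | None = None,
                                 ) -> np.ndarray:
    """Concatenated representation for one patient (inference mode).

    Sequence aggregations (shared-weight LSTM) + static features; for the
    regression task the current primary-diagnosis embedding is concatenated
    as well.
    """
    cache = _cache or _EmbeddingCache(encoder)
    parts = []
    with ad.no_grad():
        for name in sorted(record.sequences):
            x, mask = _sequence_batch([record], name, cache)
            if mask.any():
                parts.append(head.lstm(Tensor(x), mask).data[0])
            else:
                parts.append(np.zeros(head.cfg.lstm_hidden, dtype=np.float32))
    if head.cfg.task == "regression":
        current = record.sequences.get("current_diagnoses") or []
        parts.append(cache(current[0]) if current
                     else np.zeros(cache.d, dtype=np.float32))
    parts.append(np.asarray(record.static_features, dtype=np.float32))
    return np.concatenate(parts)


def _representation_tensors(records: list[PatientRecord], head: OutcomeHead,
                            cache: _EmbeddingCache, seq_names: list[str],
                            group_map: dict[str, float] | None):
    """Differentiable batch representation (grad flows into the LSTM only;
    encoder embeddings enter as constants)."""
    parts = []
    for name in seq_names:
        x, mask = _sequence_batch(records, name, cache)
        parts.append(head.lstm(Tensor(x), mask))
    if head.cfg.task == "regression":
        cur = np.stack([
            cache(r.sequences["current_diagnoses"][0])
            if r.sequences.get("current_diagnoses")
            else np.zeros(cache.d, dtype=np.float32)
            for r in records])
        parts.append(Tensor(cur))
    static = np.stack([_static_vector(r, group_map) for r in records])
    parts.append(Tensor(static.astype(np.float32)))
    return ad.concat(parts, axis=1)


def _static_vector(record: PatientRecord,
                   group_map: dict[str, float] | None) -> np.ndarray:
    vec = list(record.static_features)
    if group_map is not None:
        vec.append(group_map[record.group])
    return np.asarray(vec, dtype=np.float32)


@dataclass
class TrainedHead:
    head: OutcomeHead
    seq_names: list[str]
    group_map: dict[str, float] | None
    static_scale: np.ndarray
    history: list[float] = field(default_factory=list)

    def scores(self, encoder, records: list[PatientRecord],
               cache: _EmbeddingCache | None = None) -> np.ndarray:
        cache = cache or _EmbeddingCache(encoder)
        with ad.no_grad():
            reps = _representation_tensors(
                [ _scale_static(r, self.static_scale) for r in records],
                self.head, cache, self.seq_names, self.group_map)
            out = self.head.fc2(ad.relu(self.head.fc1(reps))).data[:, 0]
        if self.head.cfg.task == "classification":
            return 1.0 / (1.0 + np.exp(-out.astype(np.float64)))
        return out.astype(np.float64)


def _scale_static(record: PatientRecord, scale: np.ndarray) -> PatientRecord:
    feats = (np.asarray(record.static_features, dtype=np.float64) / scale).tolist()
    return PatientRecord(record.patient_id, record.group, feats,
                         record.sequences, record.outcome)


def train_outcome_head(encoder, records: list[PatientRecord],
                       cfg: HeadConfig) -> TrainedHead:
    """Train the task head on frozen-encoder representations.

    Regression minimizes mean squared error, classification binary
    cross-entropy, both with Adam at ``cfg.lr``. The encoder's parameter
    checksum is verified unchanged after training.
    """
    binary = {r.outcome for r in records} <= {0.0, 1.0}
    if cfg.task == "classification" and not binary:
        raise ValueError("classification requires binary outcomes")
    checksum_before = encoder.checksum()
    cache = _EmbeddingCache(encoder)
    seq_names = sorted({name for r in records for name in r.sequences})
    groups = sorted({r.group for r in records})
    group_map = ({g: float(i) for i, g in enumerate(groups)}
                 if cfg.include_group_feature else None)
    n_static = len(records[0].static_features) + (1 if group_map else 0)
    head = OutcomeHead(cfg, cache.d, len(seq_names), n_static)

    static_raw = np.stack([np.asarray(r.static_features, dtype=np.float64)
                           for r in records])
    scale = np.maximum(np.abs(static_raw).max(axis=0), 1e-9)
    scaled = [_scale_static(r, scale) for r in records]

    opt = Adam(head.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed + 1))
    y = np.array([r.outcome for r in records], dtype=np.float32)
    history = []
    n = len(records)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = [scaled[i] for i in idx]
            reps = _representation_tensors(batch, head, cache, seq_names, group_map)
            out = head.fc2(ad.relu(head.fc1(reps)))
            if cfg.task == "regression":
                diff = out - Tensor(y[idx][:, None])
                loss = ad.tmean(diff * diff)
            else:
                loss = ad.bce_with_logits(out, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    if encoder.checksum() != checksum_before:
        raise RuntimeError("frozen encoder changed during head training")
    return TrainedHead(head=head, seq_names=seq_names, group_map=group_map,
                       static_scale=scale, history=history)


@dataclass
class EvaluationReport:
    task: str
    metric_name: str
    overall: tuple[float, float, float]
    by_group: dict[str, tuple[float, float, float]]
    gaps: dict[str, float]
    insufficient: list[str]
    n_by_group: dict[str, int]


def evaluate_by_group(trained: TrainedHead, encoder,
                      records: list[PatientRecord], group_field: str = "group",
                      n_resamples: int = 2000, seed: int = 0,
                      ) -> EvaluationReport:
    """Per-group and overall metric with bootstrap CIs and pairwise gaps.

    Classification reports AUC, regression MAE. Groups with fewer than 2
    records are listed as insufficient rather than scored.
    """
    from . import stats

    if group_field != "group":
        raise ValueError(f"unknown group field {group_field!r}")
    scores = trained.scores(encoder, records)
    y = np.array([r.outcome for r in records], dtype=float)
    groups = np.array([r.group for r in records])
    task = trained.head.cfg.task

    if task == "classification":
        metric_name = "auc"

        def metric(data):
            arr = np.asarray(data, dtype=float)
            return stats.auc(arr[:, 0], arr[:, 1])

        paired = np.column_stack([y, scores])
    else:
        metric_name = "mae"

        def metric(data):
            arr = np.asarray(data, dtype=float)
            return float(np.abs(arr[:, 0] - arr[:, 1]).mean())

        paired = np.column_stack([y, scores])

    overall = stats.bootstrap_ci(metric, paired, n_resamples=n_resamples, seed=seed)
    by_group, insufficient, n_by_group = {}, [], {}
    for g in sorted(set(groups)):
        sel = paired[groups == g]
        n_by_group[g] = len(sel)
        if len(sel) < 2:
            insufficient.append(g)
            continue
        by_group[g] = stats.bootstrap_ci(metric, sel, n_resamples=n_resamples,
                                         seed=seed + 1)
    gaps = {}
    names = sorted(by_group)
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            gaps[f"{ga}-{gb}"] = by_group[ga][0] - by_group[gb][0]
    return EvaluationReport(task=task, metric_name=metric_name, overall=overall,
                            by_group=by_group, gaps=gaps,
                            insufficient=insufficient, n_by_group=n_by_group)
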