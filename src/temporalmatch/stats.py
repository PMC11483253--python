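"""Paired model-comparison statistics: AUC, the DeLong test for correlated
ROC curves, the Diebold-Mariano test with mean-absolute-deviation criterion,
and percentile bootstrap confidence intervals.

Conventions: two-sided p-values throughout; no significance threshold is
hard-coded; degenerate cases (zero variance with zero effect) return p = 1.0
with an explicit flag rather than NaN.

The Diebold-Mariano test is defined for forecast time series; applied to
cross-sectional subjects it reduces to the lag-0 (iid) variant, i.e. a
paired z-test on absolute errors — which is how it is used here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata


@dataclass(frozen=True)
class PairedScores:
    """Classifier scores from two models on the same subjects."""

    labels: np.ndarray
    scores_a: np.ndarray
    scores_b: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        a = np.asarray(self.scores_a, dtype=float)
        b = np.asarray(self.scores_b, dtype=float)
        if not (len(labels) == len(a) == len(b)):
            raise ValueError("labels and both score vectors must have equal length")
        object.__setattr__(self, "labels", labels.astype(int))
        object.__setattr__(self, "scores_a", a)
        object.__setattr__(self, "scores_b", b)


@dataclass(frozen=True)
class PairedErrors:
    """Per-subject prediction errors from two models on the same subjects."""

    errors_a: np.ndarray
    errors_b: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.errors_a, dtype=float)
        b = np.asarray(self.errors_b, dtype=float)
        if len(a) != len(b):
            raise ValueError("error vectors must have equal length")
        if len(a) < 2:
            raise ValueError("need at least 2 paired errors")
        object.__setattr__(self, "errors_a", a)
        object.__setattr__(self, "errors_b", b)


def auc(labels, scores) -> float:
    """Area under the ROC curve, Mann-Whitney form with ties counted 0.5."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - m * (m + 1) / 2.0) / (m * n))


def _placements(scores: np.ndarray, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values via midranks: (V01 per positive, V10 per
    negative, AUC)."""
    m, n = int(pos.sum()), int((~pos).sum())
    tz = rankdata(scores)
    tx = rankdata(scores[pos])
    ty = rankdata(scores[~pos])
    v01 = (tz[pos] - tx) / n
    v10 = 1.0 - (tz[~pos] - ty) / m
    return v01, v10, float(v01.mean())


def delong_test(ps: PairedScores) -> dict:
    """Paired DeLong test for the difference of two correlated AUCs.

    Returns ``{"auc_a", "auc_b", "z", "p", "degenerate"}``. Identical score
    vectors (zero variance, zero difference) give p = 1.0 with the
    degenerate flag set; zero variance with a nonzero difference is an
    error.
    """
    labels = ps.labels
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("DeLong test requires both classes present")
    if m + n < 10:
        warnings.warn("fewer than 10 subjects: normal approximation is crude",
                      stacklevel=2)
    v01a, v10a, auc_a = _placements(ps.scores_a, pos)
    v01b, v10b, auc_b = _placements(ps.scores_b, pos)
    delta = auc_a - auc_b
    if m > 1 and n > 1:
        s01 = np.cov(np.vstack([v01a, v01b]))
        s10 = np.cov(np.vstack([v10a, v10b]))
        var = ((s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / m
               + (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n)
    else:
        var = 0.0
    if var <= 0.0:
        if delta == 0.0:
            return {"auc_a": auc_a, "auc_b": auc_b, "z": 0.0, "p": 1.0,
                    "degenerate": True}
        raise ValueError("zero DeLong variance with nonzero AUC difference")
    z = delta / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return {"auc_a": auc_a, "auc_b": auc_b, "z": float(z), "p": float(p),
            "degenerate": False}


def diebold_mariano(pe: PairedErrors, criterion: str = "mad") -> dict:
    """Diebold-Mariano test of equal predictive accuracy (lag-0 variant).

    With the mean-absolute-deviation criterion the loss differential is
    ``d_i = |e_a,i| - |e_b,i|`` and the statistic is
    ``mean(d) / sqrt(var(d)/n)``, referred to the standard normal.
    """
    if criterion != "mad":
        raise ValueError("only the MAD criterion is implemented")
    n = len(pe.errors_a)
    if n < 10:
        warnings.warn("fewer than 10 subjects: normal approximation is crude",
                      stacklevel=2)
    d = np.abs(pe.errors_a) - np.abs(pe.errors_b)
    mean_d = d.mean()
    var_d = d.var(ddof=1)
    if var_d == 0.0:
        if mean_d == 0.0:
            return {"statistic": 0.0, "p": 1.0, "degenerate": True}
        raise ValueError("zero variance of loss differentials with nonzero mean")
    stat = mean_d / np.sqrt(var_d / n)
    p = 2.0 * norm.sf(abs(stat))
    return {"statistic": float(stat), "p": float(p), "degenerate": False}


def bootstrap_ci(metric_fn, data, n_resamples: int = 2000, seed: int = 0,
                 alpha: float = 0.05, max_redraw_factor: int = 10,
                 ) -> tuple[float, float, float]:
    """Subject-level percentile bootstrap interval for ``metric_fn(data)``.

    ``data`` is indexable (list or array of subjects); resamples on which
    the metric is undefined (raises ``ValueError``, e.g. a single-class AUC
    resample) are redrawn, up to ``max_redraw_factor * n_resamples`` total
    draws. Returns ``(point, lo, hi)``.
    """
    n = len(data)
    if n == 0:
        raise ValueError("data must be non-empty")
    point = float(metric_fn(data))
    rng = np.random.default_rng(seed)
    values = []
    failures = 0
    budget = max_redraw_factor * n_resamples
    draws = 0
    indexable = np.asarray(data, dtype=object) if isinstance(data, list) else data
    while len(values) < n_resamples:
        if draws >= budget:
            raise RuntimeError(
                f"bootstrap redraw cap exceeded: {failures}/{draws} resamples "
                "had undefined metrics")
        idx = rng.integers(0, n, size=n)
        draws += 1
        try:
            if isinstance(data, list):
                values.append(float(metric_fn([data[i] for i in idx])))
            else:
                values.append(float(metric_fn(indexable[idx])))
        except ValueError:
            failures += 1
    values = np.asarray(values)
    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return point, float(lo), float(hi)
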