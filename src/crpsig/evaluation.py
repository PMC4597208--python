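"""Discrimination and association statistics.

Confusion metrics use the clinical definitions: sensitivity is the fraction
of events (next-day CRP increased) correctly predicted as increased,
specificity the fraction of non-events correctly predicted as non-increased,
accuracy the overall fraction correct.

AUC is the rank (Mann-Whitney) estimator -- the probability that a randomly
chosen event outscores a randomly chosen non-event, ties counting one half.
Its variance comes from the paired placement-value (DeLong-type) estimator,
giving a normal-theory 95% CI truncated to [0, 1] and a two-sided p-value
against AUC = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "ROCCurve",
    "SpearmanResult",
    "GroupComparison",
    "confusion_metrics",
    "auc_rank",
    "auc_ci",
    "per_feature_auc",
    "spearman_assoc",
    "compare_groups",
    "DegenerateDataError",
]


class DegenerateDataError(ValueError):
    """Statistic undefined on this input (constant vector, single class...)."""


@dataclass(frozen=True)
class ConfusionCounts:
    true_positives: int
    false_negatives: int
    true_negatives: int
    false_positives: int

    @property
    def n(self) -> int:
        return self.true_positives + self.false_negatives + self.true_negatives + self.false_positives

    @property
    def n_events(self) -> int:
        return self.true_positives + self.false_negatives

    @property
    def n_nonevents(self) -> int:
        return self.true_negatives + self.false_positives

    @property
    def sensitivity(self) -> float:
        return self.true_positives / self.n_events

    @property
    def specificity(self) -> float:
        return self.true_negatives / self.n_nonevents

    @property
    def accuracy(self) -> float:
        return (self.true_positives + self.true_negatives) / self.n


def confusion_metrics(predicted: Sequence[bool], observed: Sequence[bool]) -> ConfusionCounts:
    """Cross-tabulate binary predictions against observed events."""
    p = np.asarray(predicted, dtype=bool)
    o = np.asarray(observed, dtype=bool)
    if p.shape != o.shape:
        raise ValueError("predicted and observed lengths differ")
    if p.size == 0:
        raise DegenerateDataError("empty input")
    if o.all() or not o.any():
        raise DegenerateDataError("observed outcomes contain a single class")
    return ConfusionCounts(
        true_positives=int((p & o).sum()),
        false_negatives=int((~p & o).sum()),
        true_negatives=int((~p & ~o).sum()),
        false_positives=int((p & ~o).sum()),
    )


def _split_scores(scores, events):
    s = np.asarray(scores, dtype=float)
    e = np.asarray(events, dtype=bool)
    if s.shape != e.shape:
        raise ValueError("scores and events lengths differ")
    if e.all() or not e.any():
        raise DegenerateDataError("both classes required for ROC analysis")
    return s[e], s[~e]


def auc_rank(scores: Sequence[float], events: Sequence[bool]) -> float:
    """Rank/Mann-Whitney AUC estimator, ties counted one half."""
    pos, neg = _split_scores(scores, events)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n1, n0 = len(pos), len(neg)
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: V10 per event, V01 per non-event."""
    v10 = np.empty(len(pos))
    for i, s in enumerate(pos):
        v10[i] = ((neg < s).sum() + 0.5 * (neg == s).sum()) / len(neg)
    v01 = np.empty(len(neg))
    for j, s in enumerate(neg):
        v01[j] = ((pos > s).sum() + 0.5 * (pos == s).sum()) / len(pos)
    return v10, v01


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    ci95: tuple[float, float]
    p_value: float
    se: float


def auc_ci(scores: Sequence[float], events: Sequence[bool]) -> ROCCurve:
    """ROC curve with DeLong-type AUC confidence interval and p vs 0.5."""
    pos, neg = _split_scores(scores, events)
    if len(pos) < 2 or len(neg) < 2:
        raise DegenerateDataError("need at least 2 members per class for a CI")
    auc = auc_rank(scores, events)
    v10, v01 = _placements(pos, neg)
    var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.975)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    if se > 0:
        p = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 1.0 if auc == 0.5 else 0.0

    # curve points: classify positive when score >= cutoff, cutoffs at the
    # distinct scores descending, with the (0,0) endpoint prepended
    s = np.concatenate([pos, neg])
    e = np.concatenate([np.ones(len(pos), bool), np.zeros(len(neg), bool)])
    cuts = np.unique(s)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for c in cuts:
        called = s >= c
        tpr.append(float((called & e).sum() / len(pos)))
        fpr.append(float((called & ~e).sum() / len(neg)))
    return ROCCurve(
        thresholds=np.concatenate([[np.inf], cuts]),
        tpr=np.asarray(tpr),
        fpr=np.asarray(fpr),
        auc=auc,
        ci95=(float(lo), float(hi)),
        p_value=p,
        se=se,
    )


def per_feature_auc(matrix, events: Sequence[bool]) -> pd.DataFrame:
    """One ROC analysis per protein, ranked by AUC (no multiplicity correction)."""
    values = matrix.values if hasattr(matrix, "values") else pd.DataFrame(matrix)
    rows = []
    for pid in values.columns:
        roc = auc_ci(values[pid].to_numpy(dtype=float), events)
        rows.append(
            {
                "protein": pid,
                "auc": roc.auc,
                "ci_low": roc.ci95[0],
                "ci_high": roc.ci95[1],
                "p_value": roc.p_value,
            }
        )
    return (
        pd.DataFrame(rows).sort_values("auc", ascending=False, kind="mergesort").reset_index(drop=True)
    )


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    ci95: tuple[float, float]
    p_value: float
    n: int


def spearman_assoc(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with a Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    if abs(rho) >= 1.0:
        ci = (rho, rho)
    else:
        z = np.arctanh(rho)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return SpearmanResult(rho=float(rho), ci95=ci, p_value=float(p), n=n)


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    p_value: float


def compare_groups(values: Sequence, group: Sequence[bool], kind: str = "auto") -> GroupComparison:
    """Two-group comparison: Mann-Whitney for continuous, Fisher's exact for binary.

    ``kind`` may be "continuous", "categorical" or "auto" (numeric dtype =>
    continuous). The Mann-Whitney test uses the tie-corrected normal
    approximation except for very small groups (both sides <= 10), where
    scipy's exact enumeration is used.
    """
    g = np.asarray(group, dtype=bool)
    v = np.asarray(values)
    if v.shape[0] != g.shape[0]:
        raise ValueError("length mismatch")
    if g.all() or not g.any():
        raise DegenerateDataError("both groups must be non-empty")
    if kind == "auto":
        kind = "continuous" if np.issubdtype(v.dtype, np.number) and len(np.unique(v)) > 2 else "categorical"

    if kind == "continuous":
        a, b = v[g].astype(float), v[~g].astype(float)
        method = "exact" if max(len(a), len(b)) <= 10 else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return GroupComparison(test="mann-whitney", statistic=float(res.statistic), p_value=float(res.pvalue))

    levels = pd.unique(pd.Series(v))
    if len(levels) != 2:
        raise ValueError(f"Fisher's exact needs a binary category, got {len(levels)} levels")
    table = [
        [int(((v == levels[0]) & g).sum()), int(((v == levels[1]) & g).sum())],
        [int(((v == levels[0]) & ~g).sum()), int(((v == levels[1]) & ~g).sum())],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return GroupComparison(test="fisher-exact", statistic=float(odds), p_value=float(p))
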