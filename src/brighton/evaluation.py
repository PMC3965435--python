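"""Screening-performance evaluation: sensitivity/specificity with exact
binomial confidence intervals, ROC curves, and rank-statistic AUC with a
DeLong interval.

Conventions: the positive class is the gold label ``case``; proportions
get Clopper–Pearson (exact binomial) intervals; the AUC is the
Mann–Whitney statistic (ties count one half) with its variance estimated
by DeLong's placement method.  The choice of interval methods is recorded
in the output of :func:`compare_methods` so downstream tables are
self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from brighton.core_model import CASE


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    calls: Mapping[str, bool], labels: Mapping[str, str]
) -> ConfusionCounts:
    """Cross-tabulate binary calls against gold labels (positive = case).

    Raises ``ValueError`` if the two id sets differ.
    """
    if set(calls) != set(labels):
        only_calls = sorted(set(calls) - set(labels))[:5]
        only_labels = sorted(set(labels) - set(calls))[:5]
        raise ValueError(
            f"call/label id mismatch; calls-only={only_calls}, labels-only={only_labels}"
        )
    tp = fp = tn = fn = 0
    for rid, call in calls.items():
        is_case = labels[rid] == CASE
        if call and is_case:
            tp += 1
        elif call and not is_case:
            fp += 1
        elif not call and is_case:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Clopper–Pearson) interval for a proportion k/n,
    via beta-distribution quantiles."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def sens_spec_ci(counts: ConfusionCounts, level: float = 0.95) -> dict:
    """Sensitivity and specificity with exact binomial CIs.

    Raises ``ValueError`` naming the empty class if the corpus lacks
    positives (tp+fn = 0) or negatives (tn+fp = 0).
    """
    n_pos = counts.tp + counts.fn
    n_neg = counts.tn + counts.fp
    if n_pos == 0:
        raise ValueError("no positive reports: sensitivity undefined")
    if n_neg == 0:
        raise ValueError("no negative reports: specificity undefined")
    return {
        "sensitivity": counts.tp / n_pos,
        "sensitivity_ci": clopper_pearson(counts.tp, n_pos, level),
        "specificity": counts.tn / n_neg,
        "specificity_ci": clopper_pearson(counts.tn, n_neg, level),
        "ci_method": "clopper_pearson",
        "level": level,
    }


# --- ROC / AUC -----------------------------------------------------------


@dataclass(frozen=True)
class RocCurve:
    """Threshold sweep over distinct scores, with (fpr, tpr) per cut.

    The sweep starts at (0, 0) (call nothing) and ends at (1, 1) (call
    everything); both rates are non-decreasing along it.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _as_arrays(
    scores: Mapping[str, float] | Sequence[float],
    labels: Mapping[str, str] | Sequence[bool],
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(scores, Mapping):
        if set(scores) != set(labels):
            raise ValueError("score/label id mismatch")
        ids = sorted(scores)
        s = np.array([float(scores[i]) for i in ids])
        y = np.array([labels[i] == CASE for i in ids])
    else:
        s = np.asarray(scores, dtype=float)
        if isinstance(labels, Mapping):
            raise ValueError("labels must be a sequence when scores are")
        y = np.asarray(
            [l == CASE if isinstance(l, str) else bool(l) for l in labels]
        )
        if len(s) != len(y):
            raise ValueError("scores and labels differ in length")
    if not y.any() or y.all():
        raise ValueError("ROC needs both classes represented")
    return s, y


def rank_auc(scores, labels) -> float:
    """AUC as the Mann–Whitney rank statistic: the probability a random
    positive outscores a random negative, ties counting one half."""
    s, y = _as_arrays(scores, labels)
    ranks = stats.rankdata(s)  # midranks handle ties
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    rank_sum = float(ranks[y].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_curve_points(scores, labels) -> RocCurve:
    """ROC curve by sweeping the distinct scores as thresholds
    (call = score >= threshold), AUC by the rank statistic."""
    s, y = _as_arrays(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    cuts = np.unique(s)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    thresholds = [np.inf]
    for t in cuts:
        calls = s >= t
        tpr.append((calls & y).sum() / n_pos)
        fpr.append((calls & ~y).sum() / n_neg)
        thresholds.append(float(t))
    return RocCurve(
        thresholds=np.array(thresholds),
        fpr=np.array(fpr),
        tpr=np.array(tpr),
        auc=rank_auc(s, y),
    )


def _delong_variance(s: np.ndarray, y: np.ndarray) -> float:
    """DeLong's placement-based variance estimate of the AUC."""
    pos = s[y]
    neg = s[~y]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array(
        [((p > neg).sum() + 0.5 * (p == neg).sum()) / n for p in pos]
    )
    v01 = np.array(
        [((pos > q).sum() + 0.5 * (pos == q).sum()) / m for q in neg]
    )
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc_ci(scores, labels, level: float = 0.95) -> tuple[RocCurve, tuple]:
    """ROC curve plus a DeLong confidence interval for its AUC."""
    s, y = _as_arrays(scores, labels)
    curve = roc_curve_points(s, y)
    var = _delong_variance(s, y)
    z = float(stats.norm.ppf(0.5 + level / 2))
    half = z * np.sqrt(var)
    ci = (max(0.0, curve.auc - half), min(1.0, curve.auc + half))
    return curve, ci


def roc_to_frame(curve: RocCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {"threshold": curve.thresholds, "fpr": curve.fpr, "tpr": curve.tpr}
    )


# --- method comparison ---------------------------------------------------


def compare_methods(
    labels: Mapping[str, str],
    methods: Mapping[str, Mapping],
    level: float = 0.95,
) -> pd.DataFrame:
    """One row per classification method, mirroring a published
    methods-comparison table: sensitivity/specificity (with CIs) where
    the method makes binary calls, AUC (with CI) where it scores.

    ``methods`` maps a method name to a dict with keys ``calls``
    (report_id -> bool) and/or ``scores`` (report_id -> float).
    """
    rows = []
    for name, output in methods.items():
        row: dict = {"method": name}
        calls = output.get("calls")
        scores = output.get("scores")
        if calls is not None:
            metrics = sens_spec_ci(confusion(calls, labels), level=level)
            row.update(
                sensitivity=metrics["sensitivity"],
                sensitivity_ci_low=metrics["sensitivity_ci"][0],
                sensitivity_ci_high=metrics["sensitivity_ci"][1],
                specificity=metrics["specificity"],
                specificity_ci_low=metrics["specificity_ci"][0],
                specificity_ci_high=metrics["specificity_ci"][1],
            )
        if scores is not None:
            curve, ci = roc_auc_ci(scores, labels, level=level)
            row.update(auc=curve.auc, auc_ci_low=ci[0], auc_ci_high=ci[1])
        rows.append(row)
    columns = [
        "method",
        "sensitivity",
        "sensitivity_ci_low",
        "sensitivity_ci_high",
        "specificity",
        "specificity_ci_low",
        "specificity_ci_high",
        "auc",
        "auc_ci_low",
        "auc_ci_high",
    ]
    frame = pd.DataFrame(rows)
    for col in columns:
        if col not in frame.columns:
            frame[col] = np.nan
    frame.attrs["proportion_ci"] = "clopper_pearson"
    frame.attrs["auc_ci"] = "delong"
    frame.attrs["level"] = level
    return frame[columns]
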