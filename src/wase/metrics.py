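"""Diagnostic evaluation statistics.

ROC/AUC with midrank tie handling, the Youden-J operating threshold,
confusion-matrix metrics, stratified percentile-bootstrap confidence
intervals, the unpaired DeLong comparison of two AUCs, and the
Hosmer-Lemeshow calibration test.

Conventions used throughout: classification is positive iff score is
STRICTLY greater than the threshold, and undefined ratios (zero
denominator) are reported as ``None`` rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "MetricReport",
    "DeLongResult",
    "CalibrationTable",
    "roc_auc",
    "roc_curve",
    "youden_threshold",
    "confusion_metrics",
    "bootstrap_ci",
    "delong_test",
    "hosmer_lemeshow",
]


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return scores, labels.astype(int)


def _require_both_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("need at least one case and one control")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class RocCurve:
    """Operating points swept over descending thresholds (strict > rule)."""

    thresholds: np.ndarray  # descending; last entry -inf (everyone positive)
    tpr: np.ndarray
    fpr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


@dataclass
class MetricReport:
    """Point diagnostic metrics with optional bootstrap CIs.

    Metrics with a zero denominator are ``None``; ``ci`` maps metric name to
    a (lo, hi) percentile interval when computed.
    """

    auc: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    threshold: float
    n_cases: int
    n_controls: int
    counts: ConfusionCounts
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "threshold": self.threshold,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "counts": vars(self.counts),
            "ci": {k: list(v) for k, v in self.ci.items()},
        }
        return d


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p_value: float

    def to_dict(self) -> dict:
        return vars(self)


@dataclass
class CalibrationTable:
    """Hosmer-Lemeshow bins plus the chi-square summary."""

    bins: pd.DataFrame  # columns: n, mean_pred, observed_rate, o1, e1, o0, e0
    chi2: float
    df: int
    p_value: float
    merged_bins: int = 0

    def to_dict(self) -> dict:
        return {
            "bins": self.bins.to_dict(orient="records"),
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "merged_bins": self.merged_bins,
        }


def roc_auc(scores, labels) -> float:
    """AUC via the Mann-Whitney rank-sum with midrank tie correction.

    Identical to brute-force pair counting (wins + half ties over all
    case-control pairs).
    """
    scores, labels = _validate(scores, labels)
    _require_both_classes(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_curve(scores, labels) -> RocCurve:
    """Full ROC sweep: one operating point per distinct score, plus (1, 1)."""
    scores, labels = _validate(scores, labels)
    _require_both_classes(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    starts = np.flatnonzero(np.r_[True, s[1:] != s[:-1]])
    cum_tp = np.concatenate(([0], np.cumsum(y)))
    cum_fp = np.concatenate(([0], np.cumsum(1 - y)))
    thresholds = np.concatenate((s[starts], [-np.inf]))
    tp = np.concatenate((cum_tp[starts], [n1]))
    fp = np.concatenate((cum_fp[starts], [n0]))
    return RocCurve(thresholds=thresholds, tpr=tp / n1, fpr=fp / n0)


def youden_threshold(roc: RocCurve) -> float:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the higher sensitivity, then the lower threshold.
    """
    if len(roc.thresholds) == 0:
        raise ValueError("empty ROC curve")
    j = roc.tpr - roc.fpr
    best = max(
        range(len(j)),
        key=lambda i: (j[i], roc.tpr[i], -roc.thresholds[i]),
    )
    return float(roc.thresholds[best])


def confusion_metrics(scores, labels, threshold: float) -> MetricReport:
    """Point metrics at a fixed threshold (positive iff score > threshold)."""
    scores, labels = _validate(scores, labels)
    if not np.isfinite(threshold) and threshold != -np.inf:
        raise ValueError(f"threshold must be finite or -inf, got {threshold}")
    pred = scores > threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)

    def ratio(num: int, denom: int) -> float | None:
        return num / denom if denom > 0 else None

    n1, n0 = tp + fn, tn + fp
    auc = roc_auc(scores, labels) if (n1 > 0 and n0 > 0) else None
    return MetricReport(
        auc=auc,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        accuracy=ratio(tp + tn, counts.n),
        threshold=float(threshold),
        n_cases=n1,
        n_controls=n0,
        counts=counts,
    )


def bootstrap_ci(
    statistic: Callable[[np.ndarray, np.ndarray], float],
    scores,
    labels,
    B: int = 2000,
    seed: int | None = None,
    *,
    alpha: float = 0.05,
    max_retries: int = 100,
) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for a scores/labels statistic.

    Cases and controls are resampled separately (preserving their counts);
    a resample on which the statistic is undefined is redrawn, up to
    ``max_retries`` times.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    scores, labels = _validate(scores, labels)
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(labels == 1)
    ctrl_idx = np.flatnonzero(labels == 0)
    vals = np.empty(B)
    for b in range(B):
        for _ in range(max_retries):
            idx = np.concatenate(
                (
                    rng.choice(case_idx, size=len(case_idx), replace=True),
                    rng.choice(ctrl_idx, size=len(ctrl_idx), replace=True),
                )
            )
            try:
                v = statistic(scores[idx], labels[idx])
            except (ValueError, ZeroDivisionError):
                continue
            if v is not None and np.isfinite(v):
                vals[b] = v
                break
        else:
            raise RuntimeError(
                f"statistic undefined on {max_retries} consecutive resamples"
            )
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _placements(scores: np.ndarray, labels: np.ndarray):
    """Placement values: per-case and per-control win + half-tie rates."""
    cases = scores[labels == 1]
    ctrls = scores[labels == 0]
    diff = cases[:, None] - ctrls[None, :]
    wins = diff > 0
    ties = diff == 0
    v10 = wins.mean(axis=1) + 0.5 * ties.mean(axis=1)  # one per case
    v01 = wins.mean(axis=0) + 0.5 * ties.mean(axis=0)  # one per control
    return v10, v01


def delong_test(scores_a, labels_a, scores_b, labels_b) -> DeLongResult:
    """Unpaired DeLong comparison of two AUCs from independent samples.

    Each AUC's variance comes from the structural-components (placement
    value) estimator: var = S10/m + S01/n with S10, S01 the sample variances
    of the case and control placements.
    """
    scores_a, labels_a = _validate(scores_a, labels_a)
    scores_b, labels_b = _validate(scores_b, labels_b)
    _require_both_classes(labels_a)
    _require_both_classes(labels_b)

    def auc_var(scores, labels):
        v10, v01 = _placements(scores, labels)
        auc = float(v10.mean())
        var = 0.0
        if len(v10) > 1:
            var += float(np.var(v10, ddof=1)) / len(v10)
        if len(v01) > 1:
            var += float(np.var(v01, ddof=1)) / len(v01)
        return auc, var

    auc_a, var_a = auc_var(scores_a, labels_a)
    auc_b, var_b = auc_var(scores_b, labels_b)
    se = np.sqrt(var_a + var_b)
    if se == 0:
        raise ValueError("degenerate placement variance; DeLong test undefined")
    z = (auc_a - auc_b) / se
    p = float(2 * norm.sf(abs(z)))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, z=float(z), p_value=p)


def hosmer_lemeshow(probs, outcomes, g: int = 10) -> CalibrationTable:
    """Hosmer-Lemeshow goodness-of-fit over g risk-ordered bins.

    Participants are sorted by predicted probability and split into g
    equal-count bins (largest-remainder sizing, tied probabilities kept in
    one bin).  A bin with zero expected events or non-events is merged into
    its neighbour.  chi2 sums (O-E)^2/E over events and non-events;
    df = bins - 2.
    """
    probs, outcomes = _validate(probs, outcomes)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if g < 2:
        raise ValueError("need at least two bins")
    n = len(probs)
    if g > n:
        raise ValueError("more bins than observations")
    order = np.argsort(probs, kind="stable")
    p = probs[order]
    y = outcomes[order]
    base, rem = divmod(n, g)
    sizes = [base + 1] * rem + [base] * (g - rem)
    edges = list(np.cumsum(sizes)[:-1])
    # keep tied probabilities together: push each edge past the tie run
    pushed = []
    for e in edges:
        while 0 < e < n and p[e] == p[e - 1]:
            e += 1
        if e < n:
            pushed.append(e)
    edges = sorted(set(pushed))
    bounds = [0] + edges + [n]

    rows = []
    for i, j in zip(bounds[:-1], bounds[1:]):
        nk = j - i
        e1 = float(p[i:j].sum())
        o1 = float(y[i:j].sum())
        rows.append(
            {
                "n": nk,
                "mean_pred": float(p[i:j].mean()),
                "observed_rate": o1 / nk,
                "o1": o1,
                "e1": e1,
                "o0": nk - o1,
                "e0": nk - e1,
            }
        )

    # merge bins whose expected events or non-events vanish
    merged = 0
    k = 0
    while k < len(rows):
        if len(rows) > 1 and (rows[k]["e1"] == 0 or rows[k]["e0"] == 0):
            j = k + 1 if k + 1 < len(rows) else k - 1
            a, b = rows[min(k, j)], rows[max(k, j)]
            nk = a["n"] + b["n"]
            combined = {
                "n": nk,
                "mean_pred": (a["mean_pred"] * a["n"] + b["mean_pred"] * b["n"]) / nk,
                "observed_rate": (a["o1"] + b["o1"]) / nk,
                "o1": a["o1"] + b["o1"],
                "e1": a["e1"] + b["e1"],
                "o0": a["o0"] + b["o0"],
                "e0": a["e0"] + b["e0"],
            }
            rows[min(k, j)] = combined
            del rows[max(k, j)]
            merged += 1
            k = 0  # re-scan from the start after a merge
        else:
            k += 1

    chi2 = 0.0
    for r in rows:
        chi2 += (r["o1"] - r["e1"]) ** 2 / r["e1"] + (r["o0"] - r["e0"]) ** 2 / r["e0"]
    df = len(rows) - 2
    p_value = float(chi2_dist.sf(chi2, df)) if df >= 1 else float("nan")
    return CalibrationTable(
        bins=pd.DataFrame(rows),
        chi2=float(chi2),
        df=df,
        p_value=p_value,
        merged_bins=merged,
    )
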