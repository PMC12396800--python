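"""Evaluation: ranking metrics, threshold metrics, percentile-bootstrap
confidence intervals, and the ICD-code baseline contingency table.

Definitions are pinned down exactly because they are the package's
reporting contract:

* AUROC is the probability that a random positive outscores a random
  negative, counting ties as 1/2 — computed by the tie-corrected rank
  formula, which equals the literal pairwise count.
* AUPRC is step-wise average precision: with thresholds swept over the
  distinct scores in descending order, ``sum_i (R_i - R_{i-1}) * P_i``.
  No trapezoidal interpolation in PR space (it flatters the curve).
* Threshold metrics call a note positive when ``score >= threshold``.
  An undefined ratio (e.g. precision with no predicted positives) is
  reported as ``None``, never silently as 0.
* Bootstrap CIs are percentile-based: the 2.5th/50th/97.5th percentiles of
  the metric over ``B`` resamples of note indices drawn with replacement;
  a resample containing a single class is redrawn and the redraw count
  reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .corpus import ClinicalNote

logger = logging.getLogger(__name__)

__all__ = [
    "rank_metrics",
    "threshold_metrics",
    "bootstrap_ci",
    "icd_baseline",
    "Contingency",
    "EvalReport",
    "evaluate_scores",
    "roc_curve_points",
    "pr_curve_points",
]

RANK_METRICS = ("auroc", "auprc")
THRESHOLD_METRICS = ("f1", "recall", "precision", "specificity")


def _check_labels(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")


def rank_metrics(scores: Sequence[float], labels: Sequence[bool]) -> dict[str, float]:
    """AUROC (tie-corrected rank statistic) and AUPRC (average precision)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    _check_labels(y)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos

    ranks = rankdata(s)  # average ranks handle ties -> pairwise 1/2 credit
    auroc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # Average precision over distinct thresholds, descending.
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # last index of each tie block = positions where the next score differs
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp_d = tp[distinct]
    fp_d = fp[distinct]
    recall = tp_d / n_pos
    precision = tp_d / (tp_d + fp_d)
    auprc = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return {"auroc": float(auroc), "auprc": auprc}


def threshold_metrics(
    scores: Sequence[float],
    labels: Sequence[bool],
    threshold: float = 0.5,
) -> dict[str, float | None]:
    """F1, recall, precision, specificity at ``score >= threshold``."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_labels(y)
    call = s >= threshold
    tp = int((call & y).sum())
    fp = int((call & ~y).sum())
    fn = int((~call & y).sum())
    tn = int((~call & ~y).sum())
    recall = tp / (tp + fn)
    specificity = tn / (tn + fp)
    if tp + fp == 0:
        logger.warning("no predicted positives at threshold %.3g; "
                       "precision and F1 undefined", threshold)
        precision = None
        f1 = None
    else:
        precision = tp / (tp + fp)
        f1 = (
            0.0
            if precision + recall == 0
            else 2 * precision * recall / (precision + recall)
        )
    return {"f1": f1, "recall": recall, "precision": precision,
            "specificity": specificity}


def _metric_fn(metric: str, threshold: float) -> Callable:
    if metric in RANK_METRICS:
        return lambda s, y: rank_metrics(s, y)[metric]
    if metric in THRESHOLD_METRICS:
        return lambda s, y: threshold_metrics(s, y, threshold)[metric]
    raise ValueError(f"unknown metric {metric!r}")


def bootstrap_ci(
    scores: Sequence[float],
    labels: Sequence[bool],
    metric: str,
    B: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict[str, float | int]:
    """Percentile bootstrap of one metric over note resamples.

    Returns the bootstrap median and 95% CI bounds plus ``n_redrawn``, the
    number of resamples rejected (single class, or metric undefined on the
    resample) and redrawn so that ``B`` effective draws remain.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    fn = _metric_fn(metric, threshold)
    fn(s, y)  # must be computable on the full sample
    rng = np.random.default_rng(seed)
    n = s.size
    values = np.empty(B)
    redrawn = 0
    for b in range(B):
        for _ in range(1000):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if not yb.any() or yb.all():
                redrawn += 1
                continue
            v = fn(s[idx], yb)
            if v is None:
                redrawn += 1
                continue
            values[b] = v
            break
        else:
            raise RuntimeError(f"metric {metric!r} never computable on resamples")
    lo, med, hi = np.percentile(values, [2.5, 50.0, 97.5])
    if redrawn:
        logger.info("bootstrap(%s): %d resamples redrawn", metric, redrawn)
    return {"median": float(med), "ci_low": float(lo), "ci_high": float(hi),
            "n_redrawn": redrawn}


@dataclass(frozen=True)
class Contingency:
    """2x2 table of a binary flag against the expert label."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be >= 0")

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv,
        }


def icd_baseline(notes: Sequence[ClinicalNote]) -> Contingency:
    """Contingency of the ICD-flag proxy against the expert label.

    This is the "billing codes alone" baseline the NLP model is measured
    against: high sensitivity, poor specificity in the study regime.
    """
    missing = [n.note_id for n in notes if n.label is None]
    if missing:
        raise ValueError(f"notes missing expert labels: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    tp = sum(1 for n in notes if n.label and n.icd_nid_flag)
    fp = sum(1 for n in notes if not n.label and n.icd_nid_flag)
    fn = sum(1 for n in notes if n.label and not n.icd_nid_flag)
    tn = sum(1 for n in notes if not n.label and not n.icd_nid_flag)
    return Contingency(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class EvalReport:
    """Point metrics with bootstrap medians and 95% CIs for one test set."""

    metrics: dict[str, dict]  # name -> {point, bootstrap_median, ci_low, ci_high}
    n_notes: int
    n_positive: int
    B: int
    seed: int
    threshold: float = 0.5
    n_redrawn: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "metrics": self.metrics,
                "n_notes": self.n_notes,
                "n_positive": self.n_positive,
                "B": self.B,
                "seed": self.seed,
                "threshold": self.threshold,
                "n_redrawn": self.n_redrawn,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload + "\n", encoding="utf-8")
        return payload

    def table(self) -> str:
        """Human-readable metric table, one row per metric."""
        lines = [
            f"Evaluation on {self.n_notes} notes "
            f"({self.n_positive} positive), B={self.B}",
            f"{'Metric':<13}{'Point':>8}  Median (95% CI)",
        ]
        for name in RANK_METRICS + THRESHOLD_METRICS:
            m = self.metrics.get(name)
            if m is None:
                continue
            pt = "   n/a" if m["point"] is None else f"{m['point']:6.3f}"
            lines.append(
                f"{name:<13}{pt:>8}  {m['bootstrap_median']:.3f} "
                f"({m['ci_low']:.3f}-{m['ci_high']:.3f})"
            )
        return "\n".join(lines)


def evaluate_scores(
    scores: Sequence[float],
    labels: Sequence[bool],
    threshold: float = 0.5,
    B: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Full report: point value + percentile-bootstrap summary for AUROC,
    AUPRC, F1, recall, precision, and specificity."""
    y = np.asarray(labels, dtype=bool)
    points: dict[str, float | None] = dict(rank_metrics(scores, labels))
    points.update(threshold_metrics(scores, labels, threshold))
    metrics = {}
    redrawn = 0
    for name, pt in points.items():
        boot = bootstrap_ci(scores, labels, name, B=B, seed=seed, threshold=threshold)
        redrawn += int(boot["n_redrawn"])
        metrics[name] = {
            "point": pt,
            "bootstrap_median": boot["median"],
            "ci_low": boot["ci_low"],
            "ci_high": boot["ci_high"],
        }
    return EvalReport(
        metrics=metrics,
        n_notes=int(y.size),
        n_positive=int(y.sum()),
        B=B,
        seed=seed,
        threshold=threshold,
        n_redrawn=redrawn,
    )


def roc_curve_points(scores, labels) -> "np.ndarray":
    """(fpr, tpr) pairs at each distinct threshold, for CSV export."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_labels(y)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    distinct = np.r_[s[order][1:] != s[order][:-1], True]
    fpr = np.r_[0.0, fp[distinct] / (~y).sum()]
    tpr = np.r_[0.0, tp[distinct] / y.sum()]
    return np.column_stack([fpr, tpr])


def pr_curve_points(scores, labels) -> "np.ndarray":
    """(recall, precision) pairs at each distinct threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_labels(y)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    distinct = np.r_[s[order][1:] != s[order][:-1], True]
    recall = tp[distinct] / y.sum()
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    return np.column_stack([recall, precision])
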