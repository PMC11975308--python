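"""Scan-level evaluation: discrimination metrics with uncertainty, paired
AUROC comparison (DeLong), and subgroup / per-grade breakdowns.

All metrics are computed at the individual-scan level: each scan's risk is
scored against that scan's own label, whether the risk came from a single
scan or from the scan-2 composition.  Undefined metrics (a cell lacking both
classes, or lacking positives for average precision) are reported as
``None`` — never silently as 0 or 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .cohort_prep import PairSet

__all__ = [
    "UndefinedMetricError",
    "auroc",
    "auprc",
    "bootstrap_ci",
    "delong_pvalue",
    "delong_auc_variance",
    "SubgroupSpec",
    "build_subgroups",
    "per_grade_auroc",
    "evaluate_predictions",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value on the given labels."""


def _check_labels_scores(labels, scores):
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D arrays")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be binary")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return labels.astype(int), scores


def auroc(labels, scores) -> float:
    """Mann-Whitney AUROC: probability a random positive outranks a random
    negative, ties counted one half."""
    labels, scores = _check_labels_scores(labels, scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC needs both classes")
    ranks = rankdata(scores)  # mid-ranks handle ties as 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(labels, scores) -> float:
    """Step-wise area under precision-recall (average precision).

    Computed over unique score thresholds in descending order:
    ``AP = sum_k (R_k - R_{k-1}) * P_k``.
    """
    labels, scores = _check_labels_scores(labels, scores)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise UndefinedMetricError("average precision needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # collapse tied scores: keep the last index of each distinct threshold
    last_of_threshold = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp = tp[last_of_threshold]
    fp = fp[last_of_threshold]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    d_recall = np.diff(np.r_[0.0, recall])
    return float(np.sum(d_recall * precision))


def bootstrap_ci(metric, labels, scores, n_boot=1000, level=0.95, seed=0):
    """Percentile bootstrap interval for a scan-level metric.

    Resamples scans with replacement; resamples on which the metric is
    undefined (e.g. one class only) are skipped and counted.  Returns
    ``(lower, upper, n_skipped)``; deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    labels, scores = _check_labels_scores(labels, scores)
    rng = np.random.default_rng([int(seed), 977])
    n = labels.size
    values = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(metric(labels[idx], scores[idx]))
        except UndefinedMetricError:
            skipped += 1
    if not values:
        raise UndefinedMetricError("metric undefined on every bootstrap resample")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi), skipped


def _structural_components(labels, scores):
    """DeLong placement values: V10 per positive, V01 per negative."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    cmp_matrix = (pos[:, None] > neg[None, :]).astype(float)
    cmp_matrix += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_matrix.mean(axis=1)
    v01 = cmp_matrix.mean(axis=0)
    return v10, v01


def delong_auc_variance(labels, scores_a, scores_b):
    """AUCs, their difference and its DeLong variance for paired scores."""
    labels = np.asarray(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (labels.shape == a.shape == b.shape):
        raise ValueError("labels, scores_a, scores_b must have equal length")
    labels, a = _check_labels_scores(labels, a)
    _, b = _check_labels_scores(labels, b)
    m = int(labels.sum())
    n = labels.size - m
    if m == 0 or n == 0:
        raise UndefinedMetricError("DeLong needs both classes")
    v10_a, v01_a = _structural_components(labels, a)
    v10_b, v01_b = _structural_components(labels, b)
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())
    if m > 1:
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    return auc_a, auc_b, auc_a - auc_b, float(max(var, 0.0))


def delong_pvalue(labels, scores_a, scores_b) -> float:
    """Two-sided DeLong test for the difference of two correlated AUROCs.

    Variance of the AUC difference is estimated from the structural
    components of the paired predictors; the test statistic is referred to
    the standard normal.  A zero-variance difference of exactly zero
    (identical predictors) returns p = 1.
    """
    _, _, delta, var = delong_auc_variance(labels, scores_a, scores_b)
    if var == 0.0:
        return 1.0 if delta == 0.0 else 0.0
    z = delta / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


@dataclass(frozen=True)
class SubgroupSpec:
    """Index sets over evaluated scans, keyed by the pair's progression set.

    Cohort 1 = progression pairs (Set 1); Cohort 2 = Set 1 + stable-negative
    (Set 2); Cohort 3 = Set 1 + stable-positive (Set 3); Cohort 4 = Set 2 +
    Set 3.  Single-scan subjects are excluded throughout.
    """

    cohort1: tuple
    cohort2: tuple
    cohort3: tuple
    cohort4: tuple

    def as_dict(self):
        return {
            "cohort1": self.cohort1,
            "cohort2": self.cohort2,
            "cohort3": self.cohort3,
            "cohort4": self.cohort4,
        }


def build_subgroups(set_ids) -> SubgroupSpec:
    """Subgroup index sets from per-scan progression-set labels.

    ``set_ids``: sequence of :class:`PairSet` (or their string values), one
    per evaluated scan (both scans of a pair carry the pair's set).
    """
    sets = [PairSet(s) for s in set_ids]
    idx = {
        ps: tuple(i for i, s in enumerate(sets) if s is ps)
        for ps in (PairSet.SET1_PROGRESSION, PairSet.SET2_STABLE_NEG, PairSet.SET3_STABLE_POS)
    }
    s1 = idx[PairSet.SET1_PROGRESSION]
    s2 = idx[PairSet.SET2_STABLE_NEG]
    s3 = idx[PairSet.SET3_STABLE_POS]
    return SubgroupSpec(
        cohort1=s1,
        cohort2=tuple(sorted(s1 + s2)),
        cohort3=tuple(sorted(s1 + s3)),
        cohort4=tuple(sorted(s2 + s3)),
    )


def per_grade_auroc(labels, scores, grades):
    """AUROC within each severity grade 0-4; ``None`` where undefined."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    grades = np.asarray(grades, dtype=int)
    if not np.all((grades >= 0) & (grades <= 4)):
        raise ValueError("grades must lie in 0..4")
    out = {}
    for g in range(5):
        mask = grades == g
        try:
            out[g] = auroc(labels[mask], scores[mask]) if mask.any() else None
        except UndefinedMetricError:
            out[g] = None
    return out


def _safe(metric, labels, scores):
    try:
        return metric(labels, scores)
    except UndefinedMetricError:
        return None


def evaluate_predictions(pred: pd.DataFrame, n_boot=1000, seed=0, contrasts=(),
                         subgroup_horizon=None) -> dict:
    """Full scan-level evaluation report.

    ``pred`` columns: subject_id, scan_index, horizon, formulation, risk,
    label, grade, set_id.  ``contrasts`` are (formulation_a, formulation_b)
    pairs compared with the DeLong test on identical scans.
    ``subgroup_horizon`` selects the horizon for the subgroup and per-grade
    analyses (default: the largest present).
    """
    report: dict = {"metrics": {}, "delong": {}, "subgroups": {}, "per_grade": {}}
    horizons = sorted(pred["horizon"].unique())
    if subgroup_horizon is None and horizons:
        subgroup_horizon = horizons[-1]
    for h in horizons:
        at_h = pred[pred["horizon"] == h]
        for form in sorted(at_h["formulation"].unique()):
            cell = at_h[at_h["formulation"] == form]
            y = cell["label"].to_numpy(dtype=int)
            s = cell["risk"].to_numpy(dtype=float)
            entry = {
                "n_scans": int(len(cell)),
                "n_positive": int(y.sum()),
                "auroc": _safe(auroc, y, s),
                "auprc": _safe(auprc, y, s),
            }
            if entry["auroc"] is not None:
                lo, hi, _ = bootstrap_ci(auroc, y, s, n_boot=n_boot, seed=seed)
                entry["auroc_ci"] = [lo, hi]
            if entry["auprc"] is not None:
                lo, hi, _ = bootstrap_ci(auprc, y, s, n_boot=n_boot, seed=seed)
                entry["auprc_ci"] = [lo, hi]
            report["metrics"].setdefault(f"h{h:g}", {})[str(form)] = entry

        for form_a, form_b in contrasts:
            key_cols = ["subject_id", "scan_index"]
            a = at_h[at_h["formulation"] == form_a].set_index(key_cols)
            b = at_h[at_h["formulation"] == form_b].set_index(key_cols)
            common = a.index.intersection(b.index)
            if len(common) == 0:
                continue
            y = a.loc[common, "label"].to_numpy(dtype=int)
            p = delong_pvalue(
                y,
                a.loc[common, "risk"].to_numpy(dtype=float),
                b.loc[common, "risk"].to_numpy(dtype=float),
            )
            report["delong"].setdefault(f"h{h:g}", {})[f"{form_a}_vs_{form_b}"] = p

    if subgroup_horizon is not None:
        at_h = pred[pred["horizon"] == subgroup_horizon]
        for form in sorted(at_h["formulation"].unique()):
            cell = at_h[
                (at_h["formulation"] == form)
                & (at_h["set_id"] != PairSet.SINGLE.value)
            ].reset_index(drop=True)
            spec = build_subgroups(cell["set_id"])
            y = cell["label"].to_numpy(dtype=int)
            s = cell["risk"].to_numpy(dtype=float)
            sub = {}
            for name, idx in spec.as_dict().items():
                idx = np.asarray(idx, dtype=int)
                sub[name] = {
                    "n_scans": int(idx.size),
                    "auroc": _safe(auroc, y[idx], s[idx]) if idx.size else None,
                    "auprc": _safe(auprc, y[idx], s[idx]) if idx.size else None,
                }
            report["subgroups"][str(form)] = sub
            report["per_grade"][str(form)] = {
                str(g): v
                for g, v in per_grade_auroc(
                    y, s, cell["grade"].to_numpy(dtype=int)
                ).items()
            }
        report["subgroup_horizon"] = float(subgroup_horizon)
    return report
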