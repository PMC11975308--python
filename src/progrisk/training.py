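"""Fold-level training and ensembled scan-level prediction.

Thin orchestration over :class:`progrisk.estimators.PairedRiskClassifier`:
assembling (scan1, scan2) payload arrays from prepared pair samples,
training one model per nested-CV assignment, ensembling member risks by
arithmetic mean, and producing the long-format scan-level prediction table
that :mod:`progrisk.evaluation` consumes.

The nested protocol: 7 outer x 6 inner subject
folds; each outer test fold is predicted by the ensemble of its 6 inner
models, so the whole cohort receives out-of-sample predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_prep import PairSample, SplitPlan
from .estimators import PairedRiskClassifier

__all__ = [
    "FittedModel",
    "EnsemblePrediction",
    "pairs_to_arrays",
    "train_fold",
    "predict_scan_risks",
    "ensemble_predict",
    "run_nested_training",
    "PREDICTION_COLUMNS",
]

PREDICTION_COLUMNS = [
    "subject_id", "scan_index", "horizon", "formulation",
    "risk", "label", "grade", "set_id",
]

#: approach name -> (formulation, reg_mode) for the comparison table rows:
#: the two progressive compositions, the unconstrained baseline, and the
#: baseline with soft-constraint penalties added.
APPROACHES = {
    "baseline": ("baseline", "none"),
    "riskreg": ("baseline", "riskreg"),
    "conreg": ("baseline", "conreg"),
    "conreg+riskreg": ("baseline", "both"),
    "riskform1": ("riskform1", "none"),
    "riskform2": ("riskform2", "none"),
}


def resolve_approach(name):
    """Map an approach name to its (formulation, reg_mode) pair."""
    name = str(name)
    if name not in APPROACHES:
        raise ValueError(
            f"unknown approach {name!r}; choose from {sorted(APPROACHES)}"
        )
    return APPROACHES[name]


@dataclass
class FittedModel:
    """A trained estimator plus the identity of its data slice."""

    estimator: PairedRiskClassifier
    formulation: str
    horizon: float
    outer_fold: int | None = None
    inner_fold: int | None = None

    @property
    def hyperparameters(self) -> dict:
        return self.estimator.get_params()


@dataclass(frozen=True)
class EnsemblePrediction:
    """Per-scan ensemble risk: the arithmetic mean of member risks."""

    risk: float
    member_risks: tuple

    def __post_init__(self) -> None:
        if not self.member_risks:
            raise ValueError("ensemble needs at least one member risk")
        if not np.isclose(self.risk, float(np.mean(self.member_risks))):
            raise ValueError("ensemble risk must equal the member mean")

    @property
    def n_members(self) -> int:
        return len(self.member_risks)


def pairs_to_arrays(pairs, payloads):
    """Stack pair samples into estimator input.

    Returns ``(X, y, meta)``: ``X`` of shape (n, 2, ...) with NaN slabs for
    absent second scans, ``y`` of shape (n, 2) with NaN second labels, and a
    metadata frame (subject, scan times, grades, set_id) aligned with rows.
    """
    if not pairs:
        raise ValueError("no pair samples")
    first = np.asarray(payloads[pairs[0].scan1.payload_ref], dtype=float)
    shape = first.shape
    n = len(pairs)
    X = np.full((n, 2, *shape), np.nan)
    y = np.full((n, 2), np.nan)
    meta_rows = []
    for i, p in enumerate(pairs):
        X[i, 0] = payloads[p.scan1.payload_ref]
        y[i, 0] = p.y1
        if p.scan2 is not None:
            X[i, 1] = payloads[p.scan2.payload_ref]
            y[i, 1] = p.y2
        meta_rows.append(
            {
                "subject_id": p.scan1.subject_id,
                "scan1_time": p.scan1.scan_time_years,
                "scan2_time": p.scan2.scan_time_years if p.scan2 else np.nan,
                "grade1": p.scan1.grade,
                "grade2": p.scan2.grade if p.scan2 else np.nan,
                "set_id": p.set_id.value,
                "horizon": p.horizon,
            }
        )
    return X, y, pd.DataFrame(meta_rows)


def train_fold(train_pairs, payloads, formulation, val_pairs=None,
               hyper=None, seed=0, horizon=None, outer_fold=None,
               inner_fold=None) -> FittedModel:
    """Train one estimator on a fold's pairs and singles.

    ``formulation`` may be an approach name (``riskreg``, ``conreg``, ...),
    which resolves to a (formulation, reg_mode) pair; ``hyper`` overrides
    :class:`PairedRiskClassifier` constructor defaults; validation pairs
    drive best-epoch selection when given.
    """
    hyper = dict(hyper or {})
    form, reg_mode = resolve_approach(formulation)
    hyper.setdefault("formulation", form)
    hyper.setdefault("reg_mode", reg_mode)
    hyper.setdefault("seed", seed)
    est = PairedRiskClassifier(**hyper)
    X, y, _ = pairs_to_arrays(train_pairs, payloads)
    if val_pairs:
        Xv, yv, _ = pairs_to_arrays(val_pairs, payloads)
        est.fit(X, y, X_val=Xv, y_val=yv)
    else:
        est.fit(X, y)
    h = horizon if horizon is not None else train_pairs[0].horizon
    return FittedModel(est, str(formulation), float(h), outer_fold, inner_fold)


def predict_scan_risks(model: FittedModel, pair: PairSample, payloads):
    """Scan-level risks for one pair: ``(risk1, risk2-or-None)``."""
    X, _, _ = pairs_to_arrays([pair], payloads)
    risks = model.estimator.predict_pair_proba(X)[0]
    r2 = None if np.isnan(risks[1]) else float(risks[1])
    return float(risks[0]), r2


def ensemble_predict(models, pairs, payloads):
    """Ensembled per-scan risks over pair samples.

    Member risks are composed per model first, then averaged, so the
    progressive ordering of each member is preserved by the mean.  Returns
    ``(pred1, pred2)``: lists of :class:`EnsemblePrediction` (entries of
    ``pred2`` are ``None`` for single-scan samples).
    """
    models = list(models)
    if not models:
        raise ValueError("empty model list")
    forms = {m.formulation for m in models}
    if len(forms) > 1:
        raise ValueError(f"mixed formulations in ensemble: {sorted(forms)}")
    X, _, _ = pairs_to_arrays(pairs, payloads)
    member = np.stack([m.estimator.predict_pair_proba(X) for m in models])
    mean = member.mean(axis=0)
    pred1, pred2 = [], []
    for i in range(len(pairs)):
        pred1.append(EnsemblePrediction(float(mean[i, 0]), tuple(member[:, i, 0])))
        if np.isnan(mean[i, 1]):
            pred2.append(None)
        else:
            pred2.append(
                EnsemblePrediction(float(mean[i, 1]), tuple(member[:, i, 1]))
            )
    return pred1, pred2


def _prediction_rows(pairs, pred1, pred2, formulation, horizon):
    rows = []
    for p, r1, r2 in zip(pairs, pred1, pred2):
        rows.append(
            {
                "subject_id": p.scan1.subject_id,
                "scan_index": 1,
                "horizon": horizon,
                "formulation": formulation,
                "risk": r1.risk,
                "label": p.y1,
                "grade": p.scan1.grade,
                "set_id": p.set_id.value,
            }
        )
        if r2 is not None:
            rows.append(
                {
                    "subject_id": p.scan1.subject_id,
                    "scan_index": 2,
                    "horizon": horizon,
                    "formulation": formulation,
                    "risk": r2.risk,
                    "label": p.y2,
                    "grade": p.scan2.grade,
                    "set_id": p.set_id.value,
                }
            )
    return rows


def run_nested_training(pairs, payloads, plan: SplitPlan, formulation,
                        hyper=None, seed=0, horizon=None):
    """Nested-CV training with per-outer-fold ensembling.

    For each outer fold, the 6 inner models (trained on their inner-train
    split, best epoch selected on their inner-validation split) are
    ensembled to predict the outer test subjects.  Returns
    ``(models, predictions)``: the fitted models and a long-format
    scan-level prediction table covering the whole cohort out of sample.
    """
    by_subject = {p.scan1.subject_id: p for p in pairs}
    h = float(horizon) if horizon is not None else float(pairs[0].horizon)
    models = []
    rows = []
    per_outer: dict[int, list] = {}
    for o, i, train_ids, val_ids, test_ids in plan.assignments():
        train_pairs = [by_subject[s] for s in train_ids if s in by_subject]
        val_pairs = [by_subject[s] for s in val_ids if s in by_subject]
        model = train_fold(
            train_pairs, payloads, formulation, val_pairs=val_pairs,
            hyper=hyper, seed=seed * 1009 + o * 13 + i, horizon=h,
            outer_fold=o, inner_fold=i,
        )
        models.append(model)
        per_outer.setdefault(o, []).append(model)

    for o, members in sorted(per_outer.items()):
        test_ids = plan.frame.loc[plan.frame.outer_fold == o, "subject_id"]
        test_pairs = [by_subject[s] for s in test_ids if s in by_subject]
        if not test_pairs:
            continue
        pred1, pred2 = ensemble_predict(members, test_pairs, payloads)
        rows.extend(_prediction_rows(test_pairs, pred1, pred2,
                                     str(formulation), h))
    predictions = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    return models, predictions
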