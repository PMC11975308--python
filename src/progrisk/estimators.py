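"""Scikit-learn style estimator for paired-scan progressive risk prediction.

:class:`PairedRiskClassifier` fits one or two reference scorers (MLP for
feature payloads, small CNN for image payloads) by mini-batch Adam on the
summed pair cross-entropy, with the scan-2 risk composed according to the
chosen formulation.  Single-scan samples contribute only the scan-1 term
(and never update the scan-2 scorer of the dual-model formulation).  The
soft-constraint comparators (margin penalty on scores, Siamese contrastive
penalty on embeddings) attach to the unconstrained baseline formulation
only.

The estimator follows sklearn conventions: constructor stores
hyperparameters verbatim, ``fit`` returns ``self``, fitted state lives in
trailing-underscore attributes, and ``get_params`` / ``set_params`` /
``clone`` work as usual.  Pair input is a 3-D (or 4-D, for images) array
``X[:, 0]`` = scan 1, ``X[:, 1]`` = scan 2, with NaN slabs marking absent
second scans; ``y`` is ``(n, 2)`` with NaN for the missing second label.
Plain 2-D (or 3-D image) input is treated as single scans.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import risk_core
from .risk_core import Formulation, RegMode, RegularizerConfig
from .scorers import Adam, ConvScorer, MLPScorer
from .evaluation import UndefinedMetricError, auroc

__all__ = ["PairedRiskClassifier"]


def _as_pair_arrays(X, y=None):
    """Normalise input to (X1, X2, mask2, y1, y2) with NaNs resolved."""
    X = np.asarray(X, dtype=float)
    if X.ndim in (2, 3) and not (X.ndim == 3 and X.shape[1] == 2):
        # single-scan input: (n, d) features or (n, H, W) images
        X1, X2 = X, None
        mask = np.zeros(X.shape[0])
    else:
        if X.shape[1] != 2:
            raise ValueError("pair input must have axis 1 of size 2 (scan1, scan2)")
        X1 = X[:, 0]
        X2 = X[:, 1]
        flat2 = X2.reshape(X2.shape[0], -1)
        mask = np.isfinite(flat2).all(axis=1).astype(float)
        X2 = np.where(np.isfinite(X2), X2, 0.0)
    if not np.all(np.isfinite(X1)):
        raise ValueError("scan-1 payloads must be finite")
    if y is None:
        return X1, X2, mask, None, None
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y1, y2 = y, np.zeros_like(y)
        mask = np.zeros(y.shape[0])
    else:
        y1 = y[:, 0]
        y2 = y[:, 1]
        mask = mask * np.isfinite(y2)
        y2 = np.nan_to_num(y2)
    if np.any(np.isnan(y1)):
        raise ValueError("scan-1 labels must be defined")
    return X1, X2, mask, y1, y2


class PairedRiskClassifier(BaseEstimator, ClassifierMixin):
    """Progressive-risk classifier over (scan 1, scan 2) pairs.

    Parameters
    ----------
    formulation : {"baseline", "riskform1", "riskform2"}
        How the scan-2 risk is composed (see :mod:`progrisk.risk_core`).
    reg_mode : {"none", "riskreg", "conreg", "both"}
        Soft-constraint penalties; only valid with the baseline formulation.
    margin, gamma : float
        Penalty margin and weight (margin 2.0 on the score scale).
    payload : {"features", "image"}
        Selects the MLP or CNN reference scorer.
    hidden : tuple of int
        MLP hidden sizes (feature payloads).
    channels : tuple of int
        CNN block channels (image payloads).
    lr, weight_decay, epochs, batch_size : training hyperparameters (Adam).
    seed : int
        Controls initialisation and batch shuffling; fitting is
        deterministic given data and seed.
    """

    def __init__(self, formulation="riskform1", reg_mode="none", margin=2.0,
                 gamma=1.0, payload="features", hidden=(16,),
                 channels=(4, 8, 8), lr=0.01, weight_decay=1e-4, epochs=60,
                 batch_size=32, seed=0):
        self.formulation = formulation
        self.reg_mode = reg_mode
        self.margin = margin
        self.gamma = gamma
        self.payload = payload
        self.hidden = hidden
        self.channels = channels
        self.lr = lr
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    # ------------------------------------------------------------------ fit

    def _make_scorer(self, X1, seed_salt):
        if self.payload == "features":
            return MLPScorer(X1.shape[1], hidden=self.hidden,
                             seed=self.seed * 1000 + seed_salt)
        if self.payload == "image":
            return ConvScorer(X1.shape[1], channels=self.channels,
                              seed=self.seed * 1000 + seed_salt)
        raise ValueError(f"unknown payload kind {self.payload!r}")

    def fit(self, X, y, X_val=None, y_val=None):
        """Fit the scorer(s) by mini-batch Adam on the pair loss.

        When a validation set is given, parameters from the epoch with the
        best validation AUROC (scan-level, pooled over both scans) are
        retained.
        """
        form = Formulation(self.formulation)
        cfg = RegularizerConfig(self.margin, self.gamma, RegMode(self.reg_mode))
        if cfg.mode is not RegMode.NONE and form is not Formulation.BASELINE:
            raise ValueError(
                "score/embedding penalties attach to the baseline formulation only"
            )
        X1, X2, mask, y1, y2 = _as_pair_arrays(X, y)
        n = X1.shape[0]
        if n == 0:
            raise ValueError("empty training set")
        observed = np.concatenate([y1, y2[mask > 0]])
        if len(np.unique(observed)) < 2:
            raise ValueError("training set must contain both classes")

        self.formulation_ = form
        self.regularizer_ = cfg
        self.n_features_in_ = X1.shape[1] if X1.ndim == 2 else None
        self.classes_ = np.array([0, 1])

        f = self._make_scorer(X1, 1)
        g = self._make_scorer(X1, 2) if form is Formulation.RISKFORM2 else None
        opt_f = Adam(f.params, lr=self.lr, weight_decay=self.weight_decay)
        opt_g = (
            Adam(g.params, lr=self.lr, weight_decay=self.weight_decay)
            if g is not None else None
        )

        rng = np.random.default_rng([int(self.seed), 53])
        history = []
        best = (-np.inf, None, None, -1)

        def mean_loss(X1a, X2a, maska, y1a, y2a):
            s1 = f.forward(X1a)
            s2 = np.zeros_like(s1)
            idx = maska > 0
            if X2a is not None and idx.any():
                s2[idx] = (g if g is not None else f).forward(X2a[idx])
            loss, _, _ = risk_core.pair_loss_and_grads(
                s1, s2, y1a, y2a, maska, form
            )
            return float(loss.mean())

        history.append({"epoch": 0, "train_loss": mean_loss(X1, X2, mask, y1, y2)})
        val = None
        if X_val is not None:
            val = _as_pair_arrays(X_val, y_val)

        for epoch in range(1, int(self.epochs) + 1):
            order = rng.permutation(n)
            for start in range(0, n, int(self.batch_size)):
                sel = order[start : start + int(self.batch_size)]
                self._step(f, g, opt_f, opt_g, cfg, form,
                           X1[sel], None if X2 is None else X2[sel],
                           mask[sel], y1[sel], y2[sel])
            entry = {"epoch": epoch,
                     "train_loss": mean_loss(X1, X2, mask, y1, y2)}
            if val is not None:
                score = self._val_score(f, g, form, val)
                entry["val_score"] = score
                if score > best[0]:
                    best = (score, f.copy_params(),
                            g.copy_params() if g is not None else None, epoch)
            history.append(entry)

        if val is not None and best[1] is not None:
            f.set_params_(best[1])
            if g is not None:
                g.set_params_(best[2])
            self.best_epoch_ = best[3]
        else:
            self.best_epoch_ = int(self.epochs)
        self.scorer_f_ = f
        self.scorer_g_ = g
        self.history_ = history
        return self

    def _step(self, f, g, opt_f, opt_g, cfg, form, X1, X2, mask, y1, y2):
        nb = X1.shape[0]
        s1, cache1 = f.forward_cache(X1)
        idx = mask > 0
        scorer2 = g if g is not None else f
        s2 = np.zeros_like(s1)
        cache2 = None
        if X2 is not None and idx.any():
            s2_sub, cache2 = scorer2.forward_cache(X2[idx])
            s2[idx] = s2_sub
        _, g1, g2 = risk_core.pair_loss_and_grads(s1, s2, y1, y2, mask, form)

        demb1 = demb2 = None
        if cfg.mode.has_riskreg and idx.any():
            _, pr1, pr2 = risk_core.riskreg_penalty_and_grads(s1[idx], s2[idx], cfg)
            g1[idx] += pr1
            g2[idx] += pr2
        if cfg.mode.has_conreg and idx.any():
            h1 = f.embed_from_cache(cache1)[idx]
            h2 = scorer2.embed_from_cache(cache2)
            dissim = (y1[idx] != y2[idx]).astype(float)
            _, dh1, dh2 = risk_core.conreg_penalty_and_grads(h1, h2, dissim, cfg)
            demb1 = np.zeros((nb, h1.shape[1]))
            demb1[idx] = dh1 / nb
            demb2 = dh2 / nb

        grads_f = f.backward(cache1, g1 / nb, demb1)
        if cache2 is not None:
            grads2 = scorer2.backward(cache2, g2[idx] / nb, demb2)
            if scorer2 is f:
                grads_f = [a + b for a, b in zip(grads_f, grads2)]
                opt_f.step(f.params, grads_f)
            else:
                opt_f.step(f.params, grads_f)
                opt_g.step(g.params, grads2)
        else:
            opt_f.step(f.params, grads_f)

    def _val_score(self, f, g, form, val):
        X1, X2, mask, y1, y2 = val
        s1 = f.forward(X1)
        risks = [np.asarray(risk_core.sigmoid(s1))]
        labels = [y1]
        idx = mask > 0
        if X2 is not None and idx.any():
            s2 = (g if g is not None else f).forward(X2[idx])
            _, r2 = risk_core.compose_risks(s1[idx], s2, form)
            risks.append(np.asarray(r2))
            labels.append(y2[idx])
        r = np.concatenate(risks)
        yy = np.concatenate(labels).astype(int)
        try:
            return auroc(yy, r)
        except UndefinedMetricError:
            return -float(risk_core.pair_loss(r, None, yy, has_scan2=False).mean())

    # -------------------------------------------------------------- predict

    def _check_fitted(self):
        if not hasattr(self, "scorer_f_"):
            raise RuntimeError("estimator is not fitted")

    def predict_pair_proba(self, X):
        """Composed (risk1, risk2) per pair; risk2 is NaN for single scans."""
        self._check_fitted()
        X1, X2, mask, _, _ = _as_pair_arrays(X)
        s1 = self.scorer_f_.forward(X1)
        out = np.column_stack(
            [np.asarray(risk_core.sigmoid(s1)), np.full(X1.shape[0], np.nan)]
        )
        idx = mask > 0
        if X2 is not None and idx.any():
            scorer2 = self.scorer_g_ if self.scorer_g_ is not None else self.scorer_f_
            s2 = scorer2.forward(X2[idx])
            _, r2 = risk_core.compose_risks(s1[idx], s2, self.formulation_)
            out[idx, 1] = r2
        return out

    def predict_proba(self, X):
        """Single-scan class probabilities ``[P(no event), P(event)]``."""
        self._check_fitted()
        X1 = np.asarray(X, dtype=float)
        p = np.asarray(risk_core.sigmoid(self.scorer_f_.forward(X1)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def decision_function(self, X):
        self._check_fitted()
        return self.scorer_f_.forward(np.asarray(X, dtype=float))
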