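"""Progressive risk compositions for paired longitudinal scans.

A scorer maps a scan to an unbounded real score; the standard (baseline) risk
is the sigmoid of that score.  When two scans of the same knee are available
(scan 1 at baseline, scan 2 later), a progressive disease implies the event
risk at scan 2 can never be below the risk at scan 1.  Two closed-form
compositions enforce this constraint *by construction*:

``RISKFORM1`` (single scorer ``f``)::

    y1 = sigmoid(f(x1))
    y2 = 1 - (1 - sigmoid(f(x1))) * (1 - sigmoid(f(x2)))

``RISKFORM2`` (second scorer ``g``, inversely related to risk)::

    y1 = sigmoid(f(x1))
    y2 = 1 - (1 - sigmoid(f(x1))) * sigmoid(g(x2))

Both satisfy ``y2 >= y1`` for any real scores, because the second factor of
the "no event" probability lies in (0, 1).  Training minimises the summed
binary cross-entropy over the two scans (only the scan-1 term when a second
scan is absent).  Two soft-constraint comparators are provided as well: a
margin loss on raw scores (RiskReg) and a Siamese contrastive loss on
embeddings (ConReg).

Everything here is plain numpy, vectorised over batches, with closed-form
gradients used by :mod:`progrisk.training`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Formulation",
    "RegMode",
    "RegularizerConfig",
    "ScorePair",
    "RiskPair",
    "PairLabels",
    "sigmoid",
    "compose_risks",
    "pair_loss",
    "pair_loss_and_grads",
    "riskreg_penalty",
    "riskreg_penalty_and_grads",
    "conreg_penalty",
    "conreg_penalty_and_grads",
]

#: scores are clipped here before exponentiation
SCORE_CLIP = 500.0
#: probabilities are clamped into [PROB_EPS, 1 - PROB_EPS] inside cross-entropy
PROB_EPS = 1e-7


class Formulation(str, enum.Enum):
    """How the scan-2 risk is composed from scorer outputs."""

    BASELINE = "baseline"  # independent sigmoids, no constraint
    RISKFORM1 = "riskform1"  # shared scorer, product-form composition
    RISKFORM2 = "riskform2"  # dedicated inverse scorer for scan 2


class RegMode(str, enum.Enum):
    """Which soft-constraint penalties are added to the baseline loss."""

    NONE = "none"
    RISKREG = "riskreg"
    CONREG = "conreg"
    BOTH = "both"

    @property
    def has_riskreg(self) -> bool:
        return self in (RegMode.RISKREG, RegMode.BOTH)

    @property
    def has_conreg(self) -> bool:
        return self in (RegMode.CONREG, RegMode.BOTH)


@dataclass(frozen=True)
class RegularizerConfig:
    """Margin-loss / contrastive-loss settings.

    ``margin`` lives on the unbounded score (logit) scale for RiskReg and on
    the embedding-distance scale for ConReg; ``gamma`` is the outer weight
    multiplying either penalty.
    """

    margin: float = 2.0
    gamma: float = 1.0
    mode: RegMode = RegMode.NONE

    def __post_init__(self) -> None:
        if not np.isfinite(self.margin) or self.margin < 0:
            raise ValueError(f"margin must be a non-negative real, got {self.margin}")
        if not np.isfinite(self.gamma) or self.gamma < 0:
            raise ValueError(f"gamma must be a non-negative real, got {self.gamma}")
        object.__setattr__(self, "mode", RegMode(self.mode))


@dataclass(frozen=True)
class ScorePair:
    """Raw scorer outputs for an ordered scan pair."""

    s1: float
    s2: float
    formulation: Formulation = Formulation.RISKFORM1

    def __post_init__(self) -> None:
        if not (np.isfinite(self.s1) and np.isfinite(self.s2)):
            raise ValueError("scores must be finite")
        object.__setattr__(self, "formulation", Formulation(self.formulation))


@dataclass(frozen=True)
class RiskPair:
    """Composed risk probabilities; under the progressive formulations
    ``y_hat_2 >= y_hat_1`` holds by construction."""

    y_hat_1: float
    y_hat_2: float
    formulation: Formulation

    def __post_init__(self) -> None:
        if not (0.0 < self.y_hat_1 < 1.0 and 0.0 < self.y_hat_2 < 1.0):
            raise ValueError("risks must lie strictly in (0, 1)")
        if self.formulation in (Formulation.RISKFORM1, Formulation.RISKFORM2):
            if self.y_hat_2 < self.y_hat_1:
                raise ValueError(
                    "progressive formulations require y_hat_2 >= y_hat_1"
                )

    @classmethod
    def from_scores(cls, scores: ScorePair) -> "RiskPair":
        y1, y2 = compose_risks(scores.s1, scores.s2, scores.formulation)
        return cls(float(y1), float(y2), scores.formulation)


@dataclass(frozen=True)
class PairLabels:
    """Binary event-within-horizon labels for the two scans."""

    y1: int
    y2: int | None = None
    has_scan2: bool = field(default=True)

    def __post_init__(self) -> None:
        if self.y1 not in (0, 1):
            raise ValueError(f"y1 must be 0 or 1, got {self.y1}")
        if self.has_scan2:
            if self.y2 not in (0, 1):
                raise ValueError(f"y2 must be 0 or 1 when a second scan exists")
        else:
            object.__setattr__(self, "y2", None)


def _check_finite(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")
    return x


def sigmoid(score):
    """Numerically stable logistic function, elementwise.

    Uses the two-branch form so neither exponential overflows; scores are
    clipped to +-500 first, keeping the output strictly inside (0, 1).
    """
    z = _check_finite(score, "score")
    z = np.clip(z, -SCORE_CLIP, SCORE_CLIP)
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    # exp(-500) underflows to 0 only beyond float range; keep an open interval
    np.clip(out, PROB_EPS, 1.0 - PROB_EPS, out=out)
    return out if out.ndim else float(out)


def compose_risks(s1, s2, formulation: Formulation | str = Formulation.RISKFORM1):
    """Compose the (scan-1, scan-2) risks from raw scores.

    Returns ``(y_hat_1, y_hat_2)``; elementwise over arrays.  Scan 1 is always
    ``sigmoid(s1)``.  Scan 2 depends on the formulation (see module docstring).
    """
    formulation = Formulation(formulation)
    p1 = sigmoid(s1)
    p2 = sigmoid(s2)
    # The progressive compositions are evaluated in the algebraically equal
    # additive form p1 + (1 - p1) * q, q in [0, 1]: adding a non-negative
    # rounded term can never drop below the representable p1, so y2 >= y1
    # holds exactly in floating point, not just in real arithmetic.
    if formulation is Formulation.BASELINE:
        y2 = p2
    elif formulation is Formulation.RISKFORM1:
        y2 = p1 + (1.0 - p1) * p2
    elif formulation is Formulation.RISKFORM2:
        # here s2 came from the inverse scorer g: larger score, lower risk
        y2 = p1 + (1.0 - p1) * (1.0 - p2)
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown formulation {formulation!r}")
    y2 = np.clip(y2, PROB_EPS, 1.0 - PROB_EPS)
    return p1, (y2 if np.ndim(y2) else float(y2))


def _bce(y, p):
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    y = np.asarray(y, dtype=float)
    return -(y * np.log(p) + (1.0 - y) * np.log1p(-p))


def pair_loss(y_hat_1, y_hat_2, y1, y2=None, has_scan2=True):
    """Summed natural-log binary cross-entropy over the available scans.

    ``has_scan2`` may be a boolean or a 0/1 mask; when false the scan-2 term
    is dropped (single-scan training sample).  Returns per-sample losses
    (scalar for scalar input).
    """
    y_hat_1 = _check_finite(y_hat_1, "y_hat_1")
    loss = _bce(y1, y_hat_1)
    mask = np.asarray(has_scan2, dtype=float)
    if np.any(mask > 0):
        if y_hat_2 is None or y2 is None:
            raise ValueError("y_hat_2 and y2 required when has_scan2 is set")
        y2_arr = np.where(mask > 0, np.asarray(y2, dtype=float), 0.0)
        loss = loss + mask * _bce(y2_arr, _check_finite(y_hat_2, "y_hat_2"))
    out = loss
    return out if np.ndim(out) else float(out)


def pair_loss_and_grads(s1, s2, y1, y2, mask, formulation):
    """Per-sample pair loss and its gradients w.r.t. the raw scores.

    Closed forms (writing ``p1 = sigmoid(s1)``, ``y2h`` for the composed
    scan-2 risk): the scan-1 term contributes the familiar ``p1 - y1``; the
    scan-2 term contributes

    * baseline:   ``d/ds2 = p2 - y2``
    * RISKFORM1:  ``d/ds1 = (y2h - y2) p1 / y2h``, ``d/ds2 = (y2h - y2) p2 / y2h``
    * RISKFORM2:  ``d/ds1 = (y2h - y2) p1 / y2h``, ``d/ds2 = -(y2h - y2) (1 - q2) / y2h``

    where ``q2 = sigmoid(s2)`` is the inverse-scorer multiplier.  ``mask`` is
    the 0/1 has-scan2 indicator; masked entries contribute no scan-2 loss or
    gradient.  Returns ``(loss, dL/ds1, dL/ds2)`` as arrays.
    """
    formulation = Formulation(formulation)
    s1 = np.atleast_1d(_check_finite(s1, "s1"))
    s2 = np.atleast_1d(np.nan_to_num(np.asarray(s2, dtype=float)))
    y1 = np.atleast_1d(np.asarray(y1, dtype=float))
    y2 = np.atleast_1d(np.nan_to_num(np.asarray(y2, dtype=float)))
    mask = np.atleast_1d(np.asarray(mask, dtype=float))

    p1 = np.asarray(sigmoid(s1))
    p2 = np.asarray(sigmoid(s2))
    if formulation is Formulation.BASELINE:
        y2h = p2
        d2_ds1 = np.zeros_like(p1)
        d2_ds2 = p2 - y2
    elif formulation is Formulation.RISKFORM1:
        y2h = p1 + (1.0 - p1) * p2
        denom = np.maximum(y2h, PROB_EPS)
        d2_ds1 = (y2h - y2) * p1 / denom
        d2_ds2 = (y2h - y2) * p2 / denom
    else:  # RISKFORM2
        y2h = p1 + (1.0 - p1) * (1.0 - p2)
        denom = np.maximum(y2h, PROB_EPS)
        d2_ds1 = (y2h - y2) * p1 / denom
        d2_ds2 = -(y2h - y2) * (1.0 - p2) / denom

    loss = _bce(y1, p1) + mask * _bce(y2, y2h)
    g1 = (p1 - y1) + mask * d2_ds1
    g2 = mask * d2_ds2
    return loss, g1, g2


def riskreg_penalty(s1, s2, cfg: RegularizerConfig):
    """Margin penalty pushing the scan-2 score above the scan-1 score.

    ``gamma * max(0, margin - (s2 - s1))`` on the raw score scale; zero
    exactly when ``s2 - s1 >= margin``.
    """
    if not cfg.mode.has_riskreg:
        raise ValueError(f"RegularizerConfig mode {cfg.mode} does not include RiskReg")
    pen, _, _ = riskreg_penalty_and_grads(s1, s2, cfg)
    return pen if np.ndim(pen) else float(pen)


def riskreg_penalty_and_grads(s1, s2, cfg: RegularizerConfig):
    s1 = _check_finite(s1, "s1")
    s2 = _check_finite(s2, "s2")
    gap = cfg.margin - (s2 - s1)
    active = gap > 0
    pen = cfg.gamma * np.where(active, gap, 0.0)
    g1 = cfg.gamma * active.astype(float)
    return pen, g1, -g1


def conreg_penalty(h1, h2, labels: PairLabels, cfg: RegularizerConfig):
    """Siamese contrastive penalty on the two scans' embeddings.

    With ``d`` the Euclidean distance between the embeddings and the pair
    counted as *dissimilar* when the two horizon labels differ::

        gamma * [ (1 - s) d**2 + s * max(0, margin - d)**2 ],  s = 1[y1 != y2]

    Same-label pairs are pulled together, label-crossing (progression) pairs
    pushed at least ``margin`` apart.
    """
    if not cfg.mode.has_conreg:
        raise ValueError(f"RegularizerConfig mode {cfg.mode} does not include ConReg")
    h1 = np.atleast_2d(_check_finite(h1, "h1"))
    h2 = np.atleast_2d(_check_finite(h2, "h2"))
    if h1.shape != h2.shape:
        raise ValueError(f"embedding shapes differ: {h1.shape} vs {h2.shape}")
    if not labels.has_scan2:
        raise ValueError("ConReg needs both scans' labels")
    dissim = np.asarray(float(labels.y1 != labels.y2))
    pen, _, _ = _conreg_core(h1, h2, dissim, cfg)
    return float(pen[0]) if pen.size == 1 else pen


def conreg_penalty_and_grads(h1, h2, dissimilar, cfg: RegularizerConfig):
    """Batch ConReg: ``dissimilar`` is the 0/1 label-difference indicator."""
    h1 = np.atleast_2d(_check_finite(h1, "h1"))
    h2 = np.atleast_2d(_check_finite(h2, "h2"))
    if h1.shape != h2.shape:
        raise ValueError(f"embedding shapes differ: {h1.shape} vs {h2.shape}")
    return _conreg_core(h1, h2, np.atleast_1d(np.asarray(dissimilar, float)), cfg)


def _conreg_core(h1, h2, dissim, cfg):
    diff = h1 - h2
    d = np.sqrt(np.sum(diff * diff, axis=1))
    hinge = np.maximum(0.0, cfg.margin - d)
    pen = cfg.gamma * ((1.0 - dissim) * d**2 + dissim * hinge**2)
    # gradient w.r.t. h1 (h2 gets the negative); hinge term is 0 at d == 0
    safe_d = np.where(d > 0, d, 1.0)
    coef = cfg.gamma * (
        2.0 * (1.0 - dissim) - 2.0 * dissim * np.where(d > 0, hinge / safe_d, 0.0)
    )
    g1 = coef[:, None] * diff
    return pen, g1, -g1
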