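"""The composition algebra: sigmoid head, progressive risk compositions,
pair loss, and the soft-constraint comparator penalties."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from progrisk.risk_core import (
    Formulation,
    PairLabels,
    RegMode,
    RegularizerConfig,
    RiskPair,
    ScorePair,
    compose_risks,
    conreg_penalty,
    conreg_penalty_and_grads,
    pair_loss,
    pair_loss_and_grads,
    riskreg_penalty,
    sigmoid,
)

finite_scores = st.floats(-20.0, 20.0, allow_nan=False)


@pytest.mark.parametrize(
    "z, expected",
    [(0.0, 0.5), (1.0, 1 / (1 + math.exp(-1))), (-2.0, 1 / (1 + math.exp(2)))],
)
def test_sigmoid_matches_closed_form(z, expected):
    assert sigmoid(z) == pytest.approx(expected, abs=1e-12)


def test_sigmoid_is_stable_and_open_interval_at_extreme_scores():
    for z in (-500.0, -50.0, 50.0, 500.0):
        p = sigmoid(z)
        assert 0.0 < p < 1.0
    assert sigmoid(500.0) > 0.999
    assert sigmoid(-500.0) < 1e-6


@pytest.mark.parametrize("bad", [np.nan, np.inf, -np.inf])
def test_sigmoid_rejects_nonfinite_input(bad):
    with pytest.raises(ValueError):
        sigmoid(bad)


# frozen by direct high-precision evaluation of the closed forms
COMPOSE_CASES = [
    (0.0, 0.0, "riskform1", 0.5, 0.75),
    (1.0, -2.0, "riskform1", 0.7310585786, 0.7631171819),
    (0.0, 2.0, "riskform2", 0.5, 0.5596014610),
    (0.0, 5.0, "baseline", 0.5, 0.9933071491),
]


@pytest.mark.parametrize("s1, s2, form, e1, e2", COMPOSE_CASES)
def test_compose_risks_matches_direct_evaluation(s1, s2, form, e1, e2):
    y1, y2 = compose_risks(s1, s2, form)
    assert y1 == pytest.approx(e1, abs=1e-9)
    assert y2 == pytest.approx(e2, abs=1e-9)


def test_compose_risks_rejects_unknown_formulation():
    with pytest.raises(ValueError):
        compose_risks(0.0, 0.0, "riskform3")


def test_riskpair_from_scores_enforces_ordering_invariant():
    rp = RiskPair.from_scores(ScorePair(1.0, -2.0, Formulation.RISKFORM1))
    assert rp.y_hat_2 >= rp.y_hat_1
    with pytest.raises(ValueError):
        RiskPair(0.7, 0.6, Formulation.RISKFORM1)
    with pytest.raises(ValueError):
        RiskPair(0.0, 0.5, Formulation.BASELINE)


def test_pairlabels_validation():
    single = PairLabels(1, has_scan2=False)
    assert single.y2 is None
    with pytest.raises(ValueError):
        PairLabels(2, 0)
    with pytest.raises(ValueError):
        PairLabels(0, None, has_scan2=True)


@given(s1=finite_scores, s2=finite_scores)
def test_progressive_compositions_never_decrease_risk(s1, s2):
    for form in ("riskform1", "riskform2"):
        y1, y2 = compose_risks(s1, s2, form)
        assert y2 >= y1


@given(s1=finite_scores, s2=finite_scores)
def test_riskform1_scan2_risk_is_symmetric_in_scores(s1, s2):
    _, y2a = compose_risks(s1, s2, "riskform1")
    _, y2b = compose_risks(s2, s1, "riskform1")
    assert y2a == pytest.approx(y2b, abs=1e-12)


@given(s1=st.floats(-8.0, 8.0), s2=st.floats(-8.0, 8.0), delta=st.floats(0.01, 1.0))
def test_scan2_risk_direction_of_correlation(s1, s2, delta):
    # moderate scores: strictness saturates once the clamped sigmoid does
    # increasing the scan-2 score raises risk under the shared-scorer
    # composition and lowers it under the inverse-scorer composition
    _, lo1 = compose_risks(s1, s2, "riskform1")
    _, hi1 = compose_risks(s1, s2 + delta, "riskform1")
    assert hi1 > lo1
    _, lo2 = compose_risks(s1, s2 + delta, "riskform2")
    _, hi2 = compose_risks(s1, s2, "riskform2")
    assert hi2 > lo2


def test_composition_limits_at_extreme_scores():
    # shared-scorer composition degenerates to the plain sigmoid when the
    # first scan carries no risk
    for s2 in (-3.0, 0.0, 3.0):
        _, y2 = compose_risks(-30.0, s2, "riskform1")
        assert y2 == pytest.approx(sigmoid(s2), abs=1e-6)
    # inverse-scorer composition attains the equality boundary / saturates
    y1, y2 = compose_risks(0.7, 30.0, "riskform2")
    assert y2 == pytest.approx(y1, abs=1e-6)
    _, y2 = compose_risks(0.7, -30.0, "riskform2")
    assert y2 == pytest.approx(1.0, abs=1e-6)


def test_pair_loss_matches_direct_arithmetic():
    assert pair_loss(0.5, 0.75, 0, 1) == pytest.approx(
        -math.log(0.5) - math.log(0.75), abs=1e-9
    )
    assert pair_loss(0.5, None, 1, has_scan2=False) == pytest.approx(
        -math.log(0.5), abs=1e-9
    )
    # perfect prediction: loss vanishes in the limit
    assert pair_loss(1 - 1e-9, 1 - 1e-9, 1, 1) < 1e-5


@given(
    y1h=st.floats(1e-6, 1 - 1e-6),
    y2h=st.floats(1e-6, 1 - 1e-6),
    y1=st.integers(0, 1),
    y2=st.integers(0, 1),
)
def test_pair_loss_is_nonnegative(y1h, y2h, y1, y2):
    assert pair_loss(y1h, y2h, y1, y2) >= 0.0


@pytest.mark.parametrize("form", ["baseline", "riskform1", "riskform2"])
def test_pair_loss_gradients_match_finite_differences(form):
    rng = np.random.default_rng(5)
    s1 = rng.normal(scale=2, size=8)
    s2 = rng.normal(scale=2, size=8)
    y1 = rng.integers(0, 2, 8)
    y2 = rng.integers(0, 2, 8)
    mask = np.array([1, 1, 1, 1, 0, 1, 0, 1], dtype=float)
    _, g1, g2 = pair_loss_and_grads(s1, s2, y1, y2, mask, form)
    eps = 1e-6
    for i in range(8):
        d = np.zeros(8)
        d[i] = eps
        n1 = (
            pair_loss_and_grads(s1 + d, s2, y1, y2, mask, form)[0][i]
            - pair_loss_and_grads(s1 - d, s2, y1, y2, mask, form)[0][i]
        ) / (2 * eps)
        n2 = (
            pair_loss_and_grads(s1, s2 + d, y1, y2, mask, form)[0][i]
            - pair_loss_and_grads(s1, s2 - d, y1, y2, mask, form)[0][i]
        ) / (2 * eps)
        assert g1[i] == pytest.approx(n1, abs=1e-5)
        assert g2[i] == pytest.approx(n2, abs=1e-5)


@pytest.mark.parametrize(
    "s1, s2, margin, gamma, expected",
    [(0.0, 3.0, 2.0, 1.0, 0.0), (0.0, 0.0, 2.0, 1.0, 2.0), (1.0, 2.0, 2.0, 0.5, 0.5)],
)
def test_margin_penalty_values(s1, s2, margin, gamma, expected):
    cfg = RegularizerConfig(margin, gamma, RegMode.RISKREG)
    assert riskreg_penalty(s1, s2, cfg) == pytest.approx(expected, abs=1e-12)


@given(s1=finite_scores, s2=finite_scores)
def test_margin_penalty_zero_iff_constraint_met(s1, s2):
    cfg = RegularizerConfig(2.0, 1.0, RegMode.RISKREG)
    pen = riskreg_penalty(s1, s2, cfg)
    assert pen >= 0.0
    assert (pen == 0.0) == (s2 - s1 >= 2.0)


def test_contrastive_penalty_values():
    cfg = RegularizerConfig(2.0, 1.0, RegMode.CONREG)
    h = np.array([1.0, 2.0, 3.0])
    same = PairLabels(0, 0)
    diff = PairLabels(0, 1)
    assert conreg_penalty(h, h, same, cfg) == pytest.approx(0.0)
    assert conreg_penalty(h, h, diff, cfg) == pytest.approx(4.0)
    shifted = h + np.array([1.0, 0.0, 0.0])  # distance exactly 1
    assert conreg_penalty(h, shifted, diff, cfg) == pytest.approx(1.0)


def test_contrastive_penalty_rejects_dimension_mismatch():
    cfg = RegularizerConfig(2.0, 1.0, RegMode.CONREG)
    with pytest.raises(ValueError):
        conreg_penalty(np.ones(3), np.ones(4), PairLabels(0, 1), cfg)


def test_contrastive_gradients_match_finite_differences():
    cfg = RegularizerConfig(2.0, 0.7, RegMode.CONREG)
    rng = np.random.default_rng(3)
    h1 = rng.normal(size=(4, 5))
    h2 = rng.normal(size=(4, 5))
    dissim = np.array([0.0, 1.0, 1.0, 0.0])
    _, g1, g2 = conreg_penalty_and_grads(h1, h2, dissim, cfg)
    eps = 1e-6
    for i in range(4):
        for j in range(5):
            d = np.zeros_like(h1)
            d[i, j] = eps
            n1 = (
                conreg_penalty_and_grads(h1 + d, h2, dissim, cfg)[0][i]
                - conreg_penalty_and_grads(h1 - d, h2, dissim, cfg)[0][i]
            ) / (2 * eps)
            n2 = (
                conreg_penalty_and_grads(h1, h2 + d, dissim, cfg)[0][i]
                - conreg_penalty_and_grads(h1, h2 - d, dissim, cfg)[0][i]
            ) / (2 * eps)
            assert g1[i, j] == pytest.approx(n1, abs=1e-5)
            assert g2[i, j] == pytest.approx(n2, abs=1e-5)


def test_regularizer_config_validation():
    with pytest.raises(ValueError):
        RegularizerConfig(margin=-1.0)
    with pytest.raises(ValueError):
        RegularizerConfig(gamma=-0.1)
    with pytest.raises(ValueError):
        riskreg_penalty(0.0, 0.0, RegularizerConfig(mode=RegMode.CONREG))
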