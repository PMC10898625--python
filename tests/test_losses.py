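"""Loss terms against closed forms and independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from styleharm import losses as L
from styleharm.errors import ShapeError, TrainingDivergenceError


def _loop_l1(a, b):
    """Independent elementwise oracle for every L1-based term."""
    a, b = np.asarray(a).ravel(), np.asarray(b).ravel()
    total = 0.0
    for x, y in zip(a, b):
        total += abs(float(x) - float(y))
    return total / len(a)


SHAPES = [(7,), (3, 5), (2, 3, 4, 4)]


@pytest.mark.parametrize("shape", SHAPES)
@pytest.mark.parametrize("fn", [
    L.content_consistency, L.style_consistency, L.style_diversity,
    L.identity_loss,
])
def test_l1_terms_equal_bruteforce_loop(fn, shape):
    rng = np.random.default_rng(hash((shape, fn.__name__)) % 2**32)
    a = rng.uniform(-1, 1, shape).astype(np.float32)
    b = rng.uniform(-1, 1, shape).astype(np.float32)
    assert abs(float(fn(a, b)) - _loop_l1(a, b)) < 1e-6


def test_l1_identity_and_symmetry():
    x = np.linspace(-1, 1, 24).reshape(4, 6).astype(np.float32)
    assert float(L.content_consistency(x, x)) == 0.0
    assert float(L.style_consistency(np.array([0.5, -0.5]),
                                     np.zeros(2))) == pytest.approx(0.5)
    a = np.array([0.3, -0.2], dtype=np.float32)
    b = np.array([-0.1, 0.9], dtype=np.float32)
    assert float(L.style_consistency(a, b)) == pytest.approx(
        float(L.style_consistency(b, a)))


def test_ones_vs_zeros_content_consistency():
    assert float(L.content_consistency(np.ones((3, 3)),
                                       np.zeros((3, 3)))) == pytest.approx(1.0)


def test_shape_mismatch_raises():
    with pytest.raises(ShapeError):
        L.content_consistency(np.zeros(3), np.zeros(4))


def test_adversarial_loss_closed_form():
    assert float(L.adversarial_loss(0.5, 0.5)) == pytest.approx(
        2 * math.log(0.5), abs=1e-6)
    # perfect discriminator limit
    assert abs(float(L.adversarial_loss(1 - 1e-7, 1e-7))) < 1e-5


def test_adversarial_loss_monotonicity():
    base = float(L.adversarial_loss(0.5, 0.5))
    assert float(L.adversarial_loss(0.6, 0.5)) > base
    assert float(L.adversarial_loss(0.5, 0.6)) < base


def test_content_alignment_closed_form():
    assert float(L.content_alignment(np.zeros((2, 3)))) == 0.0
    assert float(L.content_alignment(np.ones((2, 3)))) == pytest.approx(0.5)
    rng = np.random.default_rng(0)
    c = rng.standard_normal((4, 8)).astype(np.float32)
    v1 = float(L.content_alignment(c))
    assert v1 == pytest.approx(0.5 * np.mean(c.astype(np.float64) ** 2),
                               abs=1e-6)
    assert float(L.content_alignment(2 * c)) == pytest.approx(4 * v1, rel=1e-5)


def test_style_diversity_constant_offset_and_ceiling():
    a = np.zeros((4, 4), dtype=np.float32)
    b = np.full((4, 4), 0.3, dtype=np.float32)
    assert float(L.style_diversity(a, b)) == pytest.approx(0.3, abs=1e-7)
    assert float(L.style_diversity(a, b, ceiling=0.1)) == pytest.approx(0.1)


def test_image_gradient_of_ramp():
    """Forward differences of a horizontal ramp: constant 1 along x, 0 along
    y, with zero diffs at the replicated edge."""
    x = np.tile(np.arange(5, dtype=np.float32), (4, 1))
    g = np.asarray(L.image_gradient(x).data)
    gx, gy = g[:4], g[4:]
    assert np.allclose(gx, 0.0)  # ramp varies along axis 1 (width)
    assert np.allclose(gy[:, :-1], 1.0)
    assert np.allclose(gy[:, -1], 0.0)


def test_cycle_loss_constant_offset_drops_gradient_term():
    x = np.linspace(0, 1, 36).reshape(6, 6).astype(np.float32)
    x_hat = x + np.float32(0.2)
    assert float(L.cycle_loss(x, x_hat, lambda_g=0.1)) == pytest.approx(
        0.2, abs=1e-6)


def test_cycle_loss_matches_bruteforce_on_ramp_vs_constant():
    w = 6
    x = np.tile(np.arange(w, dtype=np.float32) / w, (w, 1))
    x_hat = np.full((w, w), 0.25, dtype=np.float32)
    lam = 0.1
    pix = _loop_l1(x, x_hat)

    def grads(img):
        gx = np.zeros_like(img)
        gy = np.zeros_like(img)
        gx[:-1] = img[1:] - img[:-1]
        gy[:, :-1] = img[:, 1:] - img[:, :-1]
        return np.concatenate([gx, gy], axis=0)

    grad = _loop_l1(grads(x), grads(x_hat))
    assert float(L.cycle_loss(x, x_hat, lam)) == pytest.approx(
        pix + lam * grad, abs=1e-6)


def test_total_loss_hand_computed_weighted_sum():
    """Published weights, diversity maximized: hand-computed total."""
    terms = {"adv": -1.3863, "cont": 0.1, "ca": 0.5, "sd": 0.2, "sty": 0.05,
             "cyc": 0.3, "id": 0.1}
    report = L.total_loss(terms, L.LossWeights())
    # -1.3863 + 10*0.1 + 0.01*0.5 - 1*0.2 + 10*0.05 + 10*0.3 + 10*0.1
    assert report.total == pytest.approx(3.9187, abs=1e-6)
    literal = L.total_loss(terms, L.LossWeights(), diversity_sign=1)
    assert literal.total == pytest.approx(3.9187 + 0.4, abs=1e-6)


def test_total_loss_linearity_in_weights():
    terms = {"adv": -1.0, "cont": 0.2, "ca": 0.4, "sd": 0.1, "sty": 0.3,
             "cyc": 0.5, "id": 0.6}
    w1 = L.LossWeights()
    w2 = L.LossWeights(lambda_adv=1.0, lambda_cont=20, lambda_ca=0.02,
                       lambda_sd=2, lambda_sty=20, lambda_cyc=20,
                       lambda_g=0.2, lambda_id=20)
    t1 = L.total_loss(terms, w1).total
    t2 = L.total_loss(terms, w2).total
    assert t2 - terms["adv"] == pytest.approx(2 * (t1 - terms["adv"]),
                                              rel=1e-6)


def test_total_loss_names_nan_term():
    terms = {"adv": 0.0, "cont": 0.0, "ca": float("nan"), "sd": 0.0,
             "sty": 0.0, "cyc": 0.0, "id": 0.0}
    with pytest.raises(TrainingDivergenceError, match="ca"):
        L.total_loss(terms, L.LossWeights())


def test_negative_weight_rejected():
    with pytest.raises(ValueError):
        L.LossWeights(lambda_cyc=-1.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(-1, 1, width=32), min_size=2, max_size=16),
       st.lists(st.floats(-1, 1, width=32), min_size=2, max_size=16))
def test_l1_terms_nonnegative_and_match_oracle(xs, ys):
    n = min(len(xs), len(ys))
    a = np.array(xs[:n], dtype=np.float32)
    b = np.array(ys[:n], dtype=np.float32)
    v = float(L.identity_loss(a, b))
    assert v >= 0
    assert v == pytest.approx(_loop_l1(a, b), abs=1e-6)
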