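"""Consistency and entropy losses against per-pixel loop oracles and closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mssfseg.losses import (EPS, LossBreakdown, consistency_loss, entropy_loss,
                            entropy_weight, progressive_entropy_loss, total_loss)
from mssfseg.pseudolabel import IGNORE_LABEL


def consistency_loss_oracle(probs, fused, masks):
    """Literal per-pixel, per-model loop."""
    K = len(probs)
    n = fused.size
    total = 0.0
    for k in range(K):
        p = probs[k].ravel()
        m = masks[k].ravel()
        t = fused.ravel()
        for i in range(n):
            if t[i] != IGNORE_LABEL and m[i] == 1:
                pi = min(max(p[i], EPS), 1 - EPS)
                total += -(t[i] * math.log(pi) + (1 - t[i]) * math.log(1 - pi))
    return total / (K * n)


def entropy_loss_oracle(probs, form="bernoulli"):
    K = len(probs)
    n = probs[0].size
    total = 0.0
    for k in range(K):
        for pi in probs[k].ravel():
            pi = min(max(pi, EPS), 1 - EPS)
            if form == "bernoulli":
                total += -(pi * math.log(pi) + (1 - pi) * math.log(1 - pi))
            else:
                total += -pi * math.log(pi)
    return total / (K * n)


def random_instance(rng, k):
    probs = [rng.random((8, 8)) for _ in range(k)]
    fused = rng.integers(0, 3, size=(8, 8)).astype(np.uint8)
    masks = [(rng.random((8, 8)) > 0.3).astype(np.uint8) for _ in range(k)]
    return probs, fused, masks


class TestConsistencyLoss:
    def test_everything_invalid_gives_zero(self, rng):
        probs = [rng.random((4, 4))]
        fused = np.full((4, 4), IGNORE_LABEL, dtype=np.uint8)
        masks = [np.ones((4, 4), dtype=np.uint8)]
        assert consistency_loss(probs, fused, masks) == 0.0

    def test_single_pixel_half_probability(self):
        out = consistency_loss([np.array([[0.5]])], np.array([[1]], dtype=np.uint8),
                               [np.array([[1]], dtype=np.uint8)])
        assert out == pytest.approx(math.log(2), abs=1e-6)

    def test_perfect_prediction_is_almost_free(self, rng):
        fused = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        probs = [fused.astype(float)]
        masks = [np.ones_like(fused)]
        assert consistency_loss(probs, fused, masks) < 1e-5

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_loop_oracle(self, k):
        rng = np.random.default_rng(100 + k)
        for _ in range(5):
            probs, fused, masks = random_instance(rng, k)
            fast = consistency_loss(probs, fused, masks)
            slow = consistency_loss_oracle(probs, fused, masks)
            assert fast == pytest.approx(slow, abs=1e-9)

    def test_moving_toward_target_decreases_loss(self, rng):
        probs, fused, masks = random_instance(rng, 2)
        fused = np.clip(fused, 0, 1)  # all pixels valid targets
        masks = [np.ones_like(fused) for _ in range(2)]
        base = consistency_loss(probs, fused, masks)
        towards = [p + 0.05 * (fused - p) for p in probs]
        assert consistency_loss(towards, fused, masks) < base

    def test_mask_count_mismatch_raises(self, rng):
        probs, fused, masks = random_instance(rng, 2)
        with pytest.raises(ValueError):
            consistency_loss(probs, fused, masks[:1])


class TestEntropyLoss:
    def test_confident_predictions_carry_no_entropy(self):
        probs = [np.array([[0.0, 1.0], [1.0, 0.0]])]
        assert entropy_loss(probs) < 1e-5

    def test_maximal_at_one_half(self):
        assert entropy_loss([np.full((3, 3), 0.5)]) == pytest.approx(math.log(2), abs=1e-6)

    def test_mixed_map_averages_closed_forms(self):
        probs = [np.array([0.5, 0.5, 1.0, 1.0])]
        assert entropy_loss(probs) == pytest.approx(math.log(2) / 2, abs=1e-5)

    @pytest.mark.parametrize("form", ["bernoulli", "single_term"])
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_loop_oracle(self, k, form):
        rng = np.random.default_rng(17 * k)
        probs = [rng.random((8, 8)) for _ in range(k)]
        assert entropy_loss(probs, form=form) == pytest.approx(
            entropy_loss_oracle(probs, form), abs=1e-9)

    def test_permutation_invariant(self, rng):
        p = rng.random(64)
        perm = rng.permutation(64)
        assert entropy_loss([p]) == pytest.approx(entropy_loss([p[perm]]), abs=1e-12)

    def test_concave_around_one_half(self):
        h = lambda p: entropy_loss([np.array([p])])
        for d in (0.1, 0.2, 0.3):
            assert 0.5 * (h(0.5 - d) + h(0.5 + d)) < h(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            entropy_loss([])


class TestSchedulesAndTotals:
    @pytest.mark.parametrize("epoch,expected", [(0, 0.0), (10, 1.0), (3, 0.3)])
    def test_entropy_weight_ramp(self, epoch, expected):
        assert entropy_weight(0, 1, 10, epoch) == pytest.approx(expected)

    def test_entropy_weight_monotone_non_decreasing(self):
        vals = [entropy_weight(0.2, 0.9, 7, e) for e in range(8)]
        assert vals[0] == 0.2 and vals[-1] == 0.9
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_decreasing_entropy_weight_rejected(self):
        with pytest.raises(ValueError):
            entropy_weight(1.0, 0.5, 10, 0)

    @pytest.mark.parametrize("beta,ent,expected", [(0.0, 0.7, 0.0), (1.0, 0.7, 0.7),
                                                   (0.5, 0.6, 0.3)])
    def test_progressive_entropy_scaling(self, beta, ent, expected):
        assert progressive_entropy_loss(ent, beta) == pytest.approx(expected)

    @given(con=st.floats(0, 10), pro=st.floats(0, 10))
    @settings(max_examples=30, deadline=None)
    def test_total_is_sum_of_parts(self, con, pro):
        bd = total_loss(con, pro)
        assert bd.loss_total == pytest.approx(con + pro)

    def test_breakdown_invariant_pro_ent_equals_beta_times_ent(self):
        ent, beta = 0.42, 0.6
        bd = total_loss(1.0, progressive_entropy_loss(ent, beta), loss_ent=ent, beta=beta)
        assert bd.loss_pro_ent == pytest.approx(bd.beta * bd.loss_ent)

    def test_non_finite_components_rejected(self):
        with pytest.raises(ValueError):
            total_loss(float("nan"), 0.0)
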