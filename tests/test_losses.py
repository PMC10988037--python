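"""Tversky family: worked values, identities, analytic-vs-numeric gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesseg.losses import (
    SoftPrediction,
    TverskyConfig,
    bce_loss,
    dice_loss,
    focal_loss,
    generalized_dice_loss,
    get_loss,
    tversky_gradient,
    tversky_index,
    tversky_loss,
)


def _rand_instance(rng, n=24):
    p0 = rng.uniform(0.01, 0.99, n)
    g0 = (rng.random(n) < 0.4).astype(float)
    return SoftPrediction.from_foreground(p0), g0


class TestTverskyIndex:
    def test_worked_example(self):
        """p0=(.8,.6,.2), g0=(1,1,0), alpha=.3, beta=.7 -> 1.4/1.88."""
        pred = SoftPrediction.from_foreground(np.array([0.8, 0.6, 0.2]))
        g = np.array([1.0, 1.0, 0.0])
        cfg = TverskyConfig(0.3, 0.7, eps=0.0)
        assert tversky_index(pred, g, cfg) == pytest.approx(1.4 / 1.88, abs=1e-12)
        assert tversky_loss(pred, g, cfg) == pytest.approx(1 - 1.4 / 1.88, abs=1e-12)

    def test_perfect_prediction_is_one(self, rng):
        g = (rng.random(50) < 0.3).astype(float)
        pred = SoftPrediction.from_foreground(g)
        for a, b in [(0.3, 0.7), (0.5, 0.5), (0.9, 0.1)]:
            assert tversky_index(pred, g, TverskyConfig(a, b)) == pytest.approx(1.0, abs=1e-4)
            assert tversky_loss(pred, g, TverskyConfig(a, b)) == pytest.approx(0.0, abs=1e-4)

    def test_equals_soft_dice_at_half_half(self, rng):
        for _ in range(20):
            pred, g = _rand_instance(rng)
            t = tversky_index(pred, g, TverskyConfig(0.5, 0.5))
            soft_dice = (2 * np.sum(pred.p0 * g) + 2e-5) / (np.sum(pred.p0) + np.sum(g) + 2e-5)
            assert t == pytest.approx(soft_dice, abs=1e-6)

    def test_index_in_unit_interval(self, rng):
        for _ in range(50):
            pred, g = _rand_instance(rng, n=int(rng.integers(2, 40)))
            a, b = rng.uniform(0, 2, 2)
            if a + b == 0:
                continue
            t = tversky_index(pred, g, TverskyConfig(a, b))
            assert 0.0 <= t <= 1.0 + 1e-12

    def test_loss_increases_with_false_negative_mass(self):
        """Fixed FP mass, growing FN mass: loss strictly increases for beta>0."""
        g = np.array([1.0] * 10 + [0.0] * 10)
        losses = []
        for miss in np.linspace(0.0, 0.6, 7):
            p0 = np.where(g > 0, 1.0 - miss, 0.2)
            losses.append(tversky_loss(SoftPrediction.from_foreground(p0), g,
                                       TverskyConfig(0.3, 0.7)))
        assert np.all(np.diff(losses) > 0)

    def test_shape_mismatch_raises(self):
        pred = SoftPrediction.from_foreground(np.zeros(4))
        with pytest.raises(ValueError, match="shape"):
            tversky_index(pred, np.zeros(5))

    def test_alpha_beta_validation(self):
        with pytest.raises(ValueError):
            TverskyConfig(-0.1, 0.7)
        with pytest.raises(ValueError):
            TverskyConfig(0.0, 0.0)


def _numeric_gradient(pred, g, cfg, h=1e-6):
    """Centred finite differences of the index, p0 and p1 independent."""
    dp0 = np.zeros_like(pred.p0)
    dp1 = np.zeros_like(pred.p1)
    for i in range(pred.p0.size):
        for arr, out in ((pred.p0, dp0), (pred.p1, dp1)):
            orig = arr.flat[i]
            arr.flat[i] = orig + h
            fp = _raw_index(pred.p0, pred.p1, g, cfg)
            arr.flat[i] = orig - h
            fm = _raw_index(pred.p0, pred.p1, g, cfg)
            arr.flat[i] = orig
            out.flat[i] = (fp - fm) / (2 * h)
    return dp0, dp1


def _raw_index(p0, p1, g0, cfg):
    g1 = 1 - g0
    num = np.sum(p0 * g0) + cfg.eps
    den = np.sum(p0 * g0) + cfg.alpha * np.sum(p0 * g1) + cfg.beta * np.sum(p1 * g0) + cfg.eps
    return num / den


class TestTverskyGradient:
    def test_matches_finite_differences(self, rng):
        cfg = TverskyConfig(0.3, 0.7)
        for _ in range(25):
            pred, g = _rand_instance(rng, n=int(rng.integers(4, 16)))
            a0, a1 = tversky_gradient(pred, g, cfg)
            n0, n1 = _numeric_gradient(pred, g, cfg)
            scale = max(np.abs(n0).max(), np.abs(n1).max(), 1e-12)
            assert np.abs(a0 - n0).max() / scale < 1e-4
            assert np.abs(a1 - n1).max() / scale < 1e-4

    def test_background_gradient_vanishes_off_foreground(self, rng):
        """dT/dp1_i = 0 wherever g0_i = 0."""
        pred, g = _rand_instance(rng)
        _, dp1 = tversky_gradient(pred, g, TverskyConfig(0.3, 0.7))
        assert np.all(dp1[g == 0] == 0.0)
        assert np.all(dp1[g == 1] < 0.0)

    def test_finite_at_perfect_binary_prediction(self):
        g = np.array([1.0, 0.0, 1.0, 0.0])
        pred = SoftPrediction.from_foreground(g.copy())
        dp0, dp1 = tversky_gradient(pred, g, TverskyConfig(0.3, 0.7))
        assert np.all(np.isfinite(dp0)) and np.all(np.isfinite(dp1))

    def test_symmetry_under_weight_and_role_swap(self, rng):
        """Swapping alpha<->beta while swapping the FP/FN error roles
        (p0<->p1 against g0<->g1) leaves the index unchanged."""
        pred, g = _rand_instance(rng)
        cfg1, cfg2 = TverskyConfig(0.3, 0.7, eps=0.0), TverskyConfig(0.7, 0.3, eps=0.0)
        t1 = _raw_index(pred.p0, pred.p1, g, cfg1)
        # roles swapped: treat background as the target class
        t2 = _raw_index(pred.p1, pred.p0, 1 - g, cfg2)
        num1 = np.sum(pred.p0 * g)
        num2 = np.sum(pred.p1 * (1 - g))
        # denominators share the weighted error mass; only the overlap differs
        err1 = num1 / t1 - num1
        err2 = num2 / t2 - num2
        assert err1 == pytest.approx(err2, rel=1e-9)


class TestComparisonLosses:
    def test_dice_equals_tversky_half(self, rng):
        for _ in range(10):
            pred, g = _rand_instance(rng)
            assert dice_loss(pred, g) == pytest.approx(
                tversky_loss(pred, g, TverskyConfig(0.5, 0.5)), abs=1e-12
            )

    def test_dice_hand_value(self):
        pred = SoftPrediction.from_foreground(np.array([0.5, 0.5]))
        assert dice_loss(pred, np.array([1.0, 0.0]), eps=0.0) == pytest.approx(0.5, abs=1e-12)

    def test_gdl_perfect_prediction(self, rng):
        g = (rng.random(40) < 0.3).astype(float)
        assert generalized_dice_loss(
            SoftPrediction.from_foreground(g.copy()), g
        ) == pytest.approx(0.0, abs=1e-3)

    def test_gdl_equals_mean_dice_for_symmetric_balanced_input(self):
        """Equal class weights cancel when class volumes are balanced and
        the prediction masses are symmetric."""
        g = np.array([1.0, 1.0, 0.0, 0.0])
        p0 = np.array([0.8, 0.6, 0.4, 0.2])  # sum p0 = sum p1 = 2
        pred = SoftPrediction.from_foreground(p0)
        val = generalized_dice_loss(pred, g, eps=0.0)
        d0 = 2 * np.sum(p0 * g) / (np.sum(p0) + np.sum(g))
        d1 = 2 * np.sum((1 - p0) * (1 - g)) / (np.sum(1 - p0) + np.sum(1 - g))
        assert val == pytest.approx(1 - (d0 + d1) / 2, abs=1e-6)

    def test_gdl_weights_favour_rare_class(self):
        g = np.zeros(100)
        g[:5] = 1  # 5% foreground
        w_fg = 1 / np.sum(g) ** 2
        w_bg = 1 / np.sum(1 - g) ** 2
        assert w_fg > w_bg

    def test_bce_hand_value(self):
        pred = SoftPrediction.from_foreground(np.array([0.9, 0.2, 0.7, 0.4]))
        g = np.array([1.0, 0.0, 1.0, 0.0])
        assert bce_loss(pred, g) == pytest.approx(0.2990011586691898, abs=1e-9)

    def test_bce_uniform_prediction_is_ln2(self):
        pred = SoftPrediction.from_foreground(np.full(8, 0.5))
        assert bce_loss(pred, (np.arange(8) % 2).astype(float)) == pytest.approx(
            np.log(2), abs=1e-9
        )

    def test_focal_reduces_to_bce_at_gamma_zero(self, rng):
        for _ in range(5):
            pred, g = _rand_instance(rng)
            assert focal_loss(pred, g, gamma=0.0, weight=1.0) == pytest.approx(
                bce_loss(pred, g), abs=1e-6
            )

    def test_focal_voxel_value(self):
        pred = SoftPrediction.from_foreground(np.array([0.9]))
        g = np.array([1.0])
        assert focal_loss(pred, g, gamma=2.0) == pytest.approx(
            0.01 * -np.log(0.9), abs=1e-9
        )

    def test_focal_downweights_easy_voxels(self, rng):
        g = np.array([1.0] * 8)
        pred = SoftPrediction.from_foreground(np.full(8, 0.9))
        vals = [focal_loss(pred, g, gamma=gm) for gm in (0.0, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize("name", ["tversky", "dice", "gdl", "bce", "focal"])
    def test_all_losses_zero_at_perfect_and_positive_otherwise(self, name, rng):
        loss = get_loss(name)
        g = (rng.random(60) < 0.25).astype(float)
        perfect = np.clip(g, 1e-6, 1 - 1e-6)
        assert loss(perfect, g) == pytest.approx(0.0, abs=1e-3)
        wrong = np.clip(1 - g, 1e-6, 1 - 1e-6)
        assert loss(wrong, g) > 0.1

    def test_unknown_loss_name(self):
        with pytest.raises(ValueError, match="unknown loss"):
            get_loss("hausdorff")


class TestLossGradientInterface:
    """Every registered loss's analytic gradient matches finite differences."""

    @pytest.mark.parametrize("name,params", [
        ("tversky", {"alpha": 0.3, "beta": 0.7}),
        ("dice", {}),
        ("gdl", {}),
        ("bce", {}),
        ("focal", {"gamma": 2.0}),
    ])
    def test_gradient_vs_finite_differences(self, name, params, rng):
        loss = get_loss(name, **params)
        p0 = rng.uniform(0.05, 0.95, 12)
        g0 = (rng.random(12) < 0.5).astype(float)
        dp0, dp1 = loss.gradient(p0, g0)
        # the scalar interface couples p1 = 1 - p0, so the observable
        # derivative along p0 is dL/dp0 - dL/dp1
        coupled = dp0 - dp1
        h = 1e-6
        for i in range(12):
            orig = p0[i]
            p0[i] = orig + h
            fp = loss(p0, g0)
            p0[i] = orig - h
            fm = loss(p0, g0)
            p0[i] = orig
            num = (fp - fm) / (2 * h)
            assert coupled[i] == pytest.approx(num, rel=1e-3, abs=1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=30), st.integers(min_value=0, max_value=2**32 - 1))
def test_tversky_index_unit_interval_property(n, seed):
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0, 1, n)
    g0 = (rng.random(n) < rng.uniform(0, 1)).astype(float)
    t = tversky_index(SoftPrediction.from_foreground(p0), g0, TverskyConfig(0.3, 0.7))
    assert 0.0 <= t <= 1.0 + 1e-12
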