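"""Attribution methods against closed-form and enumeration oracles."""

import numpy as np
import pytest

from conftest import LinearModel
from xecgarch.architecture import CNNSpec, LayerSpec, pad_signal
from xecgarch.nn import Model
from xecgarch.records import ECGRecord
from xecgarch.xai import (
    METHOD_NAMES,
    NON_NEGATIVE_METHODS,
    exact_shapley,
    explain,
    sampled_shapley,
)
from xecgarch.xai.relprop import _prop_conv, _prop_input_box, relevance_propagation
from xecgarch.xai.shapley import shap_gradient


def _record(x):
    return ECGRecord(samples=np.asarray(x, dtype=float), record_id="t")


class TestGradientOracles:
    w = np.array([0.5, -1.5, 2.0, 0.25])
    x = np.array([0.2, 0.8, 0.4, 1.0])

    def test_vanilla_equals_abs_weights_for_linear_model(self):
        m = explain(LinearModel(self.w), _record(self.x), "vanilla", target_class=1)
        assert np.allclose(m.values, np.abs(self.w))

    def test_itg_equals_input_times_weights(self):
        m = explain(LinearModel(self.w), _record(self.x), "itg", target_class=1)
        assert np.allclose(m.values, self.x * self.w)

    def test_integrated_gradients_completeness_on_linear_model(self):
        """For linear f and zero baseline the path integral is exact:
        IG = |x . w| elementwise."""
        m = explain(
            LinearModel(self.w), _record(self.x), "integrated_gradients", target_class=1
        )
        assert np.allclose(m.values, np.abs(self.x * self.w))

    def test_smoothgrad_on_linear_model_equals_vanilla(self):
        # the gradient is constant, so noise averaging changes nothing
        m = explain(LinearModel(self.w), _record(self.x), "smoothgrad", target_class=1, seed=3)
        assert np.allclose(m.values, np.abs(self.w))

    def test_stochastic_methods_reproducible(self, tiny_model, tiny_records):
        rec = tiny_records[0]
        for meth in ("smoothgrad", "shap"):
            a = explain(tiny_model, rec, meth, target_class=1, seed=9,
                        background=tiny_records[1:3])
            b = explain(tiny_model, rec, meth, target_class=1, seed=9,
                        background=tiny_records[1:3])
            assert np.array_equal(a.values, b.values)

    def test_finite_difference_check(self, tiny_model, tiny_records):
        """Vanilla gradient vs central differences, 100 random coordinates."""
        rec = tiny_records[0]
        m = explain(tiny_model, rec, "vanilla", target_class=1)
        r = tiny_model.spec.pad_size
        x_pad = pad_signal(rec.samples, r)
        rng = np.random.default_rng(0)
        h = 1e-3
        for j in rng.integers(0, rec.n_samples, size=100):
            xp, xm = x_pad.copy(), x_pad.copy()
            xp[r + j] += h
            xm[r + j] -= h
            num = (
                tiny_model.forward(xp[None])[0, 1] - tiny_model.forward(xm[None])[0, 1]
            ) / (2 * h)
            assert abs(abs(num) - m.values[j]) <= 1e-2 * (1 + abs(num))


class TestRelevancePropagationRules:
    def test_z_rule_single_layer(self):
        """x=[1,2], w=[3,-1]: z=1, relevance [3,-2] conserving f(x)=1."""
        a = np.array([[1.0, 2.0]])
        W = np.array([[[3.0, -1.0]]])
        R_out = np.array([[1.0]])  # relevance = the output value
        R_in = _prop_conv("lrp_z", a, W, np.zeros(1), 1, R_out, 0.1, 2.0, 1.0)
        assert np.allclose(R_in, [[3.0, -2.0]])
        assert R_in.sum() == pytest.approx(1.0)

    def test_epsilon_shrinks_relevance_monotonically(self):
        a = np.array([[1.0, 2.0]])
        W = np.array([[[3.0, -1.0]]])
        R_out = np.array([[1.0]])
        mags = []
        for eps in (0.0, 0.5, 2.0, 10.0):
            R = _prop_conv("lrp_epsilon", a, W, np.zeros(1), 1, R_out, eps, 2.0, 1.0)
            mags.append(np.abs(R).sum())
            assert np.all(np.sign(R) == np.sign([[3.0, -2.0]]))
        assert all(m1 > m2 for m1, m2 in zip(mags, mags[1:]))

    def test_w2_rule_input_independent(self):
        W = np.array([[[2.0, -1.0]]])
        R_out = np.array([[1.0]])
        for x in ([0.0, 0.0], [5.0, -3.0]):
            R = _prop_conv("lrp_w2", np.array([x]), W, np.zeros(1), 1, R_out, 0.1, 2.0, 1.0)
            assert np.allclose(R, [[4.0 / 5.0, 1.0 / 5.0]])

    def test_box_rule_zero_input_conserves(self):
        """x=0 with the [0,1] box rule: relevance comes from the bounds term
        and the propagated total is conserved."""
        rng = np.random.default_rng(5)
        W = rng.normal(size=(3, 1, 4))
        a = np.zeros((1, 10))
        R_out = np.abs(rng.normal(size=(3, 7)))
        R_in = _prop_input_box(a, W, np.zeros(3), 1, R_out)
        assert R_in.sum() == pytest.approx(R_out.sum(), abs=1e-4)

    def test_alphabeta_requires_unit_difference(self, tiny_model, tiny_records):
        with pytest.raises(ValueError, match="alpha - beta"):
            relevance_propagation(
                tiny_model, tiny_records[0].samples, "lrp_alphabeta", 1, alpha=2.0, beta=0.5
            )

    def _bias_free_model(self, positive=False, seed=6):
        spec = CNNSpec(
            layers=[
                LayerSpec(5, 2, 6, has_batch_norm=False),
                LayerSpec(3, 2, 4, has_batch_norm=False),
            ]
        )
        m = Model(spec, seed=seed, dtype=np.float64)
        for idx in m.conv_indices:
            m.layers[idx].b[...] = 0.0
            if positive:
                m.layers[idx].W[...] = np.abs(m.layers[idx].W)
        m.dense.b[...] = 0.0
        if positive:
            m.dense.W[...] = np.abs(m.dense.W)
        return m

    def test_lrp_z_conservation_bias_free(self):
        """Total LRP-Z relevance over the padded input equals the logit."""
        m = self._bias_free_model()
        rng = np.random.default_rng(1)
        x = rng.uniform(0.05, 1.0, 120)
        r = m.spec.pad_size
        logit = float(m.forward(pad_signal(x, r)[None])[0, 1])
        _, _, total = relevance_propagation(m, x, "lrp_z", 1)
        assert total == pytest.approx(logit, rel=1e-3)

    def test_lrp_epsilon_total_at_most_logit(self):
        m = self._bias_free_model(positive=True)
        rng = np.random.default_rng(2)
        x = rng.uniform(0.05, 1.0, 120)
        r = m.spec.pad_size
        logit = float(m.forward(pad_signal(x, r)[None])[0, 1])
        assert logit > 0
        _, _, total = relevance_propagation(m, x, "lrp_epsilon", 1, epsilon=0.1)
        assert total <= logit + 1e-9

    def test_dtd_equals_lrp_z_on_positive_net(self):
        """With all-positive weights and no bias, z+ == z and the box rule's
        negative-weight term vanishes, so DTD and LRP-Z coincide."""
        m = self._bias_free_model(positive=True)
        rng = np.random.default_rng(3)
        x = rng.uniform(0.05, 1.0, 120)
        dtd, _, _ = relevance_propagation(m, x, "dtd", 1)
        lrp, _, _ = relevance_propagation(m, x, "lrp_z", 1)
        assert np.allclose(dtd, lrp, atol=1e-8)

    def test_dtd_rejects_out_of_box_input(self, tiny_model):
        with pytest.raises(ValueError, match="box"):
            relevance_propagation(tiny_model, np.linspace(-1, 2, 100), "dtd", 1)


class TestNonNegativityAndRegistry:
    def test_registry_has_thirteen_methods(self):
        assert len(METHOD_NAMES) == 13
        assert len(set(METHOD_NAMES)) == 13

    @pytest.mark.parametrize("method", sorted(NON_NEGATIVE_METHODS))
    def test_declared_methods_non_negative(self, tiny_model, tiny_records, method):
        for rec in tiny_records[:2]:
            # pick the class with the positive logit so DTD has relevance
            x_pad = pad_signal(rec.samples, tiny_model.spec.pad_size)
            target = int(tiny_model.forward(x_pad[None]).argmax())
            m = explain(tiny_model, rec, method, target_class=target, seed=1)
            assert m.values.min() >= 0, method

    def test_unknown_method_rejected(self, tiny_model, tiny_records):
        with pytest.raises(ValueError, match="unknown attribution"):
            explain(tiny_model, tiny_records[0], "lime")

    def test_map_length_matches_signal(self, tiny_model, tiny_records):
        rec = tiny_records[0]
        for meth in ("vanilla", "lrp_epsilon", "gradcam"):
            m = explain(tiny_model, rec, meth, target_class=1)
            assert len(m.values) == rec.n_samples


class TestGradCam:
    def test_all_negative_gradients_give_zero_maps(self, tiny_spec):
        """If dlogit/dA < 0 everywhere, GradCAM weights are negative (map
        clipped to 0) and GradCAM+ weights are exactly 0."""
        m = Model(tiny_spec, seed=4, dtype=np.float64)
        # make the target row of the dense layer strongly negative so the
        # gradient w.r.t. every feature map is negative
        m.dense.W[1, :] = -np.abs(m.dense.W[1, :]) - 1.0
        rng = np.random.default_rng(0)
        m.forward(pad_signal(rng.uniform(0, 1, (8, 150)), tiny_spec.pad_size), train=True)
        rec = _record(rng.uniform(0, 1, 150))
        plain = explain(m, rec, "gradcam", target_class=1)
        plus = explain(m, rec, "gradcam_plus", target_class=1)
        assert np.allclose(plain.values, 0.0)
        assert np.allclose(plus.values, 0.0)

    def test_layer_out_of_range_rejected(self, tiny_model, tiny_records):
        with pytest.raises(ValueError, match="layer"):
            explain(tiny_model, tiny_records[0], "gradcam", target_class=1, layer=99)


class TestShapley:
    def test_two_player_game_enumeration(self):
        """v(empty)=0, v({1})=1, v({2})=2, v({1,2})=4 -> phi = (1.5, 2.5)."""
        table = {(False, False): 0.0, (True, False): 1.0, (False, True): 2.0, (True, True): 4.0}
        v = lambda mask: table[(bool(mask[0]), bool(mask[1]))]
        assert np.allclose(exact_shapley(v, 2), [1.5, 2.5])
        est = sampled_shapley(v, 2, n_draws=10_000, seed=0)
        assert np.allclose(est, [1.5, 2.5], atol=0.1)

    def test_four_player_sampling_matches_enumeration(self):
        rng = np.random.default_rng(7)
        weights = rng.uniform(0.5, 2.0, 4)
        v = lambda mask: float(np.dot(weights, mask) ** 2)
        exact = exact_shapley(v, 4)
        est = sampled_shapley(v, 4, n_draws=10_000, seed=1)
        assert np.allclose(est, exact, atol=0.1)

    def test_linear_model_zero_background(self):
        """Exact Shapley values of a linear game are x . w; the expected-
        gradients estimator recovers them exactly for a linear model."""
        w = np.array([0.5, -1.5, 2.0, 0.25])
        x = np.array([0.2, 0.8, 0.4, 1.0])
        values, _ = shap_gradient(LinearModel(w), x, [np.zeros(4)], target_class=1,
                                  n_draws=16, seed=0)
        assert np.allclose(values, x * w)

    def test_efficiency_on_model(self, tiny_model, tiny_records):
        """Sum of attributions approximates f(x) - mean f(background)."""
        rec = tiny_records[0]
        bg = [r.samples for r in tiny_records[1:4]]
        values, _ = shap_gradient(tiny_model, rec.samples, bg, target_class=1,
                                  n_draws=512, seed=2)
        r = tiny_model.spec.pad_size
        f = lambda s: float(tiny_model.forward(pad_signal(s, r)[None])[0, 1])
        gap = f(rec.samples) - np.mean([f(b) for b in bg])
        assert values.sum() == pytest.approx(gap, rel=0.1, abs=0.02)

    def test_empty_background_rejected(self, tiny_model, tiny_records):
        with pytest.raises(ValueError, match="background"):
            explain(tiny_model, tiny_records[0], "shap", target_class=1, background=[])
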