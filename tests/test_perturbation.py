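"""Pixel-flipping validator: ranking, perturbation schemes, relative AUC."""

import numpy as np
import pytest

from xecgarch.perturbation import (
    PerturbationCurve,
    compare_methods,
    perturb_interpolation,
    perturb_zero,
    pixel_flipping,
    rank_samples,
    relative_auc,
)
from xecgarch.records import ECGRecord


class TestRanking:
    def test_decreasing_order(self):
        assert rank_samples(np.array([0.1, 0.9, 0.5])).tolist() == [1, 2, 0]

    def test_ties_break_by_index(self):
        assert rank_samples(np.zeros(4)).tolist() == [0, 1, 2, 3]

    def test_is_permutation(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            order = rank_samples(rng.normal(size=50))
            assert sorted(order.tolist()) == list(range(50))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            rank_samples(np.array([0.1, np.nan]))


class TestPerturbation:
    def test_empty_mask_identity(self):
        x = np.array([3.0, 1.0, 4.0])
        assert np.array_equal(perturb_interpolation(x, np.array([], dtype=int)), x)
        assert np.array_equal(perturb_zero(x, np.array([], dtype=int)), x)

    def test_linear_signal_is_fixed_point(self):
        x = np.arange(5.0)
        out = perturb_interpolation(x, np.array([1, 2, 3]))
        assert np.allclose(out, x)

    def test_interpolates_between_neighbors(self):
        out = perturb_interpolation(np.array([0.0, 5.0, 0.0]), np.array([1]))
        assert np.array_equal(out, [0.0, 0.0, 0.0])

    def test_boundary_runs_extend_constant(self):
        out = perturb_interpolation(np.array([7.0, 8.0, 1.0, 9.0]), np.array([0, 3]))
        assert np.array_equal(out, [8.0, 8.0, 1.0, 1.0])

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            perturb_interpolation(np.ones(4), np.arange(4))

    def test_zero_scheme(self):
        x = np.array([1.0, 0.0, 2.0, 3.0])
        out = perturb_zero(x, np.array([0, 2]))
        assert np.array_equal(out, [0.0, 0.0, 0.0, 3.0])
        assert np.array_equal(perturb_zero(x, np.arange(4)), np.zeros(4))

    def test_unmasked_samples_untouched(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        masked = rng.choice(50, size=20, replace=False)
        keep = np.setdiff1d(np.arange(50), masked)
        for fn in (perturb_interpolation, perturb_zero):
            out = fn(x, masked)
            assert np.array_equal(out[keep], x[keep])


class _OneSampleModel:
    """Duck model whose logit depends on exactly one input sample."""

    class _Spec:
        pad_size = 0

    spec = _Spec()

    def __init__(self, j: int):
        self.j = j

    def forward(self, x, train=False):
        if x.ndim == 3:
            x = x[:, 0, :]
        z = 4.0 * (x[:, self.j] - 0.5)
        return np.stack([-z, z], axis=1)


def _records(n_rec=4, n=60, seed=0):
    rng = np.random.default_rng(seed)
    return [
        ECGRecord(samples=rng.uniform(0.4, 1.0, n), label="AF", record_id=f"r{i}")
        for i in range(n_rec)
    ]


class TestPixelFlipping:
    def test_curve_starts_at_baseline(self):
        model = _OneSampleModel(j=10)
        recs = _records()
        curve = pixel_flipping(model, recs, "random", scheme="zero", step=0.25, seed=1)
        from xecgarch.nn import softmax

        x = np.stack([r.samples for r in recs])
        p = softmax(model.forward(x))
        base = float(-np.log(p[:, 1]).mean())
        assert curve.loss[0] == pytest.approx(base, abs=1e-9)
        assert curve.fractions[0] == 0.0

    def test_single_dependency_loss_jumps_at_first_step(self):
        """Ranking the only used sample first moves the whole loss increase
        into the first perturbation step (zero scheme)."""
        j = 17
        model = _OneSampleModel(j)
        recs = _records()
        ranking = [np.concatenate([[j], np.delete(np.arange(60), j)]) for _ in recs]
        curve = pixel_flipping(model, recs, ranking, scheme="zero", step=0.05)
        jump = curve.loss[1] - curve.loss[0]
        later = np.abs(np.diff(curve.loss[1:]))
        assert jump > 0.5
        assert later.max() < 1e-9

    def test_reproducible_random_mode(self):
        model = _OneSampleModel(3)
        recs = _records()
        a = pixel_flipping(model, recs, "random", scheme="interpolation", step=0.25, seed=5)
        b = pixel_flipping(model, recs, "random", scheme="interpolation", step=0.25, seed=5)
        assert np.array_equal(a.loss, b.loss)

    def test_ranking_length_mismatch_rejected(self):
        model = _OneSampleModel(3)
        recs = _records()
        with pytest.raises(ValueError, match="length"):
            pixel_flipping(model, recs, [np.arange(10)] * len(recs), scheme="zero")


class TestRelativeAuc:
    def _curve(self, loss):
        n = len(loss)
        return PerturbationCurve(
            fractions=np.linspace(0, 1, n), loss=np.asarray(loss, float),
            scheme="zero", ranking="random",
        )

    def test_constant_at_normalizer_gives_one(self):
        c = self._curve([2.0] * 11)
        assert relative_auc(c, 2.0).value == pytest.approx(1.0)

    def test_zero_curve_gives_zero(self):
        assert relative_auc(self._curve([0.0] * 11), 5.0).value == 0.0

    def test_step_at_half_gives_half(self):
        loss = [0.0] * 10 + [4.0] * 11  # step between fraction 0.45 and 0.5
        c = self._curve(loss)
        assert relative_auc(c, 4.0).value == pytest.approx(0.5, abs=0.05)

    def test_monotone_in_pointwise_dominance(self):
        lo = self._curve(np.linspace(0, 1, 11))
        hi = self._curve(np.linspace(0, 1, 11) + 0.5)
        assert relative_auc(hi, 2.0).value >= relative_auc(lo, 2.0).value

    def test_normalizer_below_max_rejected(self):
        with pytest.raises(ValueError):
            relative_auc(self._curve([1.0] * 11), 0.5)

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            PerturbationCurve(
                fractions=np.array([0.1, 0.5, 1.0]), loss=np.zeros(3),
                scheme="zero", ranking="random",
            )


class TestCompareMethods:
    def test_full_table_has_56_cells(self, tiny_model, tiny_records):
        """13 methods + random baseline, 2 schemes, 2 models -> 56 rows."""
        models = {"short": tiny_model, "long": tiny_model}
        table = compare_methods(
            models, tiny_records[:3], step=0.25, seed=0,
            background=tiny_records[3:5],
        )
        assert len(table) == (13 + 1) * 2 * 2
        assert table.groupby(["scheme", "model"])["best"].sum().eq(1).all()
        assert ((table["auc"] >= 0) & (table["auc"] <= 1)).all()

    def test_identical_rankings_identical_aucs(self, tiny_model, tiny_records):
        recs = tiny_records[:3]
        orders = [np.argsort(-r.samples, kind="stable") for r in recs]
        a = pixel_flipping(tiny_model, recs, orders, scheme="zero", step=0.25)
        b = pixel_flipping(tiny_model, recs, [o.copy() for o in orders], scheme="zero", step=0.25)
        norm = max(a.loss.max(), b.loss.max())
        assert relative_auc(a, norm).value == relative_auc(b, norm).value
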