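"""Metrics, hyperparameter selection and the weighted softmax ensemble."""

import numpy as np
import pytest

from xecgarch.nn import Model
from xecgarch.records import AF, NON_AF, ECGRecord
from xecgarch.training import (
    EnsembleModel,
    EnsembleWeights,
    FoldResult,
    HyperparamGrid,
    PAPER_BEST_LONG,
    PAPER_BEST_SHORT,
    PAPER_ENSEMBLE_W_LONG,
    _binary_metrics,
    ensemble_predict,
    evaluate,
    optimize_ensemble_weight,
    select_hyperparameters,
    selection_score,
)


class TestMetrics:
    def test_hand_computed_confusion(self):
        """TP=48 FN=2 TN=45 FP=5 -> sens 96, spec 90, acc 93, F1 ~93.2."""
        y_true = np.array([1] * 50 + [0] * 50)
        y_pred = np.array([1] * 48 + [0] * 2 + [0] * 45 + [1] * 5)
        m = _binary_metrics(y_true, y_pred)
        assert m["sensitivity"] == pytest.approx(96.0)
        assert m["specificity"] == pytest.approx(90.0)
        assert m["accuracy"] == pytest.approx(93.0)
        assert m["f1"] == pytest.approx(100 * 2 * 48 / (2 * 48 + 5 + 2), abs=0.05)

    def test_perfect_predictions(self):
        m = _binary_metrics(np.array([0, 1, 1, 0]), np.array([0, 1, 1, 0]))
        assert all(v == 100.0 for v in m.values())

    def test_all_positive_predictor(self):
        m = _binary_metrics(np.array([0, 1] * 10), np.ones(20, dtype=int))
        assert m["sensitivity"] == 100.0 and m["specificity"] == 0.0

    def test_empty_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            evaluate(tiny_model, [])

    def test_fold_result_range_checked(self):
        with pytest.raises(ValueError):
            FoldResult(fold=0, sensitivity=120, specificity=0, accuracy=0, f1=0)


class TestSelection:
    def test_consistency_beats_higher_mean(self):
        """A: steady 0.9; B: mean 0.84 but std 0.196 -> A wins (0.9 > 0.644)."""
        results = {
            (8, 1e-3, 8): [0.9] * 5,
            (8, 1e-4, 8): [1.0, 1.0, 1.0, 0.6, 0.6],
        }
        assert selection_score([1.0, 1.0, 1.0, 0.6, 0.6]) == pytest.approx(0.84 - 0.19595917)
        assert select_hyperparameters(results) == (8, 1e-3, 8)

    def test_single_candidate(self):
        assert select_hyperparameters({(4, 1e-5, 16): [0.1]}) == (4, 1e-5, 16)

    def test_tie_prefers_smaller_lr_then_batch(self):
        results = {
            (32, 1e-3, 8): [0.8, 0.8],
            (32, 1e-4, 8): [0.8, 0.8],
            (4, 1e-4, 8): [0.8, 0.8],
        }
        assert select_hyperparameters(results) == (4, 1e-4, 8)

    def test_permutation_invariant_in_folds(self):
        f1s = [0.91, 0.85, 0.88, 0.95, 0.80]
        assert selection_score(f1s) == pytest.approx(selection_score(f1s[::-1]))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_hyperparameters({})
        with pytest.raises(ValueError):
            HyperparamGrid(batch_sizes=[]).combos()

    def test_published_grid_and_winners(self):
        grid = HyperparamGrid()
        assert len(grid.combos()) == 4 * 3 * 4
        assert (PAPER_BEST_SHORT["batch_size"], PAPER_BEST_SHORT["learning_rate"],
                PAPER_BEST_SHORT["f_last"]) in grid.combos()
        assert (PAPER_BEST_LONG["batch_size"], PAPER_BEST_LONG["learning_rate"],
                PAPER_BEST_LONG["f_last"]) in grid.combos()


class TestEnsemblePredict:
    def test_published_weight_example(self):
        """Weighted mean with w_long = 1.2675 on [0.6,0.4] vs [0.3,0.7]."""
        combined, label = ensemble_predict(
            np.array([0.6, 0.4]), np.array([0.3, 0.7]),
            EnsembleWeights(1.0, PAPER_ENSEMBLE_W_LONG),
        )
        expected = (np.array([0.6, 0.4]) + 1.2675 * np.array([0.3, 0.7])) / 2.2675
        assert np.allclose(combined, expected, atol=1e-4)
        assert np.allclose(combined, [0.4323, 0.5677], atol=1e-4)
        assert label == AF

    def test_equal_inputs_unchanged(self):
        p = np.array([0.25, 0.75])
        combined, _ = ensemble_predict(p, p, EnsembleWeights(1.0, 1.0))
        assert np.allclose(combined, p)

    def test_large_weight_follows_long_model(self):
        combined, label = ensemble_predict(
            np.array([0.9, 0.1]), np.array([0.2, 0.8]), EnsembleWeights(1.0, 1e6)
        )
        assert label == AF and combined[1] > 0.79

    def test_probability_vector_output(self):
        combined, _ = ensemble_predict(
            np.array([0.6, 0.4]), np.array([0.1, 0.9]), EnsembleWeights(1.0, 2.0)
        )
        assert combined.sum() == pytest.approx(1.0)
        assert (combined >= 0).all()

    def test_tie_goes_to_non_af(self):
        _, label = ensemble_predict(
            np.array([0.5, 0.5]), np.array([0.5, 0.5]), EnsembleWeights(1.0, 1.0)
        )
        assert label == NON_AF

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict(np.array([0.9, 0.3]), np.array([0.5, 0.5]), EnsembleWeights())

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            EnsembleWeights(w_long=0.0)


def _const_proba_model(tiny_spec, proba_af: float, seed: int = 0):
    """Model stub giving every record the same AF probability."""

    class Stub:
        class _Spec:
            pad_size = 1

        spec = _Spec()

        def predict_proba(self, x):
            n = x.shape[0]
            return np.tile([1 - proba_af, proba_af], (n, 1))

    return Stub()


class TestWeightOptimization:
    def _records(self, n=20):
        rng = np.random.default_rng(0)
        return [
            ECGRecord(samples=rng.uniform(0, 1, 50), label=AF if i % 2 else NON_AF)
            for i in range(n)
        ]

    def test_identical_models_tie_to_smallest_grid_value(self, tiny_spec):
        recs = self._records()
        model = _const_proba_model(tiny_spec, 0.6)
        grid = np.arange(1.0, 3.0, 0.25)
        w = optimize_ensemble_weight([(model, model)], [recs], weight_grid=grid)
        assert w.w_long == 1.0 and w.w_short == 1.0

    def test_long_dominates_when_short_is_chance(self, tiny_model):
        """Random short model, near-perfect long model: the optimum sits at
        the top of the grid."""
        rng = np.random.default_rng(1)
        recs = self._records(40)

        class GoodLong:
            class _Spec:
                pad_size = 1

            spec = _Spec()

            def predict_proba(self, x):
                # label alternates non-AF/AF by construction of _records
                n = x.shape[0]
                p = np.empty((n, 2))
                p[0::2] = [0.9, 0.1]
                p[1::2] = [0.1, 0.9]
                return p

        class NoisyShort:
            class _Spec:
                pad_size = 1

            spec = _Spec()

            def predict_proba(self, x):
                q = rng.uniform(0.05, 0.95, size=x.shape[0])
                return np.stack([1 - q, q], axis=1)

        grid = np.arange(0.25, 3.01, 0.25)
        w = optimize_ensemble_weight([(NoisyShort(), GoodLong())], [recs], weight_grid=grid)
        # the reliable long model gets upweighted past the grid minimum
        assert w.w_long > grid.min()
        # and the chosen weight achieves a better F1 than the minimum weight
        from xecgarch.training import _f1_percent

        y = np.array([r.label_idx for r in recs])
        rng2 = np.random.default_rng(1)
        q = rng2.uniform(0.05, 0.95, size=len(recs))
        u = (2 * q - 1)
        v = np.where(y == 1, 0.8, -0.8)
        f1_at = lambda w_: _f1_percent(y, (u + w_ * v > 0).astype(int))
        assert f1_at(w.w_long) >= f1_at(grid.min())

    def test_degenerate_fold_skipped(self):
        recs = [r for r in self._records(10) if r.label == AF]
        model = _const_proba_model(None, 0.6)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                optimize_ensemble_weight([(model, model)], [recs])

    def test_published_reference_weight_recorded(self):
        assert PAPER_ENSEMBLE_W_LONG == 1.2675
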