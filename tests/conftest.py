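"""Shared fixtures.

Heavy fixtures (trained networks) are session-scoped and shared across
the evaluation tests so each network is trained exactly once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from xecgarch.architecture import CNNSpec, LayerSpec, pad_signal
from xecgarch.nn import Model
from xecgarch.records import ECGRecord
from xecgarch.synthetic import GeneratorConfig, generate_dataset, train_test_split_records
from xecgarch.preprocess import preprocess_records


@pytest.fixture(scope="session")
def tiny_spec() -> CNNSpec:
    """Three-layer spec with a small receptive field, cheap to evaluate."""
    return CNNSpec(layers=[LayerSpec(5, 2, 8), LayerSpec(3, 2, 4), LayerSpec(3, 1, 2)])


@pytest.fixture(scope="session")
def tiny_model(tiny_spec) -> Model:
    """Random tiny network with populated batch-norm statistics."""
    model = Model(tiny_spec, seed=7, dtype=np.float64)
    rng = np.random.default_rng(0)
    x = pad_signal(rng.uniform(0, 1, (16, 200)), tiny_spec.pad_size)
    model.forward(x, train=True)
    return model


@pytest.fixture(scope="session")
def tiny_records() -> list[ECGRecord]:
    """A few preprocessed-scale (already in [0,1]) random records."""
    rng = np.random.default_rng(42)
    out = []
    for i in range(6):
        out.append(
            ECGRecord(
                samples=rng.uniform(0, 1, 200),
                fs=500.0,
                label="AF" if i % 2 else "non-AF",
                r_peaks=np.array([40, 100, 160]),
                record_id=f"tiny-{i}",
            )
        )
    return out


@pytest.fixture(scope="session")
def synth_dataset() -> list[ECGRecord]:
    """Small preprocessed synthetic dataset with both class signals."""
    cfg = GeneratorConfig()
    return preprocess_records(generate_dataset(cfg, 12, seed=5))


@pytest.fixture(scope="session")
def standard_trained():
    """Short- and long-term networks trained once on a standard synthetic
    dataset (both class signals present); shared across evaluation tests.

    Returns (models dict, train records, held-out test records).
    """
    from xecgarch.architecture import default_spec
    from xecgarch.training import DESK_LONG, DESK_SHORT, train_model

    cfg = GeneratorConfig()
    records = preprocess_records(generate_dataset(cfg, 100, seed=11))
    folds, test = train_test_split_records(records, 0.2, 2, seed=11)
    train = folds[0] + folds[1]
    models = {}
    for scale, hp in (("short", DESK_SHORT), ("long", DESK_LONG)):
        spec = default_spec(scale, f_last=8)
        model, result = train_model(spec, train, test, seed=11, epochs=15, **hp)
        models[scale] = (model, result)
    return models, train, test


class LinearModel:
    """Duck-typed stand-in computing logit_1(x) = w . x exactly.

    Implements the minimal surface the attribution code uses
    (``spec.pad_size``, ``forward``, ``input_gradient``) with zero
    padding, so the closed-form oracles for the gradient and Shapley
    methods hold without edge effects.
    """

    class _Spec:
        pad_size = 0

    def __init__(self, w: np.ndarray):
        self.w = np.asarray(w, dtype=np.float64)
        self.spec = self._Spec()
        self.dtype = np.float64

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim == 3:
            x = x[:, 0, :]
        elif x.ndim == 1:
            x = x[None, :]
        z = x @ self.w
        return np.stack([-z, z], axis=1)

    def predict_proba(self, x):
        from xecgarch.nn import softmax

        return softmax(self.forward(x))

    def input_gradient(self, x, class_idx: int, guided: bool = False):
        if x.ndim == 1:
            x = x[None, :]
        sign = 1.0 if class_idx == 1 else -1.0
        return np.broadcast_to(sign * self.w, x.shape[-2:] if x.ndim == 3 else x.shape).copy()
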