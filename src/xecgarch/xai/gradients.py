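"""Gradient-based attribution methods.

All methods differentiate the target-class logit with respect to the
input samples.  The input handed to the network is the edge-padded
signal; gradients on the padding are cropped away and their absolute
mass reported.

Definitions (x = input, f_c = target logit, x0 = baseline):

* vanilla        |df_c/dx|
* itg            x * df_c/dx                    (input times gradient, signed)
* integrated     |(x - x0) * mean_k df_c/dx at x0 + k/K (x - x0)|, K = 32
* smoothgrad     |mean of 32 vanilla gradients under N(0, (0.1 range)^2) noise|
* guided_backprop  gradient with negative upstream gradients zeroed at ReLUs
"""

from __future__ import annotations

import numpy as np

from ..architecture import pad_signal
from ..nn import Model


def _pad_batch(model: Model, signals: np.ndarray) -> np.ndarray:
    """(N, n) unpadded -> (N, 1, n + 2r) padded network input."""
    return pad_signal(signals, model.spec.pad_size)[:, None, :]


def _crop(model: Model, padded_values: np.ndarray, n: int) -> tuple[np.ndarray, float]:
    r = model.spec.pad_size
    core = padded_values[r : r + n]
    pad_mass = float(np.abs(padded_values).sum() - np.abs(core).sum())
    return core.astype(np.float64), pad_mass


def gradient_method(
    model: Model,
    x: np.ndarray,
    method: str,
    target_class: int,
    seed: int = 0,
    steps: int = 32,
    noise_scale: float = 0.10,
    n_augmentations: int = 32,
    baseline: np.ndarray | None = None,
) -> tuple[np.ndarray, str, float]:
    """Dispatch for the five gradient methods.

    Returns (values over the unpadded signal, postprocessing tag,
    discarded padding mass).
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]

    if method == "vanilla":
        g = model.input_gradient(_pad_batch(model, x[None])[:, 0, :], target_class)[0]
        core, mass = _crop(model, g, n)
        return np.abs(core), "abs", mass

    if method == "guided_backprop":
        g = model.input_gradient(
            _pad_batch(model, x[None])[:, 0, :], target_class, guided=True
        )[0]
        core, mass = _crop(model, g, n)
        return core, "none", mass

    if method == "itg":
        g = model.input_gradient(_pad_batch(model, x[None])[:, 0, :], target_class)[0]
        core, mass = _crop(model, g, n)
        return x * core, "none", mass

    if method == "integrated_gradients":
        x0 = np.zeros_like(x) if baseline is None else np.asarray(baseline, dtype=np.float64)
        alphas = (np.arange(steps) + 0.5) / steps  # midpoint rule on the path
        points = x0[None, :] + alphas[:, None] * (x - x0)[None, :]
        grads = model.input_gradient(_pad_batch(model, points)[:, 0, :], target_class)
        mean_grad = grads.mean(axis=0)
        core, mass = _crop(model, mean_grad, n)
        return np.abs((x - x0) * core), "abs", mass

    if method == "smoothgrad":
        rng = np.random.default_rng(seed)
        sigma = noise_scale * (x.max() - x.min())
        noisy = x[None, :] + rng.normal(0.0, sigma, size=(n_augmentations, n))
        grads = model.input_gradient(_pad_batch(model, noisy)[:, 0, :], target_class)
        mean_grad = grads.mean(axis=0)
        core, mass = _crop(model, mean_grad, n)
        return np.abs(core), "abs", mass

    raise ValueError(f"unknown gradient method {method!r}")
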