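"""Shapley-value attribution.

``exact_shapley`` enumerates every coalition of a small cooperative
game; ``sampled_shapley`` estimates the same values by uniform
permutation sampling (the marginal-contribution form of the Shapley
sum).  Both operate on an arbitrary characteristic function and are
used to validate the model explainer.

``shap_gradient`` is the gradient explainer used on records: Shapley
values of the network are approximated by expected gradients, where an
absent feature takes its value from a randomly drawn background record
and attributions integrate the gradient along the interpolation path
between background and input.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

from ..architecture import pad_signal
from ..nn import Model


def exact_shapley(value_fn, m: int) -> np.ndarray:
    """Exact Shapley values by full coalition enumeration.

    phi_i = 1/m sum_{S not containing i} C(m-1, |S|)^-1 (v(S+i) - v(S));
    ``value_fn`` receives a boolean membership mask of length m.
    Exponential in m -- intended for m <= ~12.
    """
    phi = np.zeros(m)
    players = range(m)
    for i in players:
        others = [j for j in players if j != i]
        for size in range(m):
            for S in combinations(others, size):
                mask = np.zeros(m, dtype=bool)
                mask[list(S)] = True
                v0 = value_fn(mask)
                mask[i] = True
                v1 = value_fn(mask)
                phi[i] += (v1 - v0) / (m * comb(m - 1, size))
    return phi


def sampled_shapley(value_fn, m: int, n_draws: int = 1000, seed: int = 0) -> np.ndarray:
    """Permutation-sampling Shapley estimate (unbiased)."""
    rng = np.random.default_rng(seed)
    phi = np.zeros(m)
    mask = np.zeros(m, dtype=bool)
    for _ in range(n_draws):
        perm = rng.permutation(m)
        mask[:] = False
        v_prev = value_fn(mask)
        for i in perm:
            mask[i] = True
            v_new = value_fn(mask)
            phi[i] += v_new - v_prev
            v_prev = v_new
    return phi / n_draws


def shap_gradient(
    model: Model,
    x: np.ndarray,
    background: list[np.ndarray],
    target_class: int,
    n_draws: int = 64,
    seed: int = 0,
    batch: int = 32,
) -> tuple[np.ndarray, float]:
    """Expected-gradients SHAP for one record.

    Each draw pairs a random background record b with a uniform path
    position alpha; the attribution is the average over draws of
    (x - b) * grad f_c(b + alpha (x - b)).  Seedable and deterministic.
    """
    if not background:
        raise ValueError("background dataset must be non-empty")
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(background), size=n_draws)
    alphas = rng.uniform(0.0, 1.0, size=n_draws)

    bgs = np.stack([np.asarray(background[i], dtype=np.float64) for i in idx])
    points = bgs + alphas[:, None] * (x[None, :] - bgs)
    r = model.spec.pad_size
    grads = []
    for i in range(0, n_draws, batch):
        chunk = pad_signal(points[i : i + batch], r)
        grads.append(model.input_gradient(chunk, target_class))
    g_pad = np.concatenate(grads, axis=0)  # (n_draws, n + 2r)
    core = g_pad[:, r : r + n]
    pad_mass = float(np.abs(g_pad).sum() - np.abs(core).sum()) / n_draws
    values = ((x[None, :] - bgs) * core).mean(axis=0)
    return values.astype(np.float64), pad_mass
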