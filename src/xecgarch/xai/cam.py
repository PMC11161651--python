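"""GradCAM and GradCAM+ for the 1-D GAP-CNNs.

A convolutional layer (by default the last) is selected; each of its
feature maps A_k receives a weight w_k = the mean over positions of the
gradient of the target logit with respect to A_k (GradCAM), or of the
ReLU of that gradient so only positive gradients contribute (GradCAM+).
The heatmap ReLU(sum_k w_k A_k) is then linearly upsampled from the
layer's temporal grid onto the input samples, using the center of each
neuron's receptive field as its input-domain position.
"""

from __future__ import annotations

import numpy as np

from ..architecture import pad_signal, receptive_field
from ..nn import Model


def _layer_geometry(model: Model, layer: int) -> tuple[int, int]:
    """(cumulative stride, receptive field) of spec layer ``layer``."""
    kernels = model.spec.kernels[: layer + 1]
    strides = model.spec.strides[: layer + 1]
    cum = int(np.prod(strides))
    return cum, receptive_field(kernels, strides)


def gradcam(
    model: Model,
    x: np.ndarray,
    target_class: int,
    plus: bool = False,
    layer: int | None = None,
) -> np.ndarray:
    """Relevance map over the unpadded signal from (Grad)CAM(+)."""
    n_layers = len(model.spec.layers)
    layer = n_layers - 1 if layer is None else layer
    if not 0 <= layer < n_layers:
        raise ValueError(f"layer {layer} not in [0, {n_layers})")

    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    r = model.spec.pad_size
    x_pad = pad_signal(x, r)[None, :]

    relu_idx = model.relu_indices[layer]
    model.forward(x_pad, train=False)
    A = model.activations()[relu_idx + 1][0]  # (C, L_layer) post-ReLU
    grad = model.layer_gradient(target_class, relu_idx)[0]  # dlogit/dA

    g = np.maximum(grad, 0.0) if plus else grad
    w = g.mean(axis=1)  # one weight per feature map
    heat = np.maximum((w[:, None] * A).sum(axis=0), 0.0)  # (L_layer,)

    # place each neuron at the center of its receptive field (input coords)
    cum, rf = _layer_geometry(model, layer)
    centers_padded = np.arange(heat.shape[0]) * cum + (rf - 1) / 2.0
    centers = centers_padded - r
    return np.interp(np.arange(n, dtype=np.float64), centers, heat.astype(np.float64))
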