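"""Attribution (xAI) methods for the trained networks.

Thirteen post-hoc explanation methods produce one relevance score per
input sample for a chosen output class: five gradient-based methods
(vanilla gradient, integrated gradients, input times gradient,
SmoothGrad, guided backpropagation), five relevance-propagation methods
(LRP-Z, LRP-epsilon, LRP-alphabeta, LRP-w^2 and deep Taylor
decomposition), the two activation-map methods GradCAM and GradCAM+,
and a gradient-based Shapley-value approximation (SHAP) with a
background dataset for value exchange.

All methods return a :class:`RelevanceMap` whose values are aligned
with the *unpadded* signal; relevance falling on the edge padding is
discarded and its total mass reported for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..nn import Model
from ..records import ECGRecord

from . import cam, gradients, relprop, shapley
from .shapley import sampled_shapley, exact_shapley

__all__ = [
    "RelevanceMap",
    "METHOD_NAMES",
    "explain",
    "sampled_shapley",
    "exact_shapley",
]

#: the full method registry (names as used on the command line)
METHOD_NAMES = (
    "vanilla",
    "integrated_gradients",
    "itg",
    "smoothgrad",
    "guided_backprop",
    "lrp_z",
    "lrp_epsilon",
    "lrp_alphabeta",
    "lrp_w2",
    "dtd",
    "gradcam",
    "gradcam_plus",
    "shap",
)

#: methods whose maps are non-negative by construction
NON_NEGATIVE_METHODS = frozenset(
    {"vanilla", "integrated_gradients", "smoothgrad", "dtd", "gradcam", "gradcam_plus"}
)


@dataclass
class RelevanceMap:
    """Per-sample attribution scores for one record, model and method."""

    values: np.ndarray
    method: str
    target_class: int
    postprocessing: str = "none"  # {"abs", "none"}
    #: relevance mass that fell on the edge padding (discarded from values)
    pad_mass: float = 0.0
    #: signed relevance total over the padded input (propagation methods
    #: conserve this quantity, not the cropped sum)
    total: float | None = None
    record_id: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite relevance values from method {self.method}")


def explain(
    model: Model,
    record: ECGRecord,
    method: str,
    target_class: int | None = None,
    seed: int = 0,
    background: list[ECGRecord] | None = None,
    **options,
) -> RelevanceMap:
    """Compute one relevance map.

    ``target_class`` defaults to the model's predicted class for the
    record.  ``background`` is required for ``shap``.  Extra options are
    forwarded to the method (e.g. ``epsilon``, ``alpha``, ``beta``,
    ``steps``, ``noise_scale``, ``layer``).
    """
    if method not in METHOD_NAMES:
        raise ValueError(f"unknown attribution method {method!r}; known: {METHOD_NAMES}")
    x = record.samples
    if target_class is None:
        from ..training import predict_proba_records

        target_class = int(predict_proba_records(model, [record]).argmax())

    total = None
    if method in ("vanilla", "integrated_gradients", "itg", "smoothgrad", "guided_backprop"):
        values, post, pad_mass = gradients.gradient_method(
            model, x, method, target_class, seed=seed, **options
        )
    elif method in ("lrp_z", "lrp_epsilon", "lrp_alphabeta", "lrp_w2", "dtd"):
        values, pad_mass, total = relprop.relevance_propagation(
            model, x, method, target_class, **options
        )
        post = "none"
    elif method in ("gradcam", "gradcam_plus"):
        values = cam.gradcam(model, x, target_class, plus=(method == "gradcam_plus"), **options)
        post, pad_mass = "none", 0.0
    else:  # shap
        if not background:
            raise ValueError("shap requires a non-empty background dataset")
        values, pad_mass = shapley.shap_gradient(
            model, x, [b.samples for b in background], target_class, seed=seed, **options
        )
        post = "none"

    return RelevanceMap(
        values=values,
        method=method,
        target_class=target_class,
        postprocessing=post,
        pad_mass=pad_mass,
        total=total,
        record_id=record.record_id,
        seed=seed,
    )
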