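"""Pixel-flipping faithfulness validation of attribution methods.

Samples are perturbed in the order given by a relevance ranking (most
relevant first) and the classifier's mean loss is traced as a function
of the perturbed fraction: the truer the ranking, the steeper the loss
increase.  Two perturbation schemes are implemented:

* ``interpolation`` -- the perturbed samples are removed and filled by
  linear interpolation between the nearest surviving neighbors.  This
  preserves the low-frequency structure of the signal and injects no
  out-of-distribution jumps, so randomly ordered perturbation barely
  moves the loss until most samples are gone; loss increases can then
  be attributed to relevance rather than to perturbation noise.
* ``zero`` -- the prevalent scheme of setting samples to zero, which
  injects large artificial steps the model never saw in training.

A random-order baseline quantifies the noise each scheme introduces.
Methods are scored by the relative AUC of their loss curve: the
trapezoidal area under loss-vs-fraction normalized by the area spanned
by the maximum observed loss, so values lie in [0, 1] and rows of the
comparison table share one normalizer per (scheme, model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import pad_signal
from .nn import Model, cross_entropy, softmax
from .records import ECGRecord
from .xai import METHOD_NAMES, RelevanceMap, explain

__all__ = [
    "PerturbationCurve",
    "RelativeAUC",
    "rank_samples",
    "perturb_interpolation",
    "perturb_zero",
    "pixel_flipping",
    "relative_auc",
    "compare_methods",
]

SCHEMES = ("interpolation", "zero")


@dataclass
class PerturbationCurve:
    fractions: np.ndarray
    loss: np.ndarray
    scheme: str
    ranking: str  # attribution method name or "random"
    model_tag: str = ""

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        self.loss = np.asarray(self.loss, dtype=np.float64)
        if self.fractions[0] != 0.0 or np.any(np.diff(self.fractions) <= 0):
            raise ValueError("fractions must start at 0 and increase strictly")
        if self.fractions.shape != self.loss.shape:
            raise ValueError("fractions and loss must have equal length")
        if not np.all(np.isfinite(self.loss)):
            raise ValueError("non-finite loss values in curve")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def baseline_loss(self) -> float:
        return float(self.loss[0])


@dataclass
class RelativeAUC:
    value: float
    normalizer: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"relative AUC {self.value} outside [0, 1]")


def rank_samples(relevance: RelevanceMap | np.ndarray) -> np.ndarray:
    """Indices by decreasing relevance; ties broken by ascending index."""
    values = relevance.values if isinstance(relevance, RelevanceMap) else np.asarray(relevance)
    if np.any(np.isnan(values)):
        raise ValueError("relevance contains NaN")
    # stable sort on negated values keeps ascending-index order within ties
    return np.argsort(-values, kind="stable")


def perturb_interpolation(signal: np.ndarray, masked: np.ndarray) -> np.ndarray:
    """Replace masked samples by linear interpolation between the nearest
    unmasked neighbors; boundary runs extend the nearest surviving value."""
    signal = np.asarray(signal, dtype=np.float64)
    n = signal.shape[0]
    mask = np.zeros(n, dtype=bool)
    mask[np.asarray(masked, dtype=np.int64)] = True
    if mask.all():
        raise ValueError("cannot interpolate with every sample masked")
    if not mask.any():
        return signal.copy()
    keep = np.flatnonzero(~mask)
    out = signal.copy()
    # np.interp extends the edge values constantly beyond the anchors
    out[mask] = np.interp(np.flatnonzero(mask), keep, signal[keep])
    return out


def perturb_zero(signal: np.ndarray, masked: np.ndarray) -> np.ndarray:
    out = np.asarray(signal, dtype=np.float64).copy()
    out[np.asarray(masked, dtype=np.int64)] = 0.0
    return out


_PERTURB = {"interpolation": perturb_interpolation, "zero": perturb_zero}


def _mean_loss(model: Model, signals: np.ndarray, labels: np.ndarray, batch: int = 64) -> float:
    x = pad_signal(signals, model.spec.pad_size)
    losses = []
    for i in range(0, len(x), batch):
        p = softmax(model.forward(x[i : i + batch]))
        losses.append(
            -np.log(p[np.arange(len(p)), labels[i : i + batch]] + 1e-12)
        )
    return float(np.concatenate(losses).mean())


def pixel_flipping(
    model: Model,
    records: list[ECGRecord],
    rankings: list[np.ndarray] | str,
    scheme: str = "interpolation",
    step: float = 0.02,
    seed: int = 0,
    model_tag: str = "",
) -> PerturbationCurve:
    """Loss-vs-perturbed-fraction curve for one ranking source.

    ``rankings`` is either one precomputed sample ordering per record
    (most relevant first) or the string ``"random"`` for the seeded
    random baseline.  At each fraction on the grid the top fraction of
    each record's ordering is perturbed, the records are reclassified,
    and the mean categorical cross-entropy against the true labels is
    recorded.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if not records:
        raise ValueError("no records given")
    n = records[0].n_samples
    ranking_name = "random"
    if isinstance(rankings, str):
        if rankings != "random":
            raise ValueError("rankings must be a list of orderings or 'random'")
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(n) for _ in records]
    else:
        if len(rankings) != len(records):
            raise ValueError("one ranking per record required")
        orders = [np.asarray(o, dtype=np.int64) for o in rankings]
        for o in orders:
            if o.shape[0] != n:
                raise ValueError("ranking length does not match record length")
        ranking_name = "method"

    labels = np.array([r.label_idx for r in records])
    signals = np.stack([r.samples for r in records])
    perturb = _PERTURB[scheme]

    n_steps = int(round(1.0 / step))
    fractions = np.linspace(0.0, 1.0, n_steps + 1)
    losses = np.empty_like(fractions)
    for j, frac in enumerate(fractions):
        k = int(round(frac * n))
        if k == 0:
            batch_sig = signals
        else:
            k_eff = min(k, n - 1) if scheme == "interpolation" else k
            batch_sig = np.stack(
                [perturb(sig, order[:k_eff]) for sig, order in zip(signals, orders)]
            )
        losses[j] = _mean_loss(model, batch_sig, labels)
    return PerturbationCurve(
        fractions=fractions, loss=losses, scheme=scheme, ranking=ranking_name,
        model_tag=model_tag,
    )


def relative_auc(curve: PerturbationCurve, normalizer: float) -> RelativeAUC:
    """Trapezoidal area under the curve divided by the area spanned by
    the maximum loss score (normalizer x unit fraction range)."""
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    if normalizer < curve.loss.max() - 1e-12:
        raise ValueError(
            f"normalizer {normalizer} below curve maximum {curve.loss.max()}"
        )
    area = float(np.trapezoid(curve.loss, curve.fractions))
    return RelativeAUC(value=area / normalizer, normalizer=normalizer)


def compare_methods(
    models: dict[str, Model],
    records: list[ECGRecord],
    methods: tuple[str, ...] = METHOD_NAMES,
    schemes: tuple[str, ...] = SCHEMES,
    step: float = 0.02,
    seed: int = 0,
    background: list[ECGRecord] | None = None,
) -> pd.DataFrame:
    """Relative-AUC table over (method + random) x scheme x model.

    The normalizer is shared within each (scheme, model) pair: the
    maximum loss observed across all rankings including the random
    baseline, so the rows are mutually comparable.  Columns:
    ``scheme, model, ranking, auc, best, second``.
    """
    rows = []
    for model_tag, model in models.items():
        maps = {
            meth: [
                explain(model, r, meth, seed=seed, background=background)
                for r in records
            ]
            for meth in methods
        }
        for scheme in schemes:
            curves = {}
            for meth in methods:
                orders = [rank_samples(m) for m in maps[meth]]
                curves[meth] = pixel_flipping(
                    model, records, orders, scheme=scheme, step=step,
                    seed=seed, model_tag=model_tag,
                )
            curves["random"] = pixel_flipping(
                model, records, "random", scheme=scheme, step=step,
                seed=seed, model_tag=model_tag,
            )
            normalizer = max(c.loss.max() for c in curves.values())
            aucs = {
                name: relative_auc(c, normalizer).value for name, c in curves.items()
            }
            ranked = sorted(aucs, key=aucs.get, reverse=True)
            for name, auc in aucs.items():
                rows.append(
                    {
                        "scheme": scheme,
                        "model": model_tag,
                        "ranking": name,
                        "auc": auc,
                        "best": name == ranked[0],
                        "second": name == ranked[1],
                    }
                )
    return pd.DataFrame(rows)
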