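"""Layer-wise relevance propagation (LRP) and deep Taylor decomposition.

The target-class logit is redistributed backwards through the network
layer by layer; each rule assigns a neuron's relevance to its inputs in
proportion to (modified) contributions z_ij and differs only in the
choice of root point / stabilization:

* LRP-Z          z_ij = x_i w_ij,            denominators z_j (+ bias)
* LRP-epsilon    like Z with denominators z_j + eps * sign(z_j)
* LRP-alphabeta  positive and negative contributions weighted alpha/beta
                 (alpha - beta = 1; defaults alpha=2, beta=1), with an
                 optional epsilon stabilizer in both denominators
* LRP-w^2        z_ij = w_ij^2 (input independent)
* DTD            z+ rule (positive weights only) in hidden layers and
                 the box rule z^B on the [0, 1]-bounded input layer;
                 relevance stays non-negative throughout

Batch-norm layers are folded into the adjacent convolution before
propagation, so the propagated network is exactly the evaluation-mode
network.  Relevance entering the GAP head is spread over positions in
proportion to the (non-negative) activations.  All arithmetic is
float64.
"""

from __future__ import annotations

import numpy as np

from ..architecture import pad_signal
from ..nn import Model

_STAB = 1e-9


def _conv(a: np.ndarray, W: np.ndarray, stride: int) -> np.ndarray:
    """Valid 1-D convolution, a: (C_in, L), W: (C_out, C_in, k) -> (C_out, L_out)."""
    k = W.shape[2]
    win = np.lib.stride_tricks.sliding_window_view(a, k, axis=1)[:, ::stride, :]
    return np.einsum("clk,ock->ol", win, W, optimize=True)


def _conv_t(s: np.ndarray, W: np.ndarray, stride: int, in_len: int) -> np.ndarray:
    """Transpose of :func:`_conv`: s: (C_out, L_out) -> (C_in, in_len)."""
    c_out, l_out = s.shape
    out = np.zeros((W.shape[1], in_len))
    for t in range(W.shape[2]):
        contrib = np.tensordot(s, W[:, :, t], axes=(0, 0))  # (L_out, C_in)
        out[:, t : t + stride * l_out : stride] += contrib.T
    return out


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    return num / (den + _STAB * np.sign(den) + (den == 0) * _STAB)


def _forward_folded(model: Model, x_pad: np.ndarray):
    """Eval-mode forward through the BN-folded conv stack.

    Returns (per-layer input activations, folded (W, b, stride) list,
    GAP output, logits)."""
    convs = model.folded_convs()
    acts = [x_pad]  # acts[l] is the input of conv l
    a = x_pad
    for W, b, s in convs:
        z = _conv(a, W, s) + b[:, None]
        a = np.maximum(z, 0.0)
        acts.append(a)
    g = a.mean(axis=1)
    dense = model.dense
    logits = np.asarray(dense.W, dtype=np.float64) @ g + np.asarray(dense.b, dtype=np.float64)
    return acts, convs, g, logits


def _prop_dense(rule, Wrow, b, g, R):
    """Relevance from the target logit to the GAP vector."""
    if rule == "lrp_w2":
        w2 = Wrow**2
        return w2 / (w2.sum() + _STAB) * R
    if rule in ("dtd", "zplus"):
        z = np.maximum(Wrow, 0.0) * g
        return _safe_div(z, z.sum()) * R
    if rule == "lrp_alphabeta":
        return None  # handled by caller with alpha/beta
    z = Wrow * g
    den = z.sum() + b
    return _safe_div(z, den) * R


def _prop_conv(rule, a, W, b, stride, R, eps, alpha, beta):
    """One conv layer of relevance propagation; a: input, R: relevance of
    the layer output (pre-GAP activations)."""
    in_len = a.shape[1]
    if rule == "lrp_w2":
        W2 = W**2
        den = W2.sum(axis=(1, 2))  # per output channel
        S = R / (den[:, None] + _STAB)
        return _conv_t(S, W2, stride, in_len)
    if rule in ("dtd", "zplus"):
        Wp = np.maximum(W, 0.0)
        Zp = _conv(a, Wp, stride)
        S = _safe_div(R, Zp)
        return a * _conv_t(S, Wp, stride, in_len)
    if rule == "lrp_alphabeta":
        Wp, Wn = np.maximum(W, 0.0), np.minimum(W, 0.0)
        bp, bn = np.maximum(b, 0.0), np.minimum(b, 0.0)
        Zp = _conv(a, Wp, stride) + bp[:, None]
        Zn = _conv(a, Wn, stride) + bn[:, None]
        Sp = R / (Zp + eps + _STAB)
        Sn = R / (Zn - eps - _STAB)
        return a * (alpha * _conv_t(Sp, Wp, stride, in_len) - beta * _conv_t(Sn, Wn, stride, in_len))
    # z and epsilon rules
    Z = _conv(a, W, stride) + b[:, None]
    if rule == "lrp_epsilon":
        S = R / (Z + eps * np.sign(Z) + (Z == 0) * eps)
    else:  # lrp_z
        S = _safe_div(R, Z)
    return a * _conv_t(S, W, stride, in_len)


def _prop_input_box(a, W, b, stride, R, lo=0.0, hi=1.0):
    """DTD z^B rule for the box-constrained input layer."""
    in_len = a.shape[1]
    Wp, Wn = np.maximum(W, 0.0), np.minimum(W, 0.0)
    ones = np.ones_like(a)
    Z = _conv(a, W, stride) - lo * _conv(ones, Wp, stride) - hi * _conv(ones, Wn, stride)
    S = _safe_div(R, Z)
    return (
        a * _conv_t(S, W, stride, in_len)
        - lo * _conv_t(S, Wp, stride, in_len)
        - hi * _conv_t(S, Wn, stride, in_len)
    )


def relevance_propagation(
    model: Model,
    x: np.ndarray,
    rule: str,
    target_class: int,
    epsilon: float = 0.1,
    alpha: float = 2.0,
    beta: float = 1.0,
    input_low: float = 0.0,
    input_high: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Propagate the target logit's relevance to the input samples.

    Returns (per-sample relevance over the unpadded signal, discarded
    padding mass).  For DTD, propagation starts from the positive part
    of the logit so the resulting map is non-negative.
    """
    if rule == "lrp_alphabeta" and abs(alpha - beta - 1.0) > 1e-9:
        raise ValueError("alpha - beta must equal 1")
    if rule == "dtd":
        tol = 1e-6
        if x.min() < input_low - tol or x.max() > input_high + tol:
            raise ValueError(
                f"DTD box rule expects inputs in [{input_low}, {input_high}]; "
                f"got range [{x.min():.4g}, {x.max():.4g}]"
            )
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    r = model.spec.pad_size
    x_pad = pad_signal(x, r)[None, :]  # (1, L) single-channel

    acts, convs, g, logits = _forward_folded(model, x_pad)
    logit = logits[target_class]
    R_start = max(logit, 0.0) if rule == "dtd" else logit

    dense = model.dense
    Wrow = np.asarray(dense.W, dtype=np.float64)[target_class]
    b_dense = float(np.asarray(dense.b, dtype=np.float64)[target_class])

    if rule == "lrp_alphabeta":
        zp = np.maximum(Wrow, 0.0) * g
        zn = np.minimum(Wrow, 0.0) * g
        denp = zp.sum() + max(b_dense, 0.0) + epsilon + _STAB
        denn = zn.sum() + min(b_dense, 0.0) - epsilon - _STAB
        R_g = (alpha * zp / denp - beta * zn / denn) * R_start
    else:
        R_g = _prop_dense(rule, Wrow, b_dense, g, R_start)

    # GAP: spread channel relevance over positions, proportional to the
    # non-negative activations (uniform for the input-agnostic w^2 rule)
    a_last = acts[-1]  # (C, L_last)
    L_last = a_last.shape[1]
    if rule == "lrp_w2":
        R = np.repeat(R_g[:, None], L_last, axis=1) / L_last
    else:
        denom = a_last.sum(axis=1, keepdims=True)
        R = _safe_div(a_last, denom) * R_g[:, None]

    for l in range(len(convs) - 1, -1, -1):
        W, b, stride = convs[l]
        a_in = acts[l]
        if l == 0 and rule == "dtd":
            R = _prop_input_box(a_in, W, b, stride, R, lo=input_low, hi=input_high)
        else:
            R = _prop_conv(rule, a_in, W, b, stride, R, epsilon, alpha, beta)

    values = R[0]  # single input channel
    core = values[r : r + n]
    pad_mass = float(np.abs(values).sum() - np.abs(core).sum())
    if rule == "dtd":
        core = np.maximum(core, 0.0)  # clip float round-off below zero
    # signed sum over the *whole* padded input: the quantity conserved by
    # the propagation rules (the cropped map alone is not)
    total = float(values.sum())
    return core.astype(np.float64), pad_mass, total
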