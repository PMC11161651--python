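"""Receptive-field arithmetic and network design.

A stack of L valid (unpadded) 1-D convolutions with kernel sizes
``k_l`` and strides ``s_l`` has, at its last layer, a receptive field of

    r = sum_{l=1..L} (k_l - 1) * prod_{i=1..l-1} s_i  +  1

input samples.  The two networks of the ensemble are designed by fixing
the depth (nine layers) and *solving* this equation for (k, s): 300
samples (0.6 s at 500 Hz, at most one beat) for the short-term model,
5000 samples (the whole 10-s record) for the long-term model.

``solve_configuration`` makes that solve deterministic: it returns the
layer configuration whose receptive field equals the target exactly,
minimizing the largest kernel size over all feasible (strides, kernels)
assignments in the given ranges, with ties broken by lexicographically
smallest strides, then kernels.  Spreading the receptive field over
uniform small kernels instead of a few large ones keeps the parameter
count and per-layer cost low and reproduces the natural hand solution
for stride-1 stacks (e.g. target 19 over 9 layers -> all kernels 3).

Signals are padded before entering a network with r repetitions of the
first value on the left and r of the last value on the right, so edge
samples are covered by as many receptive fields as central ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "LayerSpec",
    "CNNSpec",
    "SolverConstraints",
    "receptive_field",
    "solve_configuration",
    "pad_signal",
    "feature_map_schedule",
    "build_model",
]

#: published design targets: short-term 0.6 s, long-term 10 s at 500 Hz
R_SHORT = 300
R_LONG = 5000
N_LAYERS = 9

#: default stride patterns of the two shipped designs.  The short-term
#: network keeps near-full temporal resolution in its early layers (beat
#: morphology lives at the 10-50 ms scale); the long-term network
#: downsamples aggressively from the start, since its job is coarse
#: multi-beat structure and its receptive field must span the whole
#: record.  Kernels are back-solved exactly by ``solve_configuration``.
SHORT_STRIDES = (2, 2, 2, 1, 1, 1, 1, 1, 1)
LONG_STRIDES = (4, 2, 2, 2, 2, 2, 2, 2, 1)


@dataclass
class LayerSpec:
    kernel_size: int
    stride: int
    feature_maps: int
    has_batch_norm: bool = True
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.stride < 1 or self.feature_maps < 1:
            raise ValueError("kernel_size, stride and feature_maps must be >= 1")


@dataclass
class CNNSpec:
    """Layer-by-layer description of one GAP-CNN.

    The convolutional stack is followed by global average pooling and a
    softmax layer of size two; ``pad_size`` (== receptive field) is the
    per-side edge padding applied to inputs.
    """

    layers: list[LayerSpec] = field(default_factory=list)

    @property
    def kernels(self) -> list[int]:
        return [l.kernel_size for l in self.layers]

    @property
    def strides(self) -> list[int]:
        return [l.stride for l in self.layers]

    @property
    def receptive_field(self) -> int:
        return receptive_field(self.kernels, self.strides)

    @property
    def pad_size(self) -> int:
        return self.receptive_field

    @property
    def f_last(self) -> int:
        return self.layers[-1].feature_maps

    def to_json(self) -> str:
        return json.dumps(
            {
                "layers": [
                    {
                        "kernel_size": l.kernel_size,
                        "stride": l.stride,
                        "feature_maps": l.feature_maps,
                        "has_batch_norm": l.has_batch_norm,
                        "activation": l.activation,
                    }
                    for l in self.layers
                ],
                "receptive_field": self.receptive_field,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CNNSpec":
        data = json.loads(text)
        return cls(layers=[LayerSpec(**l) for l in data["layers"]])


@dataclass
class SolverConstraints:
    target_r: int
    n_layers: int = N_LAYERS
    kernel_range: tuple[int, int] = (1, 24)
    stride_range: tuple[int, int] = (1, 4)
    objective: str = "min_max_kernel"
    #: require kernel >= stride in every layer so no input sample is skipped
    require_full_coverage: bool = True
    #: optionally pin the stride pattern; the solver then only back-solves kernels
    strides: tuple[int, ...] | None = None

    def validate(self) -> None:
        if self.target_r < 1:
            raise ValueError("target_r must be >= 1")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.strides is not None:
            if len(self.strides) != self.n_layers:
                raise ValueError("fixed strides must list one stride per layer")
            if any(s < 1 for s in self.strides):
                raise ValueError("strides must be >= 1")
        for lo, hi in (self.kernel_range, self.stride_range):
            if lo < 1 or hi < lo:
                raise ValueError("ranges must satisfy 1 <= lo <= hi")
        if self.objective != "min_max_kernel":
            raise ValueError(f"unknown objective {self.objective!r}")


def receptive_field(kernels: list[int], strides: list[int]) -> int:
    """Closed-form receptive field of the last layer of a conv stack."""
    if len(kernels) == 0 or len(kernels) != len(strides):
        raise ValueError("kernels and strides must be equal-length, non-empty")
    if any(k < 1 for k in kernels) or any(s < 1 for s in strides):
        raise ValueError("kernel and stride sizes must be >= 1")
    r, jump = 1, 1
    for k, s in zip(kernels, strides):
        r += (k - 1) * jump
        jump *= s
    return r


def feature_map_schedule(f_last: int, n_layers: int = N_LAYERS) -> list[int]:
    """Depth-decreasing schedule: first third 4f, middle third 2f, last third f."""
    thirds = np.array_split(np.arange(n_layers), 3)
    mult = {0: 4, 1: 2, 2: 1}
    out = []
    for g, idx in enumerate(thirds):
        out.extend([mult[g] * f_last] * len(idx))
    return out


def pad_signal(signal: np.ndarray, r: int) -> np.ndarray:
    """Edge-pad with r repetitions of the first/last value on each side."""
    if r < 0:
        raise ValueError("padding size must be >= 0")
    signal = np.asarray(signal)
    if signal.shape[-1] == 0:
        raise ValueError("cannot pad an empty signal")
    if r == 0:
        return signal.copy()
    return np.concatenate(
        [
            np.repeat(signal[..., :1], r, axis=-1),
            signal,
            np.repeat(signal[..., -1:], r, axis=-1),
        ],
        axis=-1,
    )


# --- exact digit-representation search -------------------------------------
#
# With c_l = prod_{i<l} s_i and digits d_l = k_l - 1, the receptive-field
# equation becomes  target - 1 = sum d_l * c_l  with  d_l in [dlo, dhi].
# Representability is decided by depth-first search over digits of the
# largest weights first, pruned by suffix-sum bounds.


@lru_cache(maxsize=500_000)
def _representable(T: int, terms: tuple[tuple[int, int], ...]) -> bool:
    """Is T == sum d_l * c_l with 0 <= d_l <= hi_l for terms (c_l, hi_l)?

    Terms must be sorted by decreasing c.  Depth-first with suffix-sum
    pruning; term counts here are tiny (<= n_layers).
    """
    if not terms:
        return T == 0
    # suffix capacity: max attainable by terms i..end
    caps = [0] * (len(terms) + 1)
    for i in range(len(terms) - 1, -1, -1):
        caps[i] = caps[i + 1] + terms[i][0] * terms[i][1]
    if not 0 <= T <= caps[0]:
        return False

    def rec(i: int, rem: int) -> bool:
        if i == len(terms):
            return rem == 0
        c, hi = terms[i]
        if rem > caps[i]:
            return False
        d_max = min(hi, rem // c)
        # need rem - d*c <= caps[i+1]  ->  d >= (rem - caps[i+1]) / c
        d_min = max(0, -((caps[i + 1] - rem) // c)) if rem > caps[i + 1] else 0
        for d in range(d_max, d_min - 1, -1):
            if rec(i + 1, rem - d * c):
                return True
        return False

    return rec(0, T)


def _cumulative_weights(strides: tuple[int, ...]) -> tuple[int, ...]:
    c, jump = [], 1
    for s in strides:
        c.append(jump)
        jump *= s
    return tuple(c)


def _digit_bounds(
    strides: tuple[int, ...], kmin: int, kmax: int, coverage: bool
) -> tuple[tuple[int, ...], int] | None:
    """Per-layer digit lower bounds (k_l - 1 >= dlo_l) and their base cost."""
    dlos = tuple(
        max(kmin, s if coverage else 1) - 1 for s in strides
    )
    if any(d > kmax - 1 for d in dlos):
        return None
    return dlos, 0


def _reduced_terms(
    c: tuple[int, ...], dlos: tuple[int, ...], K: int
) -> tuple[int, tuple[tuple[int, int], ...]]:
    """Shift per-layer lower bounds out: residual target offset and terms
    (c_l, K-1-dlo_l) sorted by decreasing weight."""
    offset = sum(d * w for d, w in zip(dlos, c))
    terms = tuple(
        sorted(
            ((w, K - 1 - d) for w, d in zip(c, dlos) if K - 1 - d > 0),
            key=lambda t: -t[0],
        )
    )
    return offset, terms


def _min_max_kernel(
    T: int, c: tuple[int, ...], dlos: tuple[int, ...], kmin: int, kmax: int
) -> int | None:
    """Smallest max-kernel K such that T is exactly representable."""
    lo = max(kmin, max(dlos) + 1)
    hi, best = kmax, None
    while lo <= hi:
        mid = (lo + hi) // 2
        offset, terms = _reduced_terms(c, dlos, mid)
        if _representable(T - offset, terms):
            best, hi = mid, mid - 1
        else:
            lo = mid + 1
    return best


def _lexsmallest_kernels(
    T: int, c: tuple[int, ...], dlos: tuple[int, ...], kmin: int, K: int
) -> list[int]:
    """Lexicographically smallest kernel vector (layer order) achieving T
    with all kernels <= K and k_l - 1 >= dlo_l."""
    kernels: list[int] = []
    rem = T
    for i in range(len(c)):
        rest_c, rest_d = c[i + 1 :], dlos[i + 1 :]
        offset, terms = _reduced_terms(rest_c, rest_d, K)
        for k in range(dlos[i] + 1, K + 1):
            if _representable(rem - (k - 1) * c[i] - offset, terms):
                kernels.append(k)
                rem -= (k - 1) * c[i]
                break
        else:  # pragma: no cover - guarded by feasibility of the pattern
            raise RuntimeError("kernel back-solve failed on a feasible pattern")
    return kernels


def _search(constraints: SolverConstraints) -> tuple[int, tuple[int, ...]] | None:
    """Core search: best (max_kernel, strides) for an exact target, or None."""
    T = constraints.target_r - 1
    L = constraints.n_layers
    kmin, kmax = constraints.kernel_range
    smin, smax = constraints.stride_range

    best_K: int | None = None
    best_strides: tuple[int, ...] | None = None

    if constraints.strides is not None:
        strides = tuple(constraints.strides)
        bounds = _digit_bounds(strides, kmin, kmax, constraints.require_full_coverage)
        if bounds is None:
            return None
        dlos, _ = bounds
        c = _cumulative_weights(strides)
        K = _min_max_kernel(T, c, dlos, kmin, kmax)
        return (K, strides) if K is not None else None

    def dfs(prefix: tuple[int, ...]) -> None:
        nonlocal best_K, best_strides
        if len(prefix) == L - 1:
            strides = prefix + (smin,)  # last stride never affects r
            bounds = _digit_bounds(strides, kmin, kmax, constraints.require_full_coverage)
            if bounds is None:
                return
            dlos, _ = bounds
            c = _cumulative_weights(strides)
            csum = sum(c)
            base = sum(d * w for d, w in zip(dlos, c))
            if not base <= T <= (kmax - 1) * csum:
                return
            # lower bound on achievable max kernel for this pattern
            lb = max(kmin, max(dlos) + 1, -(-T // csum) + 1)
            if best_K is not None and lb >= best_K:
                return
            K = _min_max_kernel(T, c, dlos, kmin, kmax)
            if K is not None and (best_K is None or K < best_K):
                best_K, best_strides = K, strides
            return
        # bound: even with all remaining strides maximal, can the target
        # still be reached?  (cheap monotone pruning)
        c_prefix = _cumulative_weights(prefix)
        jump = c_prefix[-1] * prefix[-1] if prefix else 1
        max_tail = jump * sum(smax ** i for i in range(L - len(prefix)))
        if (kmax - 1) * (sum(c_prefix) + max_tail) < T:
            return
        for s in range(smin, smax + 1):
            dfs(prefix + (s,))

    dfs(())
    if best_K is None or best_strides is None:
        return None
    return best_K, best_strides


def solve_configuration(constraints: SolverConstraints, f_last: int = 8) -> CNNSpec:
    """Find the deterministic (strides, kernels) solution for a target r.

    Minimizes the maximum kernel size over all stride patterns in range,
    breaking ties by lexicographically smallest strides, then kernels.
    Raises a ``ValueError`` listing the nearest achievable receptive
    field when the target is infeasible.
    """
    constraints.validate()
    found = _search(constraints)
    if found is None:
        nearest = _nearest_achievable(constraints)
        raise ValueError(
            f"no {constraints.n_layers}-layer configuration with receptive field "
            f"{constraints.target_r} in kernel range {constraints.kernel_range} "
            f"and stride range {constraints.stride_range}; nearest achievable "
            f"receptive field is {nearest}"
        )
    best_K, best_strides = found
    kmin, kmax = constraints.kernel_range
    c = _cumulative_weights(best_strides)
    dlos, _ = _digit_bounds(best_strides, kmin, kmax, constraints.require_full_coverage)
    kernels = _lexsmallest_kernels(constraints.target_r - 1, c, dlos, kmin, best_K)
    fmaps = feature_map_schedule(f_last, constraints.n_layers)
    layers = [
        LayerSpec(kernel_size=k, stride=s, feature_maps=f)
        for k, s, f in zip(kernels, best_strides, fmaps)
    ]
    spec = CNNSpec(layers=layers)
    assert spec.receptive_field == constraints.target_r
    return spec


def _nearest_achievable(constraints: SolverConstraints) -> int | None:
    """Closest feasible receptive field to an infeasible target (for the
    infeasibility error message)."""
    base = constraints.target_r
    for delta in range(1, max(2 * base, 64)):
        for cand in (base - delta, base + delta):
            if cand < 1:
                continue
            trial = SolverConstraints(
                target_r=cand,
                n_layers=constraints.n_layers,
                kernel_range=constraints.kernel_range,
                stride_range=constraints.stride_range,
                require_full_coverage=constraints.require_full_coverage,
                strides=constraints.strides,
            )
            if _search(trial) is not None:
                return cand
    return None


def default_spec(scale: str, f_last: int = 8) -> CNNSpec:
    """Shipped short-term (r=300) or long-term (r=5000) network design."""
    if scale == "short":
        cons = SolverConstraints(target_r=R_SHORT, strides=SHORT_STRIDES)
    elif scale == "long":
        cons = SolverConstraints(target_r=R_LONG, strides=LONG_STRIDES)
    else:
        raise ValueError("scale must be 'short' or 'long'")
    return solve_configuration(cons, f_last=f_last)


def build_model(spec: CNNSpec, seed: int = 0, dtype=np.float32):
    """Instantiate a trainable network matching ``spec`` (seeded init)."""
    from .nn import Model

    return Model(spec, seed=seed, dtype=dtype)
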