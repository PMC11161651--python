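"""Synthetic single-lead ECG generator with controllable class signal.

Atrial fibrillation (AF) differs from sinus rhythm in two largely
independent ways: *morphology* (the organized P wave before each QRS
complex is replaced by a continuous fibrillatory baseline oscillation,
the F waves) and *rhythm* (the RR-interval series becomes irregular).
The generator encodes exactly these two axes and lets them be switched
independently, so a classifier's reliance on one or the other can be
probed with ground truth in hand:

* default mode — non-AF records have P waves and regular RR intervals;
  AF records have F waves instead of P waves and irregular RR intervals;
* ``morphology_only`` — the RR distribution is equalized across classes,
  leaving P-vs-F morphology as the only class signal;
* ``rhythm_only`` — both classes share the sinus beat morphology
  (P waves, no F waves), leaving RR irregularity as the only class signal.

Beats are parametric sums of Gaussian bumps with distinct P/Q/R/S/T
landmarks; F waves are an amplitude-modulated 4-9 Hz sinusoid gated off
around each QRS complex; RR intervals are log-normal with a configured
coefficient of variation (CV).  Every record is a pure function of
(config, label, seed).  All shape parameters are artifact choices --
real ECG morphology is far richer -- but each landmark has a known
position, which is what the attribution-localization tests need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .records import AF, NON_AF, ECGRecord

__all__ = [
    "GeneratorConfig",
    "generate_record",
    "generate_dataset",
    "train_test_split_records",
]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic ECG generator.

    Amplitudes are in arbitrary units relative to the R peak (1.0);
    durations in seconds; the min-max scaling of the preprocessing
    pipeline removes the absolute scale anyway.
    """

    fs: float = 500.0
    duration: float = 10.0
    #: heart-rate interval (bpm) from which each record's mean rate is drawn
    heart_rate_range: tuple[float, float] = (50.0, 65.0)
    #: target CV of the RR series for sinus rhythm (tight) and AF (irregular)
    rr_cv_non_af: float = 0.05
    rr_cv_af: float = 0.45
    #: physiological bounds on RR as multiples of the record's mean RR
    #: (ventricular refractory period below, no multi-second pauses above);
    #: binds only on the heavy tails of the irregular draw
    rr_clip: tuple[float, float] = (0.62, 1.45)
    #: P wave: amplitude, Gaussian width and center offset before the R peak
    p_amplitude: float = 0.10
    p_sigma_s: float = 0.02
    pr_offset_s: float = 0.16
    #: fibrillatory oscillation: amplitude and frequency band
    f_wave_amplitude: float = 0.10
    f_wave_freq_range: tuple[float, float] = (4.0, 9.0)
    t_amplitude: float = 0.28
    noise_sd: float = 0.10
    #: per-beat probability of a premature beat (with compensatory pause)
    #: in sinus-rhythm records; emulates the ectopy common in non-AF
    #: clinical ECGs and keeps "one short interval exists" from being a
    #: trivial single-window AF giveaway
    ectopic_rate: float = 0.05
    #: equalize the rhythm axis (both classes regular) -> morphology-only signal
    morphology_only: bool = False
    #: equalize the morphology axis (both classes sinus beats) -> rhythm-only signal
    rhythm_only: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("fs and duration must be positive")
        for name in ("p_amplitude", "f_wave_amplitude", "t_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.morphology_only and self.rhythm_only:
            raise ValueError("morphology_only and rhythm_only are mutually exclusive")
        if not self.morphology_only and not self.rr_cv_af > self.rr_cv_non_af:
            raise ValueError("rr_cv_af must exceed rr_cv_non_af")
        if self.heart_rate_range[0] <= 0 or self.heart_rate_range[1] < self.heart_rate_range[0]:
            raise ValueError("invalid heart_rate_range")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _draw_rr_series(
    rng: np.random.Generator,
    mean_rr: float,
    cv: float,
    total: float,
    clip: tuple[float, float] = (0.62, 1.45),
) -> np.ndarray:
    """Log-normal RR intervals with mean ``mean_rr`` and coefficient of
    variation ``cv``, truncated to physiological bounds, enough to cover
    ``total`` seconds."""
    n_max = int(np.ceil(total / mean_rr * 3)) + 8
    if cv <= 0:
        return np.full(n_max, mean_rr)
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(mean_rr) - 0.5 * sigma**2
    rr = rng.lognormal(mean=mu, sigma=sigma, size=n_max)
    return np.clip(rr, clip[0] * mean_rr, clip[1] * mean_rr)


def generate_record(config: GeneratorConfig, label: str, seed: int) -> ECGRecord:
    """Generate one labeled 10-s record, reproducible from ``seed``."""
    config.validate()
    if label not in (AF, NON_AF):
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(seed)
    fs, n = config.fs, config.n_samples
    t = np.arange(n) / fs

    # rhythm axis: AF irregular unless morphology_only equalizes it
    sinus_rhythm = label == NON_AF or config.morphology_only
    cv = config.rr_cv_non_af if sinus_rhythm else config.rr_cv_af
    heart_rate = rng.uniform(*config.heart_rate_range)
    mean_rr = 60.0 / heart_rate
    rr = _draw_rr_series(rng, mean_rr, cv, config.duration, clip=config.rr_clip)
    if sinus_rhythm and config.ectopic_rate > 0:
        # premature beats with compensatory pause: RR_i shortens, RR_{i+1}
        # lengthens so the pair still spans two cycles
        ect = np.flatnonzero(rng.random(rr.size - 1) < config.ectopic_rate)
        for i in ect:
            total = rr[i] + rr[i + 1]
            rr[i] = 0.65 * total / 2
            rr[i + 1] = total - rr[i]

    # morphology axis: sinus beats for non-AF, and for AF in rhythm_only mode
    sinus_morphology = label == NON_AF or config.rhythm_only

    # first R peak must leave room for its P wave
    t_first = config.pr_offset_s + 3 * config.p_sigma_s + rng.uniform(0.0, mean_rr)
    r_times = t_first + np.concatenate([[0.0], np.cumsum(rr)])
    r_times = r_times[r_times < config.duration - 0.02]
    if r_times.size < 2:  # pathological config (very slow rate / short record)
        r_times = np.array([t_first, config.duration - 0.05])

    # per-record morphology jitter, drawn identically for both classes
    amp_jit = rng.normal(1.0, 0.05, size=5).clip(0.5)
    scale = rng.uniform(0.9, 1.1)

    signal = np.zeros(n)
    for tr in r_times:
        signal += scale * (
            -0.10 * amp_jit[0] * _gauss(t, tr - 0.028, 0.008)  # Q
            + 1.00 * amp_jit[1] * _gauss(t, tr, 0.012)  # R
            - 0.18 * amp_jit[2] * _gauss(t, tr + 0.030, 0.009)  # S
            + config.t_amplitude * amp_jit[3] * _gauss(t, tr + 0.30, 0.055)  # T
        )
        if sinus_morphology:
            signal += scale * config.p_amplitude * amp_jit[4] * _gauss(
                t, tr - config.pr_offset_s, config.p_sigma_s
            )

    if label == AF and not config.rhythm_only and config.f_wave_amplitude > 0:
        f_freq = rng.uniform(*config.f_wave_freq_range)
        phase = rng.uniform(0, 2 * np.pi, size=2)
        mod = 0.6 + 0.4 * np.sin(2 * np.pi * rng.uniform(0.1, 0.5) * t + phase[0])
        f_wave = config.f_wave_amplitude * mod * np.sin(2 * np.pi * f_freq * t + phase[1])
        # gate the fibrillatory baseline off around each QRS complex
        gate = np.ones(n)
        for tr in r_times:
            gate -= _gauss(t, tr, 0.05)
        signal += scale * f_wave * gate.clip(0.0, 1.0)

    if config.noise_sd > 0:
        signal += rng.normal(0.0, config.noise_sd, size=n)

    r_peaks = np.round(r_times * fs).astype(np.int64)
    r_peaks = r_peaks[(r_peaks >= 0) & (r_peaks < n)]
    if label == NON_AF:
        p_waves = r_peaks - int(round(config.pr_offset_s * fs))
    else:
        p_waves = np.empty(0, dtype=np.int64)
    return ECGRecord(
        samples=signal,
        fs=fs,
        label=label,
        r_peaks=r_peaks,
        p_waves=p_waves,
        rr_intervals=np.diff(r_peaks),
        record_id=f"syn-{label}-{seed}",
        seed=seed,
    )


def generate_dataset(
    config: GeneratorConfig, n_per_class: int, seed: int
) -> list[ECGRecord]:
    """Class-balanced dataset; per-record seeds derived from the master seed."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    record_seeds = rng.integers(0, 2**31 - 1, size=2 * n_per_class)
    records = []
    for i in range(n_per_class):
        records.append(generate_record(config, NON_AF, int(record_seeds[2 * i])))
        records.append(generate_record(config, AF, int(record_seeds[2 * i + 1])))
    return records


def train_test_split_records(
    records: list[ECGRecord],
    test_fraction: float = 0.1,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[list[list[ECGRecord]], list[ECGRecord]]:
    """Held-out test split plus label-stratified cross-validation folds.

    Mirrors the usual protocol for this task: a test fraction is set
    aside first, the remainder is partitioned into ``n_folds``
    stratified folds.  Returns ``(folds, test_records)``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    labels = [r.label for r in records]
    try:
        train_recs, test_recs = train_test_split(
            records,
            test_size=test_fraction,
            stratify=labels,
            random_state=seed % (2**32),
            shuffle=True,
        )
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32))
        train_labels = [r.label for r in train_recs]
        folds = [
            [train_recs[i] for i in val_idx]
            for _, val_idx in skf.split(train_recs, train_labels)
        ]
    except ValueError as exc:
        raise ValueError(f"too few records for stratified splitting: {exc}") from exc
    return folds, list(test_recs)
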