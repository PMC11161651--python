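"""Template beats and pseudo-quantitative relevance summaries.

For each record, fixed-length windows centered on the R peaks cut the
signal (and an aligned relevance map) into beats; the per-record
template beat is the sample-wise mean of those windows.  Relevance is
summarized per template sample by its mean across the record's beats
and by the intra-ECG variation coefficient (CV), the ratio of the
standard deviation to the mean -- low CV in a high-relevance region
means the model attends to the same beat feature consistently.
Record-level summaries are then averaged per class.

Alignment uses plain R-peak-centered windows with sample-wise
averaging; no time warping is applied before averaging, so morphology
jitter between beats smears the template slightly (a documented
simplification).  For display, the CV band is conventionally drawn at
one tenth of its stored size; stored values are never scaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import ECGRecord
from .xai import RelevanceMap

__all__ = [
    "TemplateBeatSummary",
    "segment_beats",
    "template_beat",
    "relevance_beat_stats",
    "class_aggregate",
    "summarize_record",
]

#: display-only factor for the CV band (never applied to stored values)
DISPLAY_SCALE = 0.1

#: default beat window: 0.6 s at 500 Hz, matching the short-term receptive field
DEFAULT_WINDOW = 300


@dataclass
class TemplateBeatSummary:
    template: np.ndarray
    mean_relevance: np.ndarray
    intra_ecg_cv: np.ndarray
    label: str
    n_records: int
    display_scale: float = DISPLAY_SCALE

    def __post_init__(self) -> None:
        if not len(self.template) == len(self.mean_relevance) == len(self.intra_ecg_cv):
            raise ValueError("template, mean_relevance and intra_ecg_cv lengths differ")
        if np.any(self.intra_ecg_cv < 0):
            raise ValueError("intra-ECG CV must be non-negative")


def segment_beats(
    record: ECGRecord,
    relevance: RelevanceMap | np.ndarray | None = None,
    window: int = DEFAULT_WINDOW,
) -> tuple[np.ndarray, np.ndarray | None]:
    """R-peak-centered fixed windows; out-of-bounds beats are dropped.

    Returns (beats, relevance_segments); each row is one beat of length
    ``window`` (half before, half after the R peak).
    """
    if record.r_peaks.size == 0:
        raise ValueError("record has no R-peak annotations")
    half = window // 2
    n = record.n_samples
    starts = [r - half for r in record.r_peaks if r - half >= 0 and r - half + window <= n]
    if not starts:
        raise ValueError("no beat window fits inside the signal")
    beats = np.stack([record.samples[s : s + window] for s in starts])
    rel_seg = None
    if relevance is not None:
        values = relevance.values if isinstance(relevance, RelevanceMap) else np.asarray(relevance)
        if values.shape[0] != n:
            raise ValueError("relevance length does not match the record")
        rel_seg = np.stack([values[s : s + window] for s in starts])
    return beats, rel_seg


def template_beat(beats: np.ndarray) -> np.ndarray:
    """Sample-wise mean across a record's beat segments."""
    beats = np.asarray(beats, dtype=np.float64)
    if beats.ndim != 2 or beats.shape[0] < 1:
        raise ValueError("need at least one beat segment")
    return beats.mean(axis=0)


def relevance_beat_stats(
    rel_segments: np.ndarray, mean_tolerance: float = 1e-12, force: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-template-sample mean and intra-ECG variation coefficient.

    CV = population std / mean across the record's beats; where the mean
    is at or below ``mean_tolerance`` the CV is set to 0 (a near-zero
    mean makes the ratio meaningless).  Requires >= 2 beats unless
    ``force`` is set.
    """
    seg = np.asarray(rel_segments, dtype=np.float64)
    if seg.ndim != 2:
        raise ValueError("expected a (beats, window) array")
    if seg.shape[0] < 2 and not force:
        raise ValueError("variation coefficient undefined for a single beat")
    mean = seg.mean(axis=0)
    std = seg.std(axis=0)  # population std
    cv = np.where(np.abs(mean) > mean_tolerance, std / np.where(mean == 0, 1, np.abs(mean)), 0.0)
    return mean, cv


def summarize_record(
    record: ECGRecord,
    relevance: RelevanceMap | np.ndarray,
    window: int = DEFAULT_WINDOW,
) -> TemplateBeatSummary:
    """Single-record summary (template, mean relevance, CV)."""
    beats, rel = segment_beats(record, relevance, window)
    mean, cv = relevance_beat_stats(rel, force=(beats.shape[0] == 1))
    return TemplateBeatSummary(
        template=template_beat(beats),
        mean_relevance=mean,
        intra_ecg_cv=cv,
        label=record.label,
        n_records=1,
    )


def plot_summary(summary: TemplateBeatSummary, ax=None):
    """Template beat with mean relevance overlay and the CV band drawn at
    one tenth of its stored size (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.arange(len(summary.template))
    ax.plot(x, summary.template, color="black", lw=1.0, label="template beat")
    ax.plot(x, summary.mean_relevance, color="crimson", lw=1.0, label="mean relevance")
    band = summary.display_scale * summary.intra_ecg_cv
    ax.fill_between(
        x,
        summary.mean_relevance - band,
        summary.mean_relevance + band,
        color="steelblue",
        alpha=0.3,
        label=f"intra-ECG CV (x{summary.display_scale:g})",
    )
    ax.set_xlabel("sample (R-peak centered)")
    ax.set_title(f"{summary.label} (n={summary.n_records})")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def class_aggregate(
    summaries: list[TemplateBeatSummary], label: str
) -> TemplateBeatSummary:
    """Average the per-record summaries of one class, sample-wise."""
    selected = [s for s in summaries if s.label == label]
    if not selected:
        raise ValueError(f"no summaries with label {label!r}")
    return TemplateBeatSummary(
        template=np.mean([s.template for s in selected], axis=0),
        mean_relevance=np.mean([s.mean_relevance for s in selected], axis=0),
        intra_ecg_cv=np.mean([s.intra_ecg_cv for s in selected], axis=0),
        label=label,
        n_records=len(selected),
    )
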