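"""ECG record container and dataset I/O.

An :class:`ECGRecord` holds one single-lead signal together with its label
and (for synthetic data) ground-truth annotations: R-peak sample indices,
P-wave center indices and the RR-interval series.  Real-world records read
from WFDB files carry no annotations.

Datasets are serialized as one ``.npz`` array container holding all signals
plus a JSON sidecar with labels, annotations and seeds, so a saved dataset
round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: Class names in index order used throughout the package.  AF is the
#: positive class for all binary metrics.
LABELS = ("non-AF", "AF")

NON_AF = "non-AF"
AF = "AF"


def label_index(label: str) -> int:
    """Map a class name to its softmax output index (non-AF=0, AF=1)."""
    try:
        return LABELS.index(label)
    except ValueError:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}") from None


@dataclass
class ECGRecord:
    """One single-lead ECG segment with optional ground-truth annotations.

    Parameters
    ----------
    samples:
        Signal values, arbitrary amplitude units, shape ``(n,)``.
    fs:
        Sampling frequency in Hz.
    label:
        ``"AF"`` or ``"non-AF"``.
    r_peaks:
        Sample indices of R peaks, strictly increasing.
    p_waves:
        Sample indices of P-wave centers.  Empty for AF records (the
        fibrillatory baseline replaces organized atrial activity).
    rr_intervals:
        Differences of consecutive R peaks, in samples.
    """

    samples: np.ndarray
    fs: float = 500.0
    label: str = NON_AF
    r_peaks: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    p_waves: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    rr_intervals: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    record_id: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        self.p_waves = np.asarray(self.p_waves, dtype=np.int64)
        self.rr_intervals = np.asarray(self.rr_intervals, dtype=np.int64)
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def label_idx(self) -> int:
        return label_index(self.label)

    def validate(self) -> None:
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        n = self.n_samples
        for name, idx in (("r_peaks", self.r_peaks), ("p_waves", self.p_waves)):
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"{name} contains indices outside [0, {n})")
        if self.r_peaks.size > 1 and not np.all(np.diff(self.r_peaks) > 0):
            raise ValueError("r_peaks must be strictly increasing")

    def with_samples(self, samples: np.ndarray) -> "ECGRecord":
        """Copy of this record with a new signal, annotations carried through."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


def save_dataset(records: list[ECGRecord], path: str | Path) -> None:
    """Write a dataset as ``<path>.npz`` (signals) + ``<path>.json`` (metadata)."""
    path = Path(path)
    arrays = {f"sig{i}": r.samples for i, r in enumerate(records)}
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    meta = [
        {
            "record_id": r.record_id,
            "fs": r.fs,
            "label": r.label,
            "seed": r.seed,
            "r_peaks": r.r_peaks.tolist(),
            "p_waves": r.p_waves.tolist(),
            "rr_intervals": r.rr_intervals.tolist(),
        }
        for r in records
    ]
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_dataset(path: str | Path) -> list[ECGRecord]:
    """Inverse of :func:`save_dataset`."""
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as data:
        signals = [data[f"sig{i}"] for i in range(len(data.files))]
    meta = json.loads(path.with_suffix(".json").read_text())
    return [
        ECGRecord(
            samples=sig,
            fs=m["fs"],
            label=m["label"],
            r_peaks=np.asarray(m["r_peaks"], dtype=np.int64),
            p_waves=np.asarray(m["p_waves"], dtype=np.int64),
            rr_intervals=np.asarray(m["rr_intervals"], dtype=np.int64),
            record_id=m["record_id"],
            seed=m["seed"],
        )
        for sig, m in zip(signals, meta)
    ]


def read_wfdb(record_path: str, channel: int = 0, label: str = NON_AF) -> ECGRecord:
    """Read one channel of a WFDB record into an :class:`ECGRecord`.

    Requires the optional ``wfdb`` package; annotations are left empty
    (real records carry no ground truth usable by the synthetic oracles).
    """
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install wfdb)"
        ) from exc
    rec = wfdb.rdrecord(record_path)  # pragma: no cover
    return ECGRecord(  # pragma: no cover
        samples=np.asarray(rec.p_signal[:, channel], dtype=np.float64),
        fs=float(rec.fs),
        label=label,
        record_id=str(rec.record_name),
    )
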