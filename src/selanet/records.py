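"""Core data containers: annotated two-channel recordings and 30-s segments.

A :class:`SignalRecord` holds one subject's synchronized single-lead ECG and
pulse-oximetry (SaO2) traces at a common sampling rate, together with interval
annotations of respiratory events.  All intervals are half-open ``[start, end)``
in seconds; sample ``i`` covers time ``[i/fs, (i+1)/fs)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

APNEA_FAMILY = ("obstructive_apnea", "central_apnea", "mixed_apnea", "hypopnea")
EVENT_LABELS = APNEA_FAMILY + ("rera",)


@dataclass(frozen=True)
class EventInterval:
    """One annotated respiratory event."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self):
        if self.label not in EVENT_LABELS:
            raise ValueError(f"unknown event label {self.label!r}")
        if not 0 <= self.start_s < self.end_s:
            raise ValueError(f"bad interval [{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlap_s(self, start: float, end: float) -> float:
        return max(0.0, min(self.end_s, end) - max(self.start_s, start))


@dataclass
class SignalRecord:
    """One subject's two-channel recording with annotations.

    ``truth_beats_s`` carries the generator's ground-truth R-peak times and is
    empty for real recordings.
    """

    subject_id: str
    fs: float
    ecg: np.ndarray
    sao2: np.ndarray
    events: list[EventInterval] = field(default_factory=list)
    truth_beats_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.ecg = np.asarray(self.ecg, dtype=np.float64)
        self.sao2 = np.asarray(self.sao2, dtype=np.float64)
        self.truth_beats_s = np.asarray(self.truth_beats_s, dtype=np.float64)
        if len(self.ecg) != len(self.sao2):
            raise ValueError("ecg and sao2 must have equal length")
        if np.any(np.diff(self.truth_beats_s) <= 0):
            raise ValueError("truth_beats_s must be strictly increasing")
        for ev in self.events:
            if ev.end_s > self.duration_s + 1e-9:
                raise ValueError("event extends past end of record")

    @property
    def duration_s(self) -> float:
        return len(self.ecg) / self.fs

    # -- container I/O (npz signals + JSON sidecar for events/beats) -------
    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        npz = directory / f"{self.subject_id}.npz"
        np.savez_compressed(npz, ecg=self.ecg, sao2=self.sao2, fs=self.fs)
        sidecar = {
            "subject_id": self.subject_id,
            "fs": self.fs,
            "events": [{"start_s": e.start_s, "end_s": e.end_s, "label": e.label}
                       for e in self.events],
            "truth_beats_s": self.truth_beats_s.tolist(),
        }
        (directory / f"{self.subject_id}.json").write_text(
            json.dumps(sidecar, indent=1))
        return npz

    @classmethod
    def load(cls, npz_path: str | Path) -> "SignalRecord":
        npz_path = Path(npz_path)
        with np.load(npz_path) as z:
            ecg, sao2, fs = z["ecg"], z["sao2"], float(z["fs"])
        side = json.loads(npz_path.with_suffix(".json").read_text())
        return cls(
            subject_id=side["subject_id"], fs=fs, ecg=ecg, sao2=sao2,
            events=[EventInterval(**e) for e in side["events"]],
            truth_beats_s=np.asarray(side["truth_beats_s"]),
        )


@dataclass
class Segment:
    """A 30-s, two-channel, [0,1]-normalised window.

    ``x`` has shape (2, n) with channel 0 the ECG-derived respiration and
    channel 1 SaO2.  ``y`` is ``"apnea"`` or ``"normal"``; windows overlapping
    a RERA annotation carry ``ambiguous_tag=True``, have ``y=None`` and are
    kept out of the two-class stream (test-time rejection profiling only).
    """

    subject_id: str
    start_s: float
    x: np.ndarray
    y: str | None
    ambiguous_tag: bool = False

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float32)
        if self.x.ndim != 2 or self.x.shape[0] != 2:
            raise ValueError(f"segment x must be (2, n); got {self.x.shape}")
        if self.x.min() < -1e-6 or self.x.max() > 1 + 1e-6:
            raise ValueError("segment values must lie in [0, 1]")


@dataclass
class SegmentSet:
    """Segments grouped by split; subjects never straddle splits."""

    segments: list[Segment]
    split: str

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.segments:
            key = "ambiguous" if s.ambiguous_tag else (s.y or "unlabeled")
            counts[key] = counts.get(key, 0) + 1
        return counts

    @property
    def subject_ids(self) -> set[str]:
        return {s.subject_id for s in self.segments}

    def stacked_x(self) -> np.ndarray:
        return np.stack([s.x for s in self.segments]) if self.segments else \
            np.empty((0, 2, 0), dtype=np.float32)

    def labels(self) -> np.ndarray:
        return np.array([s.y for s in self.segments], dtype=object)
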