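"""Record readers: the native array container, EDF, and annotation mapping.

Real polysomnography exports vary in channel naming; ``channel_map`` and
``label_map`` translate a file's names onto the package's conventions
(channels "ecg"/"sao2"; event labels obstructive_apnea, central_apnea,
mixed_apnea, hypopnea, rera).  Signals are resampled to the working rate
(200 Hz) when needed.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

from .records import EVENT_LABELS, EventInterval, SignalRecord

TARGET_FS = 200.0

DEFAULT_LABEL_MAP = {
    "obstructive apnea": "obstructive_apnea",
    "central apnea": "central_apnea",
    "mixed apnea": "mixed_apnea",
    "hypopnea": "hypopnea",
    "rera": "rera",
}


def resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling between rational rates."""
    if fs_in == fs_out:
        return np.asarray(x, dtype=np.float64)
    from fractions import Fraction
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return resample_poly(np.asarray(x, dtype=np.float64),
                         frac.numerator, frac.denominator)


def map_labels(raw_events: list[tuple[float, float, str]],
               label_map: dict[str, str] | None = None) -> list[EventInterval]:
    """Map (start, end, name) annotation triples onto event intervals;
    unknown names are dropped with a warning."""
    label_map = {**DEFAULT_LABEL_MAP, **(label_map or {})}
    events = []
    for start, end, name in raw_events:
        key = name.strip().lower()
        label = label_map.get(key, key if key in EVENT_LABELS else None)
        if label is None:
            warnings.warn(f"unknown annotation label {name!r}; dropped")
            continue
        events.append(EventInterval(start, end, label))
    return events


def read_edf(path: str | Path, ecg_channel: str = "ECG",
             sao2_channel: str = "SaO2",
             label_map: dict[str, str] | None = None) -> SignalRecord:
    """Read an EDF recording (requires the optional ``mne`` dependency)."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover - depends on extras
        raise ImportError("EDF reading requires the 'mne' package "
                          "(pip install selanet[edf])") from e
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    missing = [ch for ch in (ecg_channel, sao2_channel) if ch not in raw.ch_names]
    if missing:
        raise ValueError(f"channels {missing} not in file; available: {raw.ch_names}")
    fs = float(raw.info["sfreq"])
    ecg = resample_to(raw.get_data(picks=[ecg_channel])[0], fs, TARGET_FS)
    sao2 = resample_to(raw.get_data(picks=[sao2_channel])[0], fs, TARGET_FS)
    n = min(len(ecg), len(sao2))
    try:
        raw_events = [(float(on), float(on) + float(du), desc)
                      for on, du, desc in zip(raw.annotations.onset,
                                              raw.annotations.duration,
                                              raw.annotations.description)]
    except Exception:
        warnings.warn("unreadable annotations; continuing with empty events")
        raw_events = []
    return SignalRecord(subject_id=Path(path).stem, fs=TARGET_FS,
                        ecg=ecg[:n], sao2=sao2[:n],
                        events=map_labels(raw_events, label_map))


def read_wfdb(path: str | Path, **kwargs) -> SignalRecord:
    """WFDB records need the ``wfdb`` package, which this build does not
    bundle; convert to EDF or the native container instead."""
    raise ImportError("WFDB reading requires the 'wfdb' package, which is "
                      "not installed; convert the record to EDF or the "
                      "native npz+JSON container")


def read_record(path: str | Path, fmt: str = "container", **kwargs) -> SignalRecord:
    """Dispatch on format: 'container' (native npz+JSON), 'edf' or 'wfdb'."""
    fmt = fmt.lower()
    if fmt == "container":
        return SignalRecord.load(path)
    if fmt == "edf":
        return read_edf(path, **kwargs)
    if fmt == "wfdb":
        return read_wfdb(path, **kwargs)
    raise ValueError(f"unknown record format {fmt!r}")
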