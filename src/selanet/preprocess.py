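"""Raw ECG + SaO2 -> normalised, labelled 30-s two-channel segments.

Chain: R-peak detection (5-20 Hz band-pass, squaring, first-order Gaussian
differentiator, refractory peak picking) -> RR tachogram -> ECG-derived
respiration by cubic-spline interpolation onto the signal grid -> SaO2 outlier
repair -> per-recording 0-1 normalisation -> 30-s windows with 5-s overlap ->
two-class labelling with RERA windows diverted to an ambiguous stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .records import APNEA_FAMILY, EventInterval, Segment, SegmentSet, SignalRecord

WINDOW_S = 30.0
OVERLAP_S = 5.0


@dataclass
class BeatSeries:
    """Detected R-peak times and the RR intervals between them."""

    peak_times_s: np.ndarray

    def __post_init__(self):
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=np.float64)
        if np.any(np.diff(self.peak_times_s) <= 0):
            raise ValueError("peak times must be strictly increasing")

    @property
    def rr_s(self) -> np.ndarray:
        return np.diff(self.peak_times_s)

    def __len__(self) -> int:
        return len(self.peak_times_s)


def _gaussian_kernels(fs: float, sigma_s: float = 0.025) -> tuple[np.ndarray, np.ndarray]:
    sigma = sigma_s * fs
    half = int(np.ceil(4 * sigma))
    t = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(t**2) / (2 * sigma**2))
    dg = -t / sigma**2 * g  # first-order Gaussian differentiator
    return g / g.sum(), dg


def detect_r_peaks(ecg: np.ndarray, fs: float,
                   refractory_s: float = 0.25) -> BeatSeries:
    """Detect R peaks.

    Band-pass 5-20 Hz to isolate QRS energy, square (nonlinear transform),
    smooth with a Gaussian and locate energy maxima as falling zero crossings
    of the first-order Gaussian derivative of the squared signal; a 250-ms
    refractory rule keeps the strongest peak of any close pair.
    """
    if fs <= 40:
        raise ValueError("sampling rate must exceed 40 Hz for QRS detection")
    ecg = np.asarray(ecg, dtype=np.float64)
    if len(ecg) < 2 * fs:
        raise ValueError("need at least 2 s of ECG")
    if not np.any(np.isfinite(ecg)) or np.ptp(ecg[np.isfinite(ecg)]) == 0:
        warnings.warn("flat or all-NaN ECG; returning no beats")
        return BeatSeries(np.empty(0))
    ecg = np.nan_to_num(ecg)

    b, a = butter(4, [5.0, 20.0], btype="bandpass", fs=fs)
    filtered = filtfilt(b, a, ecg)
    sq = filtered**2
    g, dg = _gaussian_kernels(fs)
    energy = np.convolve(sq, g, mode="same")
    slope = np.convolve(sq, dg, mode="same")

    crossings = np.flatnonzero((slope[:-1] > 0) & (slope[1:] <= 0))
    if crossings.size == 0:
        return BeatSeries(np.empty(0))
    # locally adaptive gate: a true QRS dominates the energy envelope within
    # any 2-s neighbourhood, noise bumps between beats do not
    from scipy.ndimage import maximum_filter1d
    local_max = maximum_filter1d(energy, size=int(2.0 * fs))
    candidates = crossings[energy[crossings] > 0.3 * local_max[crossings]]
    if candidates.size == 0:
        return BeatSeries(np.empty(0))

    # refractory: strongest-first suppression within refractory_s
    import bisect
    order = candidates[np.argsort(energy[candidates])[::-1]]
    kept: list[int] = []
    min_gap = refractory_s * fs
    for idx in order:
        pos = bisect.bisect_left(kept, idx)
        left_ok = pos == 0 or idx - kept[pos - 1] >= min_gap
        right_ok = pos == len(kept) or kept[pos] - idx >= min_gap
        if left_ok and right_ok:
            kept.insert(pos, idx)
    return BeatSeries(np.asarray(kept, dtype=float) / fs)


def compute_edr(beats: BeatSeries, out_fs: float, duration_s: float) -> np.ndarray:
    """ECG-derived respiration: the RR tachogram (RR value at the later peak)
    cubic-spline interpolated onto a uniform grid; held constant beyond the
    first/last tachogram knot."""
    if len(beats) < 4:
        raise ValueError("need at least 4 beats to interpolate a tachogram")
    knots = beats.peak_times_s[1:]
    values = beats.rr_s
    spline = CubicSpline(knots, values, bc_type="natural")
    n = int(round(duration_s * out_fs))
    grid = np.arange(n) / out_fs
    return spline(np.clip(grid, knots[0], knots[-1]))


def clean_sao2(sao2: np.ndarray, fs: float, valid_range: tuple[float, float] = (50.0, 100.0),
               max_jump_pct: float = 4.0) -> np.ndarray:
    """Repair SaO2 dropouts: samples outside the physiological range or
    arriving via a >4 %/sample jump are linearly interpolated from valid
    neighbours; leading/trailing invalid runs take the nearest valid value."""
    x = np.asarray(sao2, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty SaO2")
    invalid = ~np.isfinite(x) | (x < valid_range[0]) | (x > valid_range[1])
    jumps = np.abs(np.diff(x)) > max_jump_pct
    invalid[1:] |= jumps
    if invalid.all():
        raise ValueError("no valid SaO2 samples to interpolate from")
    if not invalid.any():
        return x.copy()
    idx = np.arange(x.size)
    return np.interp(idx, idx[~invalid], x[~invalid])


def normalize01(x: np.ndarray) -> np.ndarray:
    """Min-max normalise one recording channel to [0,1]; constant -> 0.5."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty channel")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def label_window(start_s: float, end_s: float, events: list[EventInterval],
                 apnea_overlap_s: float = 10.0, rera_overlap_s: float = 1.0,
                 ) -> tuple[str | None, bool, bool]:
    """Label one window: returns (y, ambiguous_tag, keep).

    Windows overlapping a RERA annotation by >= 1 s are ambiguous and leave
    the two-class stream; >= 10 s cumulative apnea-family overlap -> apnea;
    zero event overlap -> normal; sub-threshold overlap windows are dropped
    (label noise, not evidence).
    """
    apnea_ov = 0.0
    rera_ov = 0.0
    for ev in events:
        ov = ev.overlap_s(start_s, end_s)
        if ov <= 0:
            continue
        if ev.label in APNEA_FAMILY:
            apnea_ov += ov
        elif ev.label == "rera":
            rera_ov += ov
    if rera_ov >= rera_overlap_s:
        return None, True, True
    if apnea_ov >= apnea_overlap_s:
        return "apnea", False, True
    if apnea_ov == 0.0 and rera_ov == 0.0:
        return "normal", False, True
    return None, False, False


def segment_record(edr01: np.ndarray, sao201: np.ndarray, events: list[EventInterval],
                   subject_id: str, fs: float = 200.0, window_s: float = WINDOW_S,
                   overlap_s: float = OVERLAP_S) -> list[Segment]:
    """Cut normalised channels into windows (stride = window - overlap) and
    attach labels; sub-threshold windows are dropped."""
    if len(edr01) != len(sao201):
        raise ValueError("channel length mismatch")
    n = len(edr01)
    win = int(round(window_s * fs))
    stride = int(round((window_s - overlap_s) * fs))
    segments: list[Segment] = []
    for start in range(0, n - win + 1, stride):
        start_s = start / fs
        y, ambiguous, keep = label_window(start_s, start_s + window_s, events)
        if not keep:
            continue
        x = np.stack([edr01[start:start + win], sao201[start:start + win]])
        segments.append(Segment(subject_id=subject_id, start_s=start_s, x=x,
                                y=y, ambiguous_tag=ambiguous))
    return segments


def preprocess_record(record: SignalRecord, window_s: float = WINDOW_S,
                      overlap_s: float = OVERLAP_S) -> list[Segment]:
    """Full per-record chain from raw signals to labelled segments."""
    beats = detect_r_peaks(record.ecg, record.fs)
    edr = compute_edr(beats, record.fs, record.duration_s)
    sao2 = clean_sao2(record.sao2, record.fs)
    return segment_record(normalize01(edr), normalize01(sao2), record.events,
                          record.subject_id, fs=record.fs,
                          window_s=window_s, overlap_s=overlap_s)


def _balance(segments: list[Segment], rng: np.random.Generator) -> list[Segment]:
    by_class: dict[str, list[Segment]] = {"apnea": [], "normal": []}
    for s in segments:
        by_class[s.y].append(s)
    n_min = min(len(v) for v in by_class.values())
    balanced: list[Segment] = []
    for label, group in by_class.items():
        if len(group) > n_min:
            pick = rng.choice(len(group), size=n_min, replace=False)
            group = [group[i] for i in sorted(pick)]
        balanced.extend(group)
    balanced.sort(key=lambda s: (s.subject_id, s.start_s))
    return balanced


def split_and_balance(segments: list[Segment],
                      fractions: tuple[float, float, float] = (0.70, 0.05, 0.25),
                      seed: int = 0, balance: tuple[str, ...] = ("train", "test"),
                      ) -> dict[str, SegmentSet]:
    """Subject-level split, then class balancing by undersampling the
    majority class in the train and test streams.

    Ambiguous (RERA-overlap) segments from test subjects form a separate
    ``ambiguous`` stream used only for rejection profiling; ambiguous segments
    from other subjects are discarded.
    """
    subjects = sorted({s.subject_id for s in segments})
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for a 3-way split")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    n_train = int(len(subjects) * fractions[0])
    n_val = max(1, int(len(subjects) * fractions[1]))
    assign = {}
    for i, sid in enumerate(order):
        assign[sid] = "train" if i < n_train else ("val" if i < n_train + n_val else "test")
    pools: dict[str, list[Segment]] = {"train": [], "val": [], "test": [], "ambiguous": []}
    for s in segments:
        split = assign[s.subject_id]
        if s.ambiguous_tag:
            if split == "test":
                pools["ambiguous"].append(s)
            continue
        pools[split].append(s)
    out: dict[str, SegmentSet] = {}
    for split, pool in pools.items():
        if split in balance and pool:
            pool = _balance(pool, rng)
        labels = {s.y for s in pool}
        if split in ("train", "val", "test") and len(labels) < 2:
            warnings.warn(f"split {split!r} contains a single class: {labels}")
        out[split] = SegmentSet(segments=pool, split=split)
    return out
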