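"""Synthetic two-channel PSG-like recordings with ground-truth annotations.

The generator emulates the physiology the detector exploits, not ECG
morphology: a quasi-periodic QRS-like spike train whose beat-to-beat (RR)
interval carries respiratory sinus arrhythmia plus an amplified cyclic
variation inside apnea events, and an SaO2 trace with a delayed desaturation
dip after each event.  RERA-like events get deliberately intermediate
signatures (half the RR modulation, one third of the desaturation depth) so
they are genuinely ambiguous between the apnea and normal classes.

Every stochastic choice flows from ``SynthConfig.seed``; the same config
yields bit-identical records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve

from .records import APNEA_FAMILY, EventInterval, SignalRecord

# apnea-subtype mix follows large clinical PSG corpora: hypopnea is roughly
# half of all events, mixed apnea is rare
_SUBTYPE_LABELS = ("hypopnea", "obstructive_apnea", "central_apnea", "mixed_apnea")
_SUBTYPE_PROBS = (0.50, 0.28, 0.20, 0.02)

_RESP_FREQ_HZ = 0.25          # baseline respiratory rate (15 breaths/min)
_RSA_FRACTION = 0.2           # baseline RSA depth as a fraction of hrv_depth
_QRS_WIDTH_S = 0.02           # Ricker (Gaussian 2nd-derivative) template width
_RECOVERY_TAU_S = 10.0        # SaO2 resaturation time constant
_WANDER_GAIN = 3.0            # slow SaO2 wander amplitude per unit noise_sd


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters; defaults are the package's study conditions."""

    duration_s: float = 10800.0          # 3 h desk-scale night slice
    mean_hr_bpm: float = 70.0
    hrv_depth: float = 0.25              # fractional RR modulation inside apnea
    desat_depth_pct: float = 4.0
    desat_lag_s: float = 10.0            # circulatory + oximeter delay
    apnea_rate_per_hour: float = 35.0    # severe-OSA-range event rate
    rera_rate_per_hour: float = 10.0
    noise_sd_ecg: float = 0.05           # mV, additive white
    noise_sd_sao2: float = 0.15          # percent, additive white
    fs: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if self.apnea_rate_per_hour < 0 or self.rera_rate_per_hour < 0:
            raise ValueError("event rates must be >= 0")
        if not 0 <= self.hrv_depth < 1:
            raise ValueError("hrv_depth must be in [0, 1)")
        if self.duration_s < 30:
            raise ValueError("duration too short to place one 30-s window")


def _place_events(cfg: SynthConfig, rng: np.random.Generator) -> list[EventInterval]:
    """Apnea events by an exponential-gap renewal process (keeps the target
    rate while forbidding overlap by construction); RERA by a thinned Poisson
    process around them."""
    events: list[EventInterval] = []
    T = cfg.duration_s
    if cfg.apnea_rate_per_hour > 0:
        mean_dur = 25.0  # uniform(10, 40)
        mean_gap = max(5.0, 3600.0 / cfg.apnea_rate_per_hour - mean_dur)
        t = rng.exponential(mean_gap)
        while True:
            dur = rng.uniform(10.0, 40.0)
            if t + dur + cfg.desat_lag_s + 5.0 > T:
                break
            label = _SUBTYPE_LABELS[rng.choice(len(_SUBTYPE_LABELS), p=_SUBTYPE_PROBS)]
            events.append(EventInterval(t, t + dur, label))
            t = t + dur + rng.exponential(mean_gap)
    if cfg.rera_rate_per_hour > 0:
        n = rng.poisson(cfg.rera_rate_per_hour * T / 3600.0)
        starts = np.sort(rng.uniform(0, T, size=n))
        for s in starts:
            dur = rng.uniform(5.0, 30.0)
            if s + dur + cfg.desat_lag_s + 5.0 > T:
                continue
            cand = EventInterval(s, s + dur, "rera")
            if all(cand.overlap_s(e.start_s, e.end_s) == 0 for e in events):
                events.append(cand)
    events.sort(key=lambda e: e.start_s)
    return events


def _rr_modulation(t: float, events: list[EventInterval], cfg: SynthConfig) -> float:
    """Fractional RR deviation at time t: baseline RSA everywhere plus one
    cycle of bradycardia-tachycardia swing per apnea event (half for RERA)."""
    dev = _RSA_FRACTION * cfg.hrv_depth * np.sin(2 * np.pi * _RESP_FREQ_HZ * t)
    for ev in events:  # events sorted; list is short relative to beat count
        if ev.start_s <= t < ev.end_s:
            depth = cfg.hrv_depth if ev.label in APNEA_FAMILY else cfg.hrv_depth / 2
            phase = (t - ev.start_s) / ev.duration_s
            dev += depth * np.sin(2 * np.pi * phase)
            break
        if ev.start_s > t:
            break
    return dev


def _beat_times(cfg: SynthConfig, events: list[EventInterval]) -> np.ndarray:
    rr0 = 60.0 / cfg.mean_hr_bpm
    beats = []
    t = 1.0  # keep the first QRS clear of filter edge effects
    apnea_like = [e for e in events]
    while t < cfg.duration_s - 1.0:
        beats.append(t)
        rr = rr0 * (1.0 + _rr_modulation(t, apnea_like, cfg))
        t += max(rr, 0.3)
    return np.asarray(beats)


def _qrs_template(fs: float) -> np.ndarray:
    """Ricker wavelet (second-derivative-of-Gaussian): a symmetric, QRS-like
    deflection peaking exactly at the beat time, with small Q/S-like lobes."""
    a = _QRS_WIDTH_S * fs
    half = int(np.ceil(5 * a))
    t = np.arange(-half, half + 1, dtype=float)
    return (1 - (t / a) ** 2) * np.exp(-t**2 / (2 * a**2))


def _apply_desat(dips: np.ndarray, fs: float, ev: EventInterval,
                 cfg: SynthConfig) -> None:
    """Fold one event's dip into the running max-dip profile in place:
    linear fall from event start + lag reaching full depth at event end +
    lag, then exponential resaturation (support truncated at 8 time
    constants, where the tail is < 0.04 % of the depth)."""
    depth = cfg.desat_depth_pct if ev.label in APNEA_FAMILY else cfg.desat_depth_pct / 3
    n = len(dips)
    i0 = int(round((ev.start_s + cfg.desat_lag_s) * fs))
    i1 = int(round((ev.end_s + cfg.desat_lag_s) * fs))
    i2 = min(n, i1 + int(8 * _RECOVERY_TAU_S * fs))
    fall = np.linspace(0.0, depth, max(i1, 0) - max(i0, 0), endpoint=False)
    if i0 < n and len(fall):
        seg = slice(max(i0, 0), min(i1, n))
        np.maximum(dips[seg], fall[:seg.stop - seg.start], out=dips[seg])
    if i1 < n:
        t = np.arange(i2 - i1) / fs
        np.maximum(dips[i1:i2], depth * np.exp(-t / _RECOVERY_TAU_S),
                   out=dips[i1:i2])


def generate_record(config: SynthConfig, subject_id: str = "S000") -> SignalRecord:
    """Synthesize one annotated two-channel recording."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    events = _place_events(cfg, rng)

    beats = _beat_times(cfg, events)
    beat_idx = np.round(beats * cfg.fs).astype(int)
    beats_quantized = beat_idx / cfg.fs
    impulses = np.zeros(n)
    impulses[beat_idx[beat_idx < n]] = 1.0
    ecg = fftconvolve(impulses, _qrs_template(cfg.fs), mode="same")
    if cfg.noise_sd_ecg > 0:
        ecg = ecg + rng.normal(0, cfg.noise_sd_ecg, size=n)

    baseline = 96.5
    sao2 = np.full(n, baseline)
    if cfg.noise_sd_sao2 > 0:
        # slow physiological wander (correlated noise) + white measurement noise
        tgrid = np.arange(n) / cfg.fs
        for _ in range(2):
            f = rng.uniform(0.003, 0.015)
            phase = rng.uniform(0, 2 * np.pi)
            sao2 = sao2 + _WANDER_GAIN * cfg.noise_sd_sao2 * np.sin(
                2 * np.pi * f * tgrid + phase)
        sao2 = sao2 + rng.normal(0, cfg.noise_sd_sao2, size=n)
    if events:
        dips = np.zeros(n)
        for ev in events:  # deepest dip wins at overlap; tails do not stack
            _apply_desat(dips, cfg.fs, ev, cfg)
        sao2 = sao2 - dips
    sao2 = np.clip(sao2, 70.0, 100.0)

    return SignalRecord(subject_id=subject_id, fs=cfg.fs, ecg=ecg, sao2=sao2,
                        events=events, truth_beats_s=beats_quantized)


def generate_cohort(n_subjects: int, config: SynthConfig,
                    seed: int | None = None) -> list[SignalRecord]:
    """Generate a cohort; per-subject seeds derive from one master seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = config.seed if seed is None else seed
    children = np.random.SeedSequence(master).spawn(n_subjects)
    records = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        cfg_i = replace(config, seed=sub_seed)
        records.append(generate_record(cfg_i, subject_id=f"S{i:03d}"))
    return records
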