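"""Shared fixtures: small synthetic records and segment sets.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from selanet import SynthConfig, generate_cohort, generate_record, preprocess_record


@pytest.fixture(scope="session")
def clean_config() -> SynthConfig:
    """Noise-free half-hour record: exact physiology, no stochastic nuisance."""
    return SynthConfig(duration_s=1800, mean_hr_bpm=60, hrv_depth=0.25,
                       noise_sd_ecg=0.0, noise_sd_sao2=0.0, seed=42)


@pytest.fixture(scope="session")
def clean_record(clean_config):
    return generate_record(clean_config, subject_id="CLEAN")


@pytest.fixture(scope="session")
def noisy_record():
    """Default noise levels, one hour."""
    return generate_record(SynthConfig(duration_s=3600, seed=7), subject_id="NOISY")


@pytest.fixture(scope="session")
def small_cohort_segments():
    """Segments from a 6-subject, 45-min cohort (enough for split logic)."""
    records = generate_cohort(6, SynthConfig(duration_s=2700), seed=123)
    segments = []
    for rec in records:
        segments.extend(preprocess_record(rec))
    return segments


def match_beats(detected_s: np.ndarray, truth_s: np.ndarray,
                tol_s: float = 0.05) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to true beat times.

    Returns (matched, false_positives, false_negatives); independent of the
    detector's internals, used as the oracle for recall/precision checks.
    """
    truth = list(truth_s)
    used = [False] * len(truth)
    matched = fp = 0
    for t in detected_s:
        best, best_err = None, tol_s
        for i, tt in enumerate(truth):
            if used[i]:
                continue
            err = abs(tt - t)
            if err <= best_err:
                best, best_err = i, err
        if best is None:
            fp += 1
        else:
            used[best] = True
            matched += 1
    return matched, fp, len(truth) - matched
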