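"""Preprocessing chain: R-peak detection against generator truth, EDR
interpolation, SaO2 repair, normalisation, windowing and labelling."""

import numpy as np
import pytest

from selanet import (SynthConfig, clean_sao2, compute_edr, detect_r_peaks,
                     generate_record, label_window, normalize01,
                     preprocess_record, segment_record, split_and_balance)
from selanet.preprocess import BeatSeries
from selanet.records import EventInterval

from conftest import match_beats


class TestRPeakDetection:
    def test_noise_free_beats_recovered_exactly(self, clean_record):
        beats = detect_r_peaks(clean_record.ecg, clean_record.fs)
        truth = clean_record.truth_beats_s
        errs = []
        ti = 0
        assert len(beats) == len(truth)
        for det, tru in zip(beats.peak_times_s, truth):
            errs.append(abs(det - tru))
        assert max(errs) <= 0.020  # every beat within +-20 ms, no extras

    def test_noisy_recall_and_precision(self):
        # ~10 dB SNR: QRS amplitude 1 mV vs noise sd 0.3 mV
        cfg = SynthConfig(duration_s=600, noise_sd_ecg=0.3, seed=31)
        rec = generate_record(cfg)
        beats = detect_r_peaks(rec.ecg, rec.fs)
        m, fp, fn = match_beats(beats.peak_times_s, rec.truth_beats_s)
        recall = m / (m + fn)
        precision = m / (m + fp)
        assert recall >= 0.95 and precision >= 0.95

    def test_zero_signal_gives_zero_peaks(self):
        with pytest.warns(UserWarning):
            beats = detect_r_peaks(np.zeros(2000), 200.0)
        assert len(beats) == 0

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            detect_r_peaks(np.random.default_rng(0).normal(size=400), 40.0)


class TestEDR:
    def test_constant_rr_gives_constant_edr(self):
        beats = BeatSeries(np.arange(1.0, 20.0))  # RR = 1.0 s throughout
        edr = compute_edr(beats, out_fs=200, duration_s=20)
        assert edr.shape == (4000,)
        assert np.allclose(edr, 1.0)

    def test_alternating_rr_oscillates_between_knots(self):
        # tachogram 0.9/1.1 alternating; the spline interpolant must hit the
        # knot values and oscillate with period ~2 beats
        times = np.concatenate([[0.0], np.cumsum([0.9, 1.1] * 10)])
        beats = BeatSeries(times)
        edr = compute_edr(beats, out_fs=200, duration_s=times[-1])
        for t, rr in zip(times[1:], np.diff(times)):
            i = int(round(t * 200))
            if i < len(edr):
                assert edr[i] == pytest.approx(rr, abs=1e-6)
        mid = edr[len(edr) // 4: -len(edr) // 4]
        assert mid.min() < 0.95 and mid.max() > 1.05

    @pytest.mark.parametrize("duration,out_fs", [(20, 200), (33.3, 100), (45, 64)])
    def test_output_grid_length_contract(self, duration, out_fs):
        beats = BeatSeries(np.arange(0.5, duration, 0.8))
        edr = compute_edr(beats, out_fs=out_fs, duration_s=duration)
        assert len(edr) == round(duration * out_fs)

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError):
            compute_edr(BeatSeries(np.array([1.0, 2.0, 3.0])), 200, 10)


class TestSaO2Cleaning:
    def test_single_dropout_repaired(self):
        out = clean_sao2(np.array([97.0, 97.0, 0.0, 97.0]), fs=200)
        assert np.allclose(out, 97.0)

    def test_clean_signal_unchanged(self):
        x = 96 + 0.5 * np.sin(np.linspace(0, 3, 500))
        assert np.allclose(clean_sao2(x, fs=200), x)

    def test_corrupted_trace_recovered_everywhere(self):
        cfg = SynthConfig(duration_s=300, noise_sd_ecg=0, noise_sd_sao2=0, seed=8)
        clean = generate_record(cfg).sao2
        rng = np.random.default_rng(4)
        corrupted = clean.copy()
        drop = rng.choice(len(clean), size=len(clean) // 100, replace=False)
        corrupted[drop] = 0.0
        repaired = clean_sao2(corrupted, fs=200)
        assert np.max(np.abs(repaired - clean)) < 0.5

    def test_all_invalid_rejected(self):
        with pytest.raises(ValueError):
            clean_sao2(np.zeros(100), fs=200)


class TestNormalize:
    def test_basic_and_degenerate(self):
        assert np.allclose(normalize01(np.array([2.0, 4.0, 6.0])), [0, 0.5, 1])
        assert np.allclose(normalize01(np.array([7.0, 7.0])), [0.5, 0.5])

    def test_range_contract_on_random_input(self):
        x = np.random.default_rng(1).normal(size=1000)
        out = normalize01(x)
        assert out.min() == 0.0 and out.max() == 1.0


class TestSegmentation:
    def _channels(self, t_seconds, fs=200):
        n = int(t_seconds * fs)
        return np.linspace(0, 1, n), np.linspace(1, 0, n)

    @pytest.mark.parametrize("duration,expected_starts", [
        (90, [0.0, 25.0, 50.0]),   # stride-25 enumeration
        (30, [0.0]),
        (29, []),
    ])
    def test_window_grid(self, duration, expected_starts):
        edr, sao2 = self._channels(duration)
        segs = segment_record(edr, sao2, [], "S", fs=200)
        assert [s.start_s for s in segs] == expected_starts
        for s in segs:
            assert s.x.shape == (2, 6000)

    def test_label_rules(self):
        apnea35 = [EventInterval(10, 45, "obstructive_apnea")]
        assert label_window(10, 40, apnea35) == ("apnea", False, True)
        assert label_window(100, 130, apnea35) == ("normal", False, True)
        # RERA overlap >= 1 s dominates: ambiguous, out of the 2-class stream
        rera = [EventInterval(50, 70, "rera")]
        assert label_window(58, 88, rera) == (None, True, True)
        # sub-threshold apnea overlap (0 < ov < 10 s): dropped
        assert label_window(40, 70, apnea35) == (None, False, False)

    def test_cumulative_overlap_counts_across_events(self):
        events = [EventInterval(0, 6, "hypopnea"),
                  EventInterval(10, 16, "central_apnea")]
        y, amb, keep = label_window(0, 30, events)
        assert y == "apnea" and keep and not amb


class TestSplitAndBalance:
    def test_subject_level_split_and_counts(self, small_cohort_segments):
        sets = split_and_balance(small_cohort_segments, seed=0)
        subjects = {k: v.subject_ids for k, v in sets.items()
                    if k in ("train", "val", "test")}
        assert len(subjects["train"]) == 4   # floor(6 * 0.7)
        assert len(subjects["val"]) == 1
        assert len(subjects["test"]) == 1
        assert not (subjects["train"] & subjects["val"] & subjects["test"])
        for a in ("train", "val", "test"):
            for b in ("train", "val", "test"):
                if a != b:
                    assert not (subjects[a] & subjects[b])

    def test_train_and_test_are_balanced(self, small_cohort_segments):
        sets = split_and_balance(small_cohort_segments, seed=0)
        for split in ("train", "test"):
            counts = sets[split].class_counts
            assert counts.get("apnea", 0) == counts.get("normal", 0)

    def test_split_is_seed_deterministic(self, small_cohort_segments):
        a = split_and_balance(small_cohort_segments, seed=3)
        b = split_and_balance(small_cohort_segments, seed=3)
        assert a["train"].subject_ids == b["train"].subject_ids
        assert [s.start_s for s in a["train"].segments] == \
            [s.start_s for s in b["train"].segments]

    def test_needs_three_subjects(self, small_cohort_segments):
        few = [s for s in small_cohort_segments if s.subject_id in ("S000", "S001")]
        with pytest.raises(ValueError):
            split_and_balance(few)


class TestEndToEnd:
    def test_segment_grid_and_range_invariant(self, noisy_record):
        segs = preprocess_record(noisy_record)
        assert segs
        for s in segs:
            assert s.x.shape == (2, 6000)
            assert s.x.min() >= 0.0 and s.x.max() <= 1.0

    def test_apnea_windows_carry_more_edr_variance(self, clean_record):
        # the generator injects RR modulation inside apnea; after EDR
        # estimation that must survive as higher within-window variance
        segs = preprocess_record(clean_record)
        v_apnea = np.mean([s.x[0].var() for s in segs if s.y == "apnea"])
        v_normal = np.mean([s.x[0].var() for s in segs if s.y == "normal"])
        assert v_apnea > v_normal
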