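"""Delineation tests: beat detection, fiducials vs ground truth, onset
oracle, averaging."""

import numpy as np
import pandas as pd
import pytest

from pwavekit.delineate import (
    DelineationConfig,
    average_measurements,
    delineate_record,
    detect_beats,
    detect_p_offset,
    detect_p_onset,
    detect_p_peak,
    estimate_baseline,
)
from pwavekit.ecg import ECGRecord, STANDARD_LEADS, preprocess
from pwavekit.synth import SynthEcgSpec, default_p_specs, generate_ecg

from conftest import clean_spec

FS = 500.0


def brute_force_onset(x, anchor, peak):
    """Independent point-to-chord scan: plain loop, explicit geometry."""
    x0, y0 = float(anchor), float(x[anchor])
    x1, y1 = float(peak), float(x[peak])
    best_i, best_d = None, -1.0
    chord_len = np.hypot(x1 - x0, y1 - y0)
    for i in range(anchor + 1, peak):
        # distance from point (i, x[i]) to the infinite line through the chord
        d = abs((y1 - y0) * (i - x0) - (x1 - x0) * (x[i] - y0)) / chord_len
        if d > best_d + 1e-15:
            best_d, best_i = d, i
    return best_i, best_d


class TestBeatDetection:
    def test_beat_count_at_60_bpm(self, clean_record_and_truth):
        record, truth = clean_record_and_truth
        peaks = detect_beats(record)
        n_truth = truth[truth.lead == "II"].r_index.nunique() + 1
        for lead in record.lead_names:
            assert abs(len(peaks[lead]) - n_truth) <= 1

    def test_mean_rr_at_80_bpm(self):
        record, _ = generate_ecg(clean_spec(heart_rate_bpm=80.0))
        peaks = detect_beats(record)["II"]
        mean_rr_ms = np.diff(peaks).mean() / FS * 1000.0
        assert abs(mean_rr_ms - 750.0) <= 2.0

    def test_flat_signal_rejected(self):
        rec = ECGRecord(STANDARD_LEADS, FS, np.zeros((12, 5000)))
        with pytest.raises(ValueError, match="flat"):
            detect_beats(rec)


class TestBaseline:
    def test_zero_noise_baseline_is_zero(self, clean_record_and_truth):
        record, truth = clean_record_and_truth
        row = truth[(truth.lead == "II")].iloc[3]
        b = estimate_baseline(record.lead("II"),
                              int(row.t_end_index) + 5, int(row.p_onset_index) - 5)
        assert abs(b) < 0.005

    def test_constant_offset_equivariance(self, clean_record_and_truth):
        record, _ = clean_record_and_truth
        x = record.lead("II")
        b0 = estimate_baseline(x, 100, 300)
        b1 = estimate_baseline(x + 0.2, 100, 300)
        assert b1 - b0 == pytest.approx(0.2, abs=1e-9)

    def test_white_noise_suppressed(self, rng):
        x = rng.normal(0.0, 0.02, 500)
        assert abs(estimate_baseline(x, 0, 500)) < 0.01

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_baseline(np.zeros(10), 5, 5)


class TestPPeak:
    def test_clean_peak_within_one_sample(self, clean_record_and_truth):
        record, truth = clean_record_and_truth
        for lead in ("II", "aVR", "V4"):
            x = record.lead(lead)
            row = truth[truth.lead == lead].iloc[4]
            pk = detect_p_peak(x, 0.0, int(row.t_end_index),
                               int(row.r_index) - 25, FS)
            assert abs(pk - int(row.p_peak_index)) <= 1

    def test_narrow_spike_rejected_in_favor_of_true_p(self, clean_record_and_truth):
        record, truth = clean_record_and_truth
        x = record.lead("II").copy()
        row = truth[truth.lead == "II"].iloc[4]
        spike_at = int(row.t_end_index) + 40
        x[spike_at : spike_at + 5] += 0.5  # 10 ms spike, taller than the P
        pk = detect_p_peak(x, 0.0, int(row.t_end_index), int(row.r_index) - 25, FS)
        assert abs(pk - int(row.p_peak_index)) <= 1

    def test_window_without_p_is_unmeasurable(self):
        x = np.zeros(2000)
        assert detect_p_peak(x, 0.0, 100, 900, FS) is None


class TestOnset:
    def test_matches_brute_force_oracle_on_random_beats(self):
        """The vectorized chord search must equal an exhaustive scan."""
        rng = np.random.default_rng(99)
        checked = 0
        for seed in range(4):
            hr = float(rng.uniform(55, 95))
            d = float(rng.uniform(90, 150))
            spec = clean_spec(heart_rate_bpm=hr, duration_ms=d, n_beats=10, seed=seed)
            spec.noise_sd_mv = 0.004
            record, truth = generate_ecg(spec)
            for lead in ("II", "V2", "aVF", "I", "V5", "V6", "aVL", "III"):
                x = record.lead(lead)
                for _, row in truth[truth.lead == lead].iterrows():
                    anchor = int(row.t_end_index)
                    pk = int(row.p_peak_index)
                    got = detect_p_onset(x, anchor, pk)
                    want, _ = brute_force_onset(x, anchor, pk)
                    assert got == want
                    checked += 1
                    if checked >= 100:
                        return
        assert checked >= 100

    def test_linear_ramp_is_degenerate(self):
        x = np.linspace(0.0, 1.0, 200)
        assert detect_p_onset(x, 10, 150) is None

    def test_clean_onset_within_two_samples(self, clean_record_and_truth):
        record, truth = clean_record_and_truth
        x = record.lead("II")
        for _, row in truth[truth.lead == "II"].head(5).iterrows():
            got = detect_p_onset(x, int(row.t_end_index), int(row.p_peak_index),
                                 baseline=0.0)
            assert abs(got - int(row.p_onset_index)) <= 2

    def test_literal_minimum_variant_differs(self, clean_record_and_truth):
        record, truth = clean_record_and_truth
        x = record.lead("II")
        row = truth[truth.lead == "II"].iloc[2]
        mx = detect_p_onset(x, int(row.t_end_index), int(row.p_peak_index),
                            rule="chord_max_distance")
        mn = detect_p_onset(x, int(row.t_end_index), int(row.p_peak_index),
                            rule="chord_min_distance_literal")
        assert mx != mn


class TestOffset:
    def test_clean_offset_within_two_samples(self, clean_record_and_truth):
        record, truth = clean_record_and_truth
        x = record.lead("II")
        for _, row in truth[truth.lead == "II"].head(5).iterrows():
            got, clamped = detect_p_offset(x, 0.0, int(row.p_peak_index),
                                           int(row.r_index) - 25, FS)
            assert not clamped
            assert abs(got - int(row.p_offset_index)) <= 2

    def test_symmetric_p_has_symmetric_flanks(self, clean_record_and_truth):
        record, truth = clean_record_and_truth
        x = record.lead("II")
        row = truth[truth.lead == "II"].iloc[3]
        onset = detect_p_onset(x, int(row.t_end_index), int(row.p_peak_index),
                               baseline=0.0)
        offset, _ = detect_p_offset(x, 0.0, int(row.p_peak_index),
                                    int(row.r_index) - 25, FS)
        assert abs((int(row.p_peak_index) - onset) - (offset - int(row.p_peak_index))) <= 2

    def test_wave_riding_into_qrs_is_clamped(self):
        # a ramp that never returns to baseline before the window end
        x = np.concatenate([np.zeros(100), np.linspace(0, 1, 200)])
        got, clamped = detect_p_offset(x, 0.0, 299, 299 - 1 + 1, FS)
        # too-short window: no offset at all
        assert got is None
        x2 = np.concatenate([np.zeros(50), np.linspace(0, 1, 100), np.full(100, 1.0)])
        got2, clamped2 = detect_p_offset(x2, 0.0, 149, 240, FS)
        assert clamped2 and got2 == 240

    def test_biphasic_terminal_phase_extends_offset(self, clean_record_and_truth):
        record, truth = clean_record_and_truth
        x = record.lead("V1")
        row = truth[truth.lead == "V1"].iloc[3]
        got, clamped = detect_p_offset(x, 0.0, int(row.p_peak_index),
                                       int(row.r_index) - 25, FS)
        assert not clamped
        assert abs(got - int(row.p_offset_index)) <= 3


class TestDelineateRecord:
    def test_ordering_invariant(self, noisy_record_and_truth):
        record, _ = noisy_record_and_truth
        beats = delineate_record(preprocess(record))
        ok = beats[beats.measurable]
        assert (ok.p_onset_index <= ok.p_peak_index).all()
        assert (ok.p_peak_index <= ok.p_offset_index).all()
        assert (ok.t_end_index < ok.p_onset_index).all()

    def test_shift_invariance(self):
        spec = clean_spec(n_beats=8)
        record, _ = generate_ecg(spec)
        k = 37
        shifted = ECGRecord(
            record.lead_names, record.sampling_rate_hz,
            np.concatenate([np.zeros((12, k)), record.samples[:, :-k]], axis=1),
        )
        b0 = delineate_record(record)
        b1 = delineate_record(shifted)
        m0 = b0[(b0.lead == "II") & b0.measurable].head(4)
        m1 = b1[(b1.lead == "II") & b1.measurable].head(4)
        for col in ("p_onset_index", "p_peak_index", "p_offset_index"):
            np.testing.assert_array_equal(
                m1[col].to_numpy(), m0[col].to_numpy() + k
            )

    def test_noise_free_pwd_matches_truth(self, clean_record_and_truth):
        record, truth = clean_record_and_truth
        beats = delineate_record(record)
        ok = beats[beats.measurable & (beats.lead != "V1")]
        merged = ok.merge(truth, on=["lead", "beat"], suffixes=("", "_t"))
        truth_ms = (merged.p_offset_index_t - merged.p_onset_index_t) / FS * 1000.0
        assert np.all(np.abs(merged.pwd_ms - truth_ms) <= 4.0)


class TestAveraging:
    @staticmethod
    def fake_beats(pwds, measurable=None, lead="II"):
        n = len(pwds)
        measurable = [True] * n if measurable is None else measurable
        return pd.DataFrame(
            dict(
                lead=[lead] * n, beat=np.arange(1, n + 1),
                prev_r_index=np.arange(n) * 500, r_index=np.arange(1, n + 1) * 500,
                pwd_ms=pwds, pwa_mv=[0.15] * n,
                neg_duration_ms=[0.0] * n, neg_peak_mv=[0.0] * n,
                measurable=measurable,
            )
        )

    def test_identical_beats_average_to_themselves(self):
        out = average_measurements(self.fake_beats([120.0] * 20), 20, FS)
        assert out["II"].pwd_ms == pytest.approx(120.0)
        assert out["II"].heart_rate_bpm == pytest.approx(60.0)

    def test_alternating_beats_average(self):
        out = average_measurements(self.fake_beats([118.0, 122.0] * 10), 20, FS)
        assert out["II"].pwd_ms == pytest.approx(120.0)

    def test_shortfall_error_names_lead_and_count(self):
        meas = [True] * 10 + [False] + [True] * 9
        with pytest.raises(ValueError, match=r"II \(10/20"):
            average_measurements(self.fake_beats([120.0] * 20, meas), 20, FS)

    def test_uses_first_consecutive_run(self):
        pwds = [100.0] * 5 + [200.0] * 20
        meas = [False] * 5 + [True] * 20
        out = average_measurements(self.fake_beats(pwds, meas), 20, FS)
        assert out["II"].pwd_ms == pytest.approx(200.0)

    def test_average_noise_shrinks_like_clt(self, rng):
        sds = []
        for _ in range(200):
            pwds = 120.0 + rng.normal(0.0, 4.0, 20)
            out = average_measurements(self.fake_beats(list(pwds)), 20, FS)
            sds.append(out["II"].pwd_ms)
        assert np.std(sds) == pytest.approx(4.0 / np.sqrt(20), rel=0.25)
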