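"""Fiducial delineation against the analytic ground truth."""

import dataclasses

import numpy as np
import pytest

from ecglvh import delineate, synth
from ecglvh.datatypes import LEADS, MedianBeat
from conftest import landmark_error_ms

# Landmarks of the delineation contract (T onset is an auxiliary point
# used only for the T-duration biomarker).
CONTRACT_LANDMARKS = (
    "p_onset", "p_pos_peak", "p_pos_end", "p_neg_peak", "p_offset",
    "qrs_onset", "q_peak", "q_end", "r_peak", "s_peak", "qrs_offset",
    "t_peak", "t_end",
)


def _gaussian_beat(waves, fs=500.0, length_ms=800.0, r_index_ms=300.0):
    """Unfiltered beat assembled from (amp, center_ms, sigma_ms) triples."""
    t = np.arange(int(length_ms * fs / 1000.0)) * 1000.0 / fs
    x = np.zeros_like(t)
    for amp, c, s in waves:
        x += amp * np.exp(-0.5 * ((t - c) / s) ** 2)
    return MedianBeat(beat=x, fs=fs, r_index=int(r_index_ms * fs / 1000.0),
                      pre_ms=r_index_ms, post_ms=length_ms - r_index_ms,
                      n_beats_used=5, isoelectric_level=0.0)


class TestCleanRecordFidelity:
    def test_all_landmarks_within_4ms(self, clean_beats, clean_fiducials):
        beats, _, _, truth = clean_beats
        fids, _ = clean_fiducials
        anchor = truth.beat_ms["II"]["r_peak"]
        for lead in LEADS:
            fid, _ = fids[lead]
            mb = beats[lead]
            for lm in CONTRACT_LANDMARKS:
                tv, mv, err = landmark_error_ms(fid, mb, truth, lead, lm,
                                                anchor)
                if tv is None:
                    continue
                assert mv is not None, f"{lead}/{lm} absent but expected"
                assert abs(err) <= 4.0, f"{lead}/{lm}: {err:+.2f} ms"

    def test_qrs_duration_in_reported_regime(self, clean_beats,
                                             clean_fiducials):
        # median-parameter template implies a QRS duration near 89 ms
        beats, _, _, _ = clean_beats
        fids, _ = clean_fiducials
        durations = []
        for lead in LEADS:
            fid, _ = fids[lead]
            if fid.qrs_onset is not None and fid.qrs_offset is not None:
                durations.append(
                    (fid.qrs_offset - fid.qrs_onset) * 1000.0
                    / beats[lead].fs)
        assert abs(np.median(durations) - 89.0) <= 15.0


class TestQrsBounds:
    def test_scale_invariance(self):
        waves = [(-0.08, 225, 6.5), (0.45, 250, 9.0), (-0.29, 275, 6.5)]
        mb1 = _gaussian_beat(waves)
        mb2 = dataclasses.replace(mb1, beat=2.0 * mb1.beat)
        assert delineate.qrs_bounds(mb1) == delineate.qrs_bounds(mb2)

    def test_bounds_bracket_r(self):
        mb = _gaussian_beat([(0.45, 250, 9.0)], r_index_ms=250)
        onset, offset = delineate.qrs_bounds(mb)
        assert onset < mb.r_index < offset

    def test_isolated_wave_matches_one_percent_crossing(self):
        mb = _gaussian_beat([(0.45, 300, 9.0)], r_index_ms=300)
        onset, offset = delineate.qrs_bounds(mb)
        expect_lo = 300 - delineate.K_ONSET * 9.0
        expect_hi = 300 + delineate.K_ONSET * 9.0
        assert onset * 2.0 == pytest.approx(expect_lo, abs=4.0)
        assert offset * 2.0 == pytest.approx(expect_hi, abs=4.0)


class TestLabelQrsWaves:
    def test_qrs_template_labels_all_three(self):
        mb = _gaussian_beat([(-0.08, 225, 6.5), (0.45, 250, 9.0),
                             (-0.29, 275, 6.5)], r_index_ms=250)
        onset, offset = delineate.qrs_bounds(mb)
        waves = delineate.label_qrs_waves(mb, onset, offset)
        assert abs(waves["q_peak"] * 2.0 - 225) <= 2.0
        assert abs(waves["r_peak"] * 2.0 - 250) <= 2.0
        assert abs(waves["s_peak"] * 2.0 - 275) <= 2.0

    def test_monophasic_r_has_no_q_or_s(self):
        mb = _gaussian_beat([(0.45, 250, 9.0)], r_index_ms=250)
        onset, offset = delineate.qrs_bounds(mb)
        waves = delineate.label_qrs_waves(mb, onset, offset)
        assert waves["r_peak"] is not None
        assert waves["q_peak"] is None and waves["s_peak"] is None

    def test_qs_complex_polarity_rule(self):
        # all-negative complex: the deflection is labelled Q, no R/S
        mb = _gaussian_beat([(-0.6, 250, 9.0)], r_index_ms=250)
        onset, offset = delineate.qrs_bounds(mb)
        waves = delineate.label_qrs_waves(mb, onset, offset)
        assert waves["q_peak"] is not None
        assert waves["r_peak"] is None and waves["s_peak"] is None


class TestPWave:
    def test_biphasic_components_recovered(self):
        mb = _gaussian_beat([(0.045, 100, 12.0), (-0.038, 135, 12.0),
                             (0.45, 250, 9.0)], r_index_ms=250)
        onset, _ = delineate.qrs_bounds(mb)
        p = delineate.p_wave_delineate(mb, onset)
        assert abs(p["p_pos_peak"] * 2.0 - 100) <= 4.0
        assert abs(p["p_neg_peak"] * 2.0 - 135) <= 4.0
        assert abs(mb.beat[p["p_pos_peak"]] - 0.045) <= 0.005
        assert abs(mb.beat[p["p_neg_peak"]] + 0.038) <= 0.005
        # boundaries near the 1 % crossings of the two components
        assert p["p_onset"] * 2.0 == pytest.approx(
            100 - delineate.K_ONSET * 12.0, abs=4.0)
        assert p["p_offset"] * 2.0 == pytest.approx(
            135 + delineate.K_ONSET * 12.0, abs=4.0)

    def test_monophasic_p_has_no_negative_component(self):
        mb = _gaussian_beat([(0.05, 110, 12.0), (0.45, 250, 9.0)],
                            r_index_ms=250)
        onset, _ = delineate.qrs_bounds(mb)
        p = delineate.p_wave_delineate(mb, onset)
        assert p["p_pos_peak"] is not None
        assert p["p_neg_peak"] is None and p["p_offset"] is not None

    def test_flat_window_gives_all_absent(self):
        mb = _gaussian_beat([(0.45, 250, 9.0)], r_index_ms=250)
        onset, _ = delineate.qrs_bounds(mb)
        p = delineate.p_wave_delineate(mb, onset)
        assert all(v is None for v in p.values())


class TestTWave:
    def test_tangent_matches_gaussian_closed_form(self):
        # tangent at the inflection of A·exp(−(t−c)²/2σ²) crosses zero
        # at c + 2σ
        mb = _gaussian_beat([(0.45, 250, 9.0), (0.15, 535, 26.5)],
                            r_index_ms=250, length_ms=800.0)
        _, offset = delineate.qrs_bounds(mb)
        t = delineate.t_delineate(mb, offset)
        assert t["t_end"] * 2.0 == pytest.approx(535 + 2 * 26.5, abs=4.0)
        assert t["t_peak"] * 2.0 == pytest.approx(535, abs=2.0)

    def test_amplitude_scale_invariance(self):
        mb1 = _gaussian_beat([(0.45, 250, 9.0), (0.10, 535, 26.5)],
                             r_index_ms=250)
        mb3 = dataclasses.replace(mb1, beat=3.0 * mb1.beat)
        _, off1 = delineate.qrs_bounds(mb1)
        _, off3 = delineate.qrs_bounds(mb3)
        assert delineate.t_delineate(mb1, off1)["t_end"] == \
            delineate.t_delineate(mb3, off3)["t_end"]

    def test_inverted_t_by_reflection_symmetry(self):
        up = _gaussian_beat([(0.45, 250, 9.0), (0.15, 535, 26.5)],
                            r_index_ms=250)
        down = _gaussian_beat([(0.45, 250, 9.0), (-0.15, 535, 26.5)],
                              r_index_ms=250)
        _, off = delineate.qrs_bounds(up)
        t_up = delineate.t_delineate(up, off)
        t_dn = delineate.t_delineate(down, off)
        assert abs(t_up["t_end"] - t_dn["t_end"]) <= 1


class TestInvariances:
    def test_circular_shift_moves_all_fiducials(self):
        rec, truth = synth.generate_ecg(noise=synth.NoiseSpec.none())
        from ecglvh import preprocess
        filt = preprocess.bandpass_filter(rec)
        peaks = preprocess.detect_r_peaks(filt, "II")
        rr = preprocess.mean_rr_ms(peaks, rec.fs)
        mb = preprocess.median_beat(filt, peaks)["II"]
        fid0, _ = delineate.delineate_beat(mb, rr_ms=rr)
        k = 7
        shifted = dataclasses.replace(mb, beat=np.roll(mb.beat, k),
                                      r_index=mb.r_index + k)
        fid1, _ = delineate.delineate_beat(shifted, rr_ms=rr)
        for lm in CONTRACT_LANDMARKS:
            v0, v1 = getattr(fid0, lm), getattr(fid1, lm)
            if v0 is None:
                assert v1 is None
            else:
                assert abs((v1 - v0) - k) <= 1, lm

    def test_uniform_scaling_preserves_fiducials(self, clean_beats):
        beats, _, rr, _ = clean_beats
        mb = beats["V5"]
        fid1, _ = delineate.delineate_beat(mb, rr_ms=rr)
        mb2 = dataclasses.replace(mb, beat=mb.beat * 2.0,
                                  isoelectric_level=mb.isoelectric_level * 2)
        fid2, _ = delineate.delineate_beat(mb2, rr_ms=rr)
        for lm in CONTRACT_LANDMARKS:
            v1, v2 = getattr(fid1, lm), getattr(fid2, lm)
            if v1 is None:
                assert v2 is None
            else:
                assert abs(v1 - v2) <= 1, lm
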