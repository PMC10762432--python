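import math

import numpy as np
import pytest

import earbeat as eb
from earbeat.errors import ConfigError, ParameterError
from earbeat.heartvec import ChannelNoise, GaussianWaveParams, NoiseSpec, cycle_axis

from conftest import CHANNELS_A, proportional_lead_field, regular_schedule


def zeroed_params(**r_kwargs):
    p = GaussianWaveParams()
    p.amplitudes = {k: (0.0, 0.0, 0.0) for k in "PQRST"}
    p.amplitudes.update(r_kwargs)
    return p


class TestSynthHeartVector:
    def test_null_source_is_identically_zero(self):
        hv = eb.synth_heart_vector(zeroed_params(), fs=500.0)
        assert np.all(hv.p == 0)

    def test_default_axis_and_r_alignment(self, hv, lead1_template):
        assert hv.n_samples == 300
        assert hv.t[0] == -200.0 and hv.t[-1] < 400.0
        # R maximum of the Lead-I projection at t = 0 within one sample
        assert abs(int(np.argmax(lead1_template)) - hv.r_index) <= 1

    def test_single_r_bump_matches_closed_form(self):
        params = zeroed_params(R=(1.0, 0.0, 0.0))
        params.widths_ms["R"] = 10.0
        hv = eb.synth_heart_vector(params, fs=500.0)
        for t_ms in (-20.0, -4.0, 0.0, 10.0, 30.0):
            i = int(np.argmin(np.abs(hv.t - t_ms)))
            expected = math.exp(-hv.t[i] ** 2 / (2.0 * 10.0**2))
            assert hv.p[0, i] == pytest.approx(expected, rel=1e-12)
            assert hv.p[1, i] == 0 and hv.p[2, i] == 0

    @pytest.mark.parametrize("fs,n", [(500.0, 300), (300.0, 180), (1200.0, 720)])
    def test_sample_count_scales_with_rate(self, fs, n):
        assert cycle_axis(fs).size == n
        assert eb.synth_heart_vector(fs=fs).n_samples == n

    def test_parameter_validation(self):
        bad = GaussianWaveParams()
        bad.centers_ms["Q"] = 10.0  # after R
        with pytest.raises(ParameterError):
            eb.synth_heart_vector(bad)
        bad2 = GaussianWaveParams()
        bad2.widths_ms["T"] = 0.0
        with pytest.raises(ParameterError):
            eb.synth_heart_vector(bad2)
        with pytest.raises(ParameterError):
            eb.synth_heart_vector(fs=100.0)


class TestBeatSchedule:
    def test_regular_schedule(self):
        sch = eb.synth_beat_schedule(1.0, 0.0, 10.0, seed=0)
        assert np.allclose(sch.beat_times, np.arange(10.0))

    def test_seed_reproducibility(self):
        a = eb.synth_beat_schedule(0.8, 0.05, 100.0, seed=42)
        b = eb.synth_beat_schedule(0.8, 0.05, 100.0, seed=42)
        assert np.array_equal(a.beat_times, b.beat_times)

    def test_renewal_count(self):
        # beats in [0, D) with RR ~ N(1, 0.05): renewal theory gives
        # E[count] = D/rr + 1/2 and sd(count) ~ sd*sqrt(D/rr)/rr
        counts = np.array([eb.synth_beat_schedule(1.0, 0.05, 600.0, seed=s).n_beats
                           for s in range(100)])
        sd = 0.05 * math.sqrt(600.0)
        assert abs(counts.mean() - 600.5) < 0.5
        assert np.all(np.abs(counts - 600.5) < 5 * sd)

    def test_rr_floor_respected(self):
        sch = eb.synth_beat_schedule(0.45, 0.2, 120.0, seed=5)
        assert np.all(np.diff(sch.beat_times) > 0.35)

    def test_validation(self):
        with pytest.raises(ParameterError):
            eb.synth_beat_schedule(0.3, 0.0, 10.0)
        with pytest.raises(ParameterError):
            eb.synth_beat_schedule(1.0, -0.1, 10.0)
        with pytest.raises(ParameterError):
            eb.synth_beat_schedule(1.0, 0.0, 0.5)


class TestRenderRecording:
    def test_noiseless_channel_equals_tiled_projection(self, hv, lead_field, lead1_template):
        sch = regular_schedule(duration=10.0, rr=1.0, offset=0.5, seed=0)
        rec = eb.render_recording(hv, sch, lead_field,
                                  NoiseSpec.silent(["wrist"]), 500.0, 11.0)
        trace = rec.channel("wrist")
        for b in sch.beat_times:
            k = round(b * 500)
            np.testing.assert_allclose(trace[k - 100 : k + 200], lead1_template,
                                       atol=1e-12)

    def test_bitwise_reproducibility(self, hv, lead_field):
        sch = regular_schedule(duration=5.0, rr=0.8)
        noise = NoiseSpec({ch: ChannelNoise() for ch in CHANNELS_A}, seed=9)
        a = eb.render_recording(hv, sch, lead_field, noise, 500.0, 6.0)
        b = eb.render_recording(hv, sch, lead_field, noise, 500.0, 6.0)
        assert np.array_equal(a.data, b.data)

    def test_linearity_of_clean_signal(self, hv, lead_field):
        sch = regular_schedule(duration=5.0)
        silent = NoiseSpec.silent(["wrist", "ear"])
        base = eb.render_recording(hv, sch, lead_field, silent, 500.0, 6.0)
        scaled_params = GaussianWaveParams()
        scaled_params.amplitudes = {k: tuple(3.0 * a for a in v)
                                    for k, v in scaled_params.amplitudes.items()}
        hv3 = eb.synth_heart_vector(scaled_params)
        tripled = eb.render_recording(hv3, sch, lead_field, silent, 500.0, 6.0)
        np.testing.assert_allclose(tripled.data, 3.0 * base.data, atol=1e-12)

    def test_true_r_times_within_one_sample(self, noiseless_rec):
        trace = noiseless_rec.channel("wrist")
        fs = noiseless_rec.fs
        for b in noiseless_rec.annotations:
            k = round(b * fs)
            seg = trace[k - 5 : k + 6]
            assert abs(int(np.argmax(seg)) - 5) <= 1

    def test_zero_noise_windows_identical(self, noiseless_rec):
        trace = noiseless_rec.channel("ear")
        fs = noiseless_rec.fs
        wins = [trace[round(b * fs) - 100 : round(b * fs) + 200]
                for b in noiseless_rec.annotations]
        for w in wins[1:]:
            np.testing.assert_array_equal(w, wins[0])

    def test_missing_channel_in_lead_field(self, hv, lead_field):
        sch = regular_schedule(duration=5.0)
        with pytest.raises(ConfigError):
            eb.render_recording(hv, sch, lead_field,
                                NoiseSpec.silent(["no_such_site"]), 500.0, 6.0)

    def test_invalid_output_rate(self, hv, lead_field):
        sch = regular_schedule(duration=5.0)
        with pytest.raises(ParameterError):
            eb.render_recording(hv, sch, lead_field, NoiseSpec.silent(["wrist"]),
                                fs_out=123.0, duration=6.0)

    def test_gain_ratio_recovered_downstream(self, hv, lead_field):
        # 4:2:1 lead gains with equal noise: grand-median R amplitudes in
        # the same ratio within 5% (linearity + median convergence)
        from earbeat.delineate import delineate
        from earbeat.ensemble import extract_windows, grand_median
        from earbeat.rpeaks import RPeakSet

        gains = {"neck": 0.8, "ear": 0.4, "scalp": 0.2}
        lf = proportional_lead_field(lead_field, gains)
        sch = regular_schedule(duration=240.0, rr=0.8, seed=3)
        noise = NoiseSpec(
            {ch: ChannelNoise(0.01, 0, 0, 0, 0, 0) for ch in ["neck", "ear", "scalp"]},
            seed=4)
        rec = eb.render_recording(hv, sch, lf, noise, 500.0, 241.0)
        peaks = RPeakSet(np.rint(sch.beat_times * 500).astype(int), 500.0)
        amps = {}
        for ch in gains:
            gm = grand_median(extract_windows(rec, ch, peaks))
            amps[ch] = delineate(gm).amps_mv["R"]
        assert amps["neck"] / amps["scalp"] == pytest.approx(4.0, rel=0.05)
        assert amps["ear"] / amps["scalp"] == pytest.approx(2.0, rel=0.05)
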