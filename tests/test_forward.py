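import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import earbeat as eb
from earbeat.errors import ConfigError, SingularityError
from earbeat.forward import ElectrodeLayout, LeadField, default_layout

finite3 = st.tuples(*[st.floats(-5, 5, allow_nan=False)] * 3)


def potential_oracle(p, r_dip, r_obs, sigma):
    """Independent closed-form evaluation in SI units (returns mV)."""
    p_si = [c * 1e-3 for c in p]  # mA.m -> A.m
    r = [(a - b) * 1e-3 for a, b in zip(r_obs, r_dip)]  # mm -> m
    d = math.sqrt(sum(c * c for c in r))
    phi_v = sum(pi * ri for pi, ri in zip(p_si, r)) / (4 * math.pi * sigma * d**3)
    return phi_v * 1e3


class TestDipolePotential:
    def test_orthogonal_moment_gives_zero(self):
        assert eb.dipole_potential((0, 1, 0), (0, 0, 0), (100, 0, 0), 0.2) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(p=finite3, r=finite3)
    def test_antisymmetry(self, p, r):
        obs = tuple(c * 50 + 120 for c in r)  # keep away from the source
        phi = eb.dipole_potential(p, (0, 0, 0), obs, 0.2)
        phi_neg = eb.dipole_potential(tuple(-c for c in p), (0, 0, 0), obs, 0.2)
        assert phi_neg == -phi

    def test_closed_form_value(self):
        # 1 mA.m axial dipole observed 100 mm away in sigma = 0.2 S/m
        phi = eb.dipole_potential((0, 0, 1), (0, 0, 0), (0, 0, 100), 0.2)
        assert phi == pytest.approx(39.79, abs=0.01)
        assert phi == pytest.approx(
            potential_oracle((0, 0, 1), (0, 0, 0), (0, 0, 100), 0.2), rel=1e-12)

    def test_singularity_and_sigma_errors(self):
        with pytest.raises(SingularityError):
            eb.dipole_potential((1, 0, 0), (0, 0, 0), (0.5, 0, 0), 0.2)
        with pytest.raises(ConfigError):
            eb.dipole_potential((1, 0, 0), (0, 0, 0), (100, 0, 0), 0.0)


class TestLeadField:
    def test_coincident_terminals_zero_lead(self):
        layout = ElectrodeLayout(
            positions={"a": (100, 0, 0), "b": (100, 0, 0)},
            channels={"degenerate": ("a", "b")})
        lf = eb.lead_field_from_layout(layout, sigma=0.2)
        assert np.allclose(lf.vectors["degenerate"], 0)

    def test_symmetric_pair_blind_to_orthogonal_moment(self):
        layout = ElectrodeLayout(
            positions={"up": (0, 0, 100), "down": (0, 0, -100)},
            channels={"axial": ("up", "down")})
        lf = eb.lead_field_from_layout(layout, sigma=0.2)
        # the pair senses only pz; px projects to zero
        assert lf.vectors["axial"] @ np.array([1.0, 0, 0]) == pytest.approx(0, abs=1e-15)
        assert abs(lf.vectors["axial"] @ np.array([0, 0, 1.0])) > 0

    def test_terminal_swap_negates(self, lead_field):
        layout = default_layout()
        layout.channels["ear_swapped"] = ("left_helix", "left_concha")
        lf = eb.lead_field_from_layout(layout, sigma=0.2)
        np.testing.assert_allclose(lf.vectors["ear_swapped"], -lf.vectors["ear"],
                                   atol=1e-15)

    def test_missing_electrode_rejected(self):
        layout = ElectrodeLayout(positions={"a": (1, 2, 3)},
                                 channels={"bad": ("a", "nowhere")})
        with pytest.raises(ConfigError):
            eb.lead_field_from_layout(layout, sigma=0.2)

    def test_neck_closer_hence_stronger_than_ear(self, hv, lead_field):
        # mean heart-vector direction over the cycle
        p_hat = hv.p.mean(axis=1)
        p_hat = p_hat / np.linalg.norm(p_hat)
        assert abs(lead_field.vectors["neck"] @ p_hat) > abs(lead_field.vectors["ear"] @ p_hat)


class TestSimulateChannelRhythm:
    def test_zero_lead_vector_zero_trace(self, hv, lead_field):
        lf = LeadField(vectors={"null": np.zeros(3)}, sigma=0.2,
                       dipole_pos=np.zeros(3))
        assert np.all(eb.simulate_channel_rhythm(hv, lf, "null") == 0)

    def test_parallel_leads_perfectly_correlated(self, hv, lead_field):
        lf = LeadField(vectors={"a": np.array([1.0, 0.2, 0.1]),
                                "b": 2.5 * np.array([1.0, 0.2, 0.1])},
                       sigma=0.2, dipole_pos=np.zeros(3))
        a = eb.simulate_channel_rhythm(hv, lf, "a")
        b = eb.simulate_channel_rhythm(hv, lf, "b")
        assert eb.pearson(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_channel(self, hv, lead_field):
        with pytest.raises(ConfigError):
            eb.simulate_channel_rhythm(hv, lead_field, "toe")

    def test_head_channels_correlate_with_lead1_and_attenuate(self, hv, lead_field,
                                                              lead1_template):
        amps = {}
        for ch in ["neck", "ear", "scalp", "cross_ear", "right_ear"]:
            trace = eb.simulate_channel_rhythm(hv, lead_field, ch)
            assert eb.pearson(trace, lead1_template) > 0.95
            amps[ch] = float(np.max(np.abs(trace)))
        assert amps["neck"] > amps["ear"] > amps["scalp"]
        assert amps["cross_ear"] > amps["ear"] and amps["cross_ear"] > amps["right_ear"]

    def test_superposition_exact(self, lead_field):
        from earbeat.heartvec import GaussianWaveParams

        hv1 = eb.synth_heart_vector()
        p2 = GaussianWaveParams()
        p2.amplitudes = {k: tuple(0.5 * a for a in v) for k, v in p2.amplitudes.items()}
        hv2 = eb.synth_heart_vector(p2)
        summed = eb.HeartVector(fs=hv1.fs, t=hv1.t, p=hv1.p + hv2.p)
        for ch in ["wrist", "ear"]:
            np.testing.assert_allclose(
                eb.simulate_channel_rhythm(summed, lead_field, ch),
                eb.simulate_channel_rhythm(hv1, lead_field, ch)
                + eb.simulate_channel_rhythm(hv2, lead_field, ch),
                rtol=1e-12, atol=1e-18)

    def test_distance_doubling_quarters_amplitude(self, hv):
        near = default_layout()
        far = default_layout()
        far.positions = {k: 2.0 * v for k, v in far.positions.items()}
        lf_near = eb.lead_field_from_layout(near, sigma=0.2)
        lf_far = eb.lead_field_from_layout(far, sigma=0.2)
        for ch in lf_near.vectors:
            a = eb.simulate_channel_rhythm(hv, lf_near, ch)
            b = eb.simulate_channel_rhythm(hv, lf_far, ch)
            np.testing.assert_allclose(b, a / 4.0, rtol=1e-9, atol=1e-18)
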