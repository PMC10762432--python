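import numpy as np
import pytest

import earbeat as eb
from earbeat.heartvec import ChannelNoise, NoiseSpec
from earbeat.pipeline import ExperimentPlan

CHANNELS_A = ["wrist", "scalp", "ear", "neck"]


@pytest.fixture(scope="session")
def hv():
    """Default heart vector at 500 Hz."""
    return eb.synth_heart_vector()


@pytest.fixture(scope="session")
def lead_field():
    return eb.lead_field_from_layout(eb.default_layout())


@pytest.fixture(scope="session")
def lead1_template(hv, lead_field):
    """Noiseless Lead-I (wrist) projection of the default heart vector."""
    return eb.simulate_channel_rhythm(hv, lead_field, "wrist")


def regular_schedule(duration=62.0, rr=1.0, offset=0.5, seed=1):
    """Perfectly regular beat schedule, shifted so every beat is fully rendered."""
    sch = eb.synth_beat_schedule(rr, 0.0, duration, seed=seed)
    sch.beat_times = sch.beat_times + offset
    return sch


@pytest.fixture(scope="session")
def noiseless_rec(hv, lead_field):
    """60+ beats, geometric lead field, zero noise, Experiment-A channels."""
    sch = regular_schedule()
    noise = NoiseSpec.silent(CHANNELS_A)
    return eb.render_recording(hv, sch, lead_field, noise, fs_out=500.0, duration=63.0)


@pytest.fixture(scope="session")
def noisy_reference_rec(hv, lead_field):
    """60 s at 60 bpm, reference-only broadband noise at 5% of the R amplitude."""
    sch = regular_schedule(duration=60.0, rr=1.0, offset=0.5, seed=2)
    r_amp = 1.042  # rendered wrist R amplitude of the default generator
    noise = NoiseSpec({"wrist": ChannelNoise(0.05 * r_amp, 0, 0, 0, 0, 0)}, seed=3)
    return eb.render_recording(hv, sch, lead_field, noise, fs_out=500.0, duration=60.6)


def proportional_lead_field(base, gains, reference="wrist"):
    """Lead field whose test channels are scaled copies of the reference lead."""
    from earbeat.forward import LeadField

    unit = base.vectors[reference] / np.linalg.norm(base.vectors[reference])
    vectors = {reference: base.vectors[reference]}
    vectors.update({ch: g * unit for ch, g in gains.items()})
    return LeadField(vectors=vectors, sigma=base.sigma, dipole_pos=base.dipole_pos)
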