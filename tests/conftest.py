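import numpy as np
import pytest

from cardiomap.containers import VoltageTrace
from cardiomap.synthgen import get_preset


@pytest.fixture(scope="session")
def organ():
    """Noise-free organ-explant preset (planar propagation, fiber at 30 deg)."""
    return get_preset("organ_explant", fiber_angle_deg=30.0)


@pytest.fixture(scope="session")
def monolayer():
    return get_preset("monolayer", fiber_angle_deg=30.0)


@pytest.fixture(scope="session")
def organ_point_map():
    """Activation map of a noise-free organ-explant point-stimulus movie
    (computed once; several tests interrogate it)."""
    from cardiomap.activation_mapping import compute_activation_map, preprocess_movie
    from cardiomap.synthgen import simulate_movie

    gt, tpl = get_preset("organ_explant", fiber_angle_deg=30.0, stim_site=(50, 50))
    movie = simulate_movie(gt, tpl)
    return movie, compute_activation_map(preprocess_movie(movie))


def single_beat_trace(template, sampling_interval_ms, activation_ms=100.0,
                      stim=True, duration_pad_ms=100.0):
    """One noise-free template beat with a sample exactly at ramp onset."""
    duration = activation_ms + template.t_end_ms + duration_pad_ms
    v = template.sample(duration, sampling_interval_ms, activation_ms=activation_ms)
    return VoltageTrace(
        samples=v,
        sampling_interval_ms=sampling_interval_ms,
        stim_times_ms=[activation_ms] if stim else [],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
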