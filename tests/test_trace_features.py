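"""Beat detection, diastolic measurements, normalization, APD and upstroke."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomap.containers import OPTICAL, VoltageTrace
from cardiomap.errors import (
    NotMeasurableError,
    UnitError,
    UnmeasurableAPDError,
)
from cardiomap.synthgen import get_preset, simulate_intracellular_trace
from cardiomap.template import make_template
from cardiomap.trace_features import (
    detect_beats,
    extract_features,
    measure_apd,
    measure_diastolic,
    measure_upstroke,
    normalize_beat,
)

from conftest import single_beat_trace


def triangle_trace(h=0.1):
    """Instant upstroke -80 -> +20 mV at t = 50 ms, then a linear fall back
    to baseline at t = 250 ms: APD_f = 2f ms analytically."""
    t = np.arange(0.0, 400.0 + h / 2, h)
    v = np.full_like(t, -80.0)
    fall = (t >= 50.0) & (t <= 250.0)
    v[fall] = 20.0 - 100.0 * (t[fall] - 50.0) / 200.0
    return VoltageTrace(samples=v, sampling_interval_ms=h, stim_times_ms=[50.0])


class TestDetectBeats:
    def test_constant_trace_has_no_beats(self):
        tr = VoltageTrace(samples=np.full(500, -80.0), sampling_interval_ms=1.0)
        beats, cl, spont = detect_beats(tr)
        assert beats == [] and cl is None and not spont

    def test_spontaneity_requires_missing_stimulus(self):
        gt, tpl = get_preset("organ_explant")
        paced = simulate_intracellular_trace(gt, tpl, 2700, cl_ms=500, n_stimuli=5)
        assert detect_beats(paced)[2] is False
        # same waveform without the stimulus channel -> spontaneous
        bare = VoltageTrace(samples=paced.samples, sampling_interval_ms=1.0)
        assert detect_beats(bare)[2] is True

    def test_spontaneous_cycle_length_recovered(self):
        """Spontaneous generator tuned to the published 468 ms cycle length
        is measured back within 2 ms."""
        from cardiomap.template import slope_for_cycle_length

        _, tpl = get_preset("organ_explant")
        gt, _ = get_preset(
            "organ_explant",
            diastolic_slope_mV_s=slope_for_cycle_length(tpl, 468.0),
        )
        trace = simulate_intracellular_trace(gt, tpl, duration_ms=7 * 468)
        beats, cl, _ = detect_beats(trace)
        assert len(beats) >= 6
        assert cl == pytest.approx(468.0, abs=2.0)


class TestDiastole:
    @pytest.mark.parametrize("slope,expected_flag", [(5.0, True), (4.9, False)])
    def test_inclusive_five_mv_per_s_threshold(self, slope, expected_flag):
        gt, tpl = get_preset("organ_explant", diastolic_slope_mV_s=slope)
        tau = 0.1 * tpl.apa_mV / slope * 1000.0
        trace = simulate_intracellular_trace(
            gt, tpl, duration_ms=3 * (tau + tpl.t_end_ms)
        )
        beats, _, _ = detect_beats(trace)
        dia = measure_diastolic(trace, beats)
        assert dia.phase4_flag is expected_flag
        assert dia.phase4_slope_mV_s == pytest.approx(slope, abs=0.05)

    def test_flat_diastole_reports_rmp_exactly(self):
        gt, tpl = get_preset("organ_explant")
        trace = simulate_intracellular_trace(gt, tpl, 2700, cl_ms=500, n_stimuli=5)
        beats, _, _ = detect_beats(trace)
        dia = measure_diastolic(trace, beats)
        assert not dia.phase4_flag
        assert dia.mdp_or_rmp_mV == pytest.approx(-83.9, abs=1e-6)

    def test_optical_trace_rejected(self):
        tr = VoltageTrace(samples=np.zeros(100), sampling_interval_ms=1.0,
                          modality=OPTICAL)
        with pytest.raises(UnitError):
            measure_diastolic(tr, [])

    def test_endpoint_method_agrees_on_linear_ramp(self):
        gt, tpl = get_preset("organ_explant", diastolic_slope_mV_s=20.0)
        trace = simulate_intracellular_trace(gt, tpl, 3000)
        beats, _, _ = detect_beats(trace)
        reg = measure_diastolic(trace, beats, method="regression")
        end = measure_diastolic(trace, beats, method="endpoint")
        assert reg.phase4_slope_mV_s == pytest.approx(end.phase4_slope_mV_s, abs=0.5)


class TestNormalization:
    def test_baseline_zero_peak_hundred(self):
        tr = triangle_trace()
        beats, _, _ = detect_beats(tr)
        nb = normalize_beat(tr, beats[0])
        assert nb.samples[nb.peak_idx] == pytest.approx(100.0)
        assert np.median(nb.samples[: nb.act_idx][-100:]) == pytest.approx(0.0)

    def test_idempotent(self):
        tr = triangle_trace()
        beats, _, _ = detect_beats(tr)
        nb1 = normalize_beat(tr, beats[0])
        tr2 = VoltageTrace(samples=nb1.samples, sampling_interval_ms=tr.sampling_interval_ms)
        b2, _, _ = detect_beats(tr2)
        nb2 = normalize_beat(tr2, b2[0])
        assert np.allclose(nb2.samples[b2[0].start:], nb1.samples[b2[0].start:])

    @settings(max_examples=25, deadline=None)
    @given(gain=st.floats(0.5, 2.0), offset=st.floats(-500.0, 500.0))
    def test_apd_and_upstroke_invariant_under_affine_rescaling(self, gain, offset):
        """Optical gain and baseline offsets must not change any normalized
        measurement."""
        _, tpl = get_preset("organ_explant")
        ref = single_beat_trace(tpl, 1.0)
        scaled = VoltageTrace(samples=gain * ref.samples + offset,
                              sampling_interval_ms=1.0, stim_times_ms=[100.0])
        out = []
        for tr in (ref, scaled):
            beats, _, _ = detect_beats(tr)
            nb = normalize_beat(tr, beats[0])
            out.append((measure_apd(nb, 70), measure_upstroke(nb)))
        assert out[0] == pytest.approx(out[1], rel=1e-9)


class TestAPD:
    def test_analytic_triangle(self):
        """Linear fall over 200 ms: APD_f = 2f ms, up to one sample."""
        tr = triangle_trace(h=0.1)
        beats, _, _ = detect_beats(tr)
        nb = normalize_beat(tr, beats[0])
        for f in (20, 50, 70, 90):
            assert measure_apd(nb, f) == pytest.approx(2.0 * f, abs=0.2)

    def test_clipped_beat_partial_measurability(self):
        """A beat truncated before 90% repolarization still yields
        APD20/50/70 but raises for APD90."""
        _, tpl = get_preset("organ_explant")
        trace = single_beat_trace(tpl, 1.0)
        cut = int((100.0 + tpl.apd_anchors_ms[70] + 5.0) / 1.0)
        clipped = VoltageTrace(samples=trace.samples[:cut],
                               sampling_interval_ms=1.0, stim_times_ms=[100.0])
        beats, _, _ = detect_beats(clipped)
        nb = normalize_beat(clipped, beats[0])
        for f in (20, 50, 70):
            assert measure_apd(nb, f) > 0
        with pytest.raises(UnmeasurableAPDError):
            measure_apd(nb, 90)

    @pytest.mark.parametrize("preset", ["organ_explant", "fresh_tissue", "monolayer"])
    def test_monotone_in_fraction(self, preset):
        feats = extract_features(single_beat_trace(get_preset(preset)[1], 1.0))
        apds = [feats.apd_ms[f] for f in (20, 50, 70, 90)]
        assert all(a < b for a, b in zip(apds, apds[1:]))

    @settings(max_examples=20, deadline=None)
    @given(st.data())
    def test_monotone_for_random_templates(self, data):
        """APD20 <= APD50 <= APD70 <= APD90 whenever all are measurable."""
        a20 = data.draw(st.floats(10.0, 80.0))
        gaps = [data.draw(st.floats(1.0, 60.0)) for _ in range(3)]
        anchors = {20: a20, 50: a20 + gaps[0], 70: a20 + sum(gaps[:2]),
                   90: a20 + sum(gaps)}
        tpl = make_template(rmp_mV=-75.0, t_upstroke_ms=2.5, apd_anchors_ms=anchors)
        feats = extract_features(single_beat_trace(tpl, 1.0))
        apds = [feats.apd_ms[f] for f in (20, 50, 70, 90)]
        assert all(a <= b for a, b in zip(apds, apds[1:]))

    def test_decimation_stability(self):
        """APDs at 2 ms sampling agree with 1 ms sampling within 2 ms."""
        _, tpl = get_preset("organ_explant")
        f1 = extract_features(single_beat_trace(tpl, 1.0))
        f2 = extract_features(single_beat_trace(tpl, 2.0))
        for f in (20, 50, 70, 90):
            assert f2.apd_ms[f] == pytest.approx(f1.apd_ms[f], abs=2.0)


class TestUpstroke:
    def test_linear_rise_analytic(self):
        """0 -> 100 %APA over 2 ms sampled at 1 kHz: 50 %APA/ms."""
        tpl = make_template(rmp_mV=-80.0, t_upstroke_ms=2.0,
                            apd_anchors_ms={20: 30, 50: 60, 70: 80, 90: 100})
        trace = single_beat_trace(tpl, 1.0)
        beats, _, _ = detect_beats(trace)
        nb = normalize_beat(trace, beats[0])
        assert measure_upstroke(nb) == pytest.approx(50.0, abs=0.5)

    def test_not_measurable_at_two_ms(self):
        _, tpl = get_preset("monolayer")
        trace = single_beat_trace(tpl, 2.0)
        beats, _, _ = detect_beats(trace)
        nb = normalize_beat(trace, beats[0])
        with pytest.raises(NotMeasurableError):
            measure_upstroke(nb)
        assert extract_features(trace).dapadt_max_pct_per_ms is None
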