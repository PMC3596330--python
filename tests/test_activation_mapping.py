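"""Activation maps, isochrones, conduction velocity, anisotropy, capture."""

import numpy as np
import pytest

from cardiomap.activation_mapping import (
    ActivationMap,
    PreprocessedMovie,
    assess_capture,
    compute_activation_map,
    cv_two_point,
    directional_cv_scan,
    extract_isochrones,
    preprocess_movie,
)
from cardiomap.containers import OpticalMovie
from cardiomap.errors import (
    EmptyMaskError,
    InsufficientStimuliError,
    MapError,
    UndefinedVelocityError,
)
from cardiomap.synthgen import (
    TissueGroundTruth,
    get_preset,
    simulate_movie,
    simulate_pacing_run,
)


def _aligned(a, b):
    """Compare two time fields up to a common offset (aligned at their
    earliest in-common point)."""
    return (a - np.nanmin(a)) - (b - np.nanmin(b))


def synthetic_map(t_field, pitch=0.01, h=1.0):
    mask = np.isfinite(t_field)
    gy, gx = np.gradient(t_field)
    return ActivationMap(
        t_act_ms=t_field, mask=mask,
        gradient_deg=np.degrees(np.arctan2(gy, gx)),
        stim_ref_ms=0.0, sampling_interval_ms=h, pixel_pitch_cm=pitch,
    )


class TestPreprocess:
    def test_noise_free_wave_keeps_all_pixels(self, organ):
        gt, tpl = organ
        pm = preprocess_movie(simulate_movie(gt, tpl))
        assert pm.mask.all()

    def test_zero_signal_quadrant_masked(self, organ):
        gt, tpl = organ
        movie = simulate_movie(gt, tpl)
        frames = movie.frames.copy()
        frames[:, :30, :30] = frames[0, 40, 40]  # flat fluorescence, no beat
        m2 = OpticalMovie(frames=frames, sampling_interval_ms=movie.sampling_interval_ms,
                          pixel_pitch_cm=movie.pixel_pitch_cm,
                          stim_times_ms=movie.stim_times_ms)
        pm = preprocess_movie(m2)
        assert not pm.mask[:30, :30].any()
        assert pm.mask[40:, 40:].all()

    def test_constant_movie_is_empty(self):
        movie = OpticalMovie(frames=np.ones((10, 8, 8)), sampling_interval_ms=1.0,
                             pixel_pitch_cm=0.01)
        with pytest.raises(EmptyMaskError):
            preprocess_movie(movie)

    def test_spatial_median_filter_preserves_noise_free_activation(self, organ):
        gt, tpl = organ
        movie = simulate_movie(gt, tpl)
        a1 = compute_activation_map(preprocess_movie(movie))
        a2 = compute_activation_map(preprocess_movie(movie, spatial_median=True))
        dev = _aligned(a1.t_act_ms, a2.t_act_ms)
        assert np.nanmax(np.abs(dev)) <= movie.sampling_interval_ms


class TestActivationMap:
    def test_oracle_equivalence_noise_free(self, organ):
        """The measured map matches the generator's eikonal field to within
        half a sample everywhere in-mask."""
        gt, tpl = organ
        movie = simulate_movie(gt, tpl)
        amap = compute_activation_map(preprocess_movie(movie))
        dev = _aligned(amap.t_act_ms, movie.ground_truth["activation_field_ms"])
        assert np.nanmax(np.abs(dev)) <= 0.5 * movie.sampling_interval_ms

    def test_oracle_equivalence_point_stimulus(self, organ_point_map):
        movie, amap = organ_point_map
        dev = _aligned(amap.t_act_ms, movie.ground_truth["activation_field_ms"])
        assert np.nanmax(np.abs(dev)) <= 0.5 * movie.sampling_interval_ms

    def test_subsample_refinement_used(self, organ):
        """Refined activation times fall between frames, not on them."""
        gt, tpl = organ
        amap = compute_activation_map(preprocess_movie(simulate_movie(gt, tpl)))
        frac = np.modf(amap.t_act_ms[amap.mask] / amap.sampling_interval_ms)[0]
        assert (np.abs(frac) > 1e-6).mean() > 0.9

    def test_undefined_outside_mask(self, organ):
        gt, tpl = organ
        movie = simulate_movie(gt, tpl)
        mask = np.ones(movie.frames.shape[1:], bool)
        mask[:10] = False
        movie.mask = mask
        amap = compute_activation_map(preprocess_movie(movie))
        assert np.isnan(amap.t_act_ms[:10]).all()

    def test_mostly_silent_movie_invalid(self):
        frames = np.random.default_rng(0).normal(size=(30, 20, 20))
        frames[15:, :4, :4] += 100.0  # a clean upstroke in 4% of pixels
        pm = PreprocessedMovie(frames=frames, mask=np.ones((20, 20), bool),
                               sampling_interval_ms=1.0, pixel_pitch_cm=0.01)
        with pytest.raises(MapError):
            compute_activation_map(pm)


class TestIsochrones:
    def test_planar_isochrones_are_straight_and_oriented(self, organ):
        """Plane wave along a 30-degree fiber: isochrones are straight lines
        perpendicular to the propagation direction (within 2 degrees)."""
        gt, tpl = organ
        amap = compute_activation_map(preprocess_movie(simulate_movie(gt, tpl)))
        iso = extract_isochrones(amap, 10.0)
        assert len(iso) >= 3
        for polys in iso.values():
            pts = np.vstack(polys)
            pts = pts - pts.mean(axis=0)
            # principal axis of the contour points, in (row, col) coords
            w, v = np.linalg.eigh(pts.T @ pts)
            axis = v[:, -1]
            angle = np.degrees(np.arctan2(axis[0], axis[1])) % 180.0
            expected = (gt.fiber_angle_deg + 90.0) % 180.0
            assert min(abs(angle - expected), 180 - abs(angle - expected)) < 2.0

    def test_isotropic_contours_are_nearly_circular(self):
        gt = TissueGroundTruth(v_long_cm_s=20.0, stim_site=(50, 50))
        _, tpl = get_preset("organ_explant")
        movie = simulate_movie(gt, tpl)
        amap = compute_activation_map(preprocess_movie(movie))
        iso = extract_isochrones(amap, 10.0)
        lev = sorted(iso)[1]
        pts = np.vstack(iso[lev]) - (50, 50)
        r = np.hypot(*pts.T)
        assert np.std(r) / np.mean(r) < 0.05

    def test_level_count_matches_range(self):
        t = np.tile(np.linspace(0.0, 50.0, 100), (100, 1))
        amap = synthetic_map(t)
        iso = extract_isochrones(amap, 5.0)
        assert len(iso) == 9  # interior multiples of 5 in (0, 50)

    def test_oversized_spacing_warns(self):
        amap = synthetic_map(np.tile(np.linspace(0, 4.0, 50), (50, 1)))
        with pytest.warns(UserWarning):
            assert extract_isochrones(amap, 100.0) == {}


class TestTwoPointCV:
    def test_arithmetic_on_synthetic_field(self):
        """18.2-pixel separation covered in 10 ms at 0.01 cm pitch:
        18.2 cm/s by plain arithmetic."""
        t = np.tile(np.arange(100) * (10.0 / 18.2), (100, 1))
        amap = synthetic_map(t)
        est = cv_two_point(amap, (50, 10), (50, 28))
        d_cm = 18 * 0.01
        dt_s = 18 * (10.0 / 18.2) / 1000.0
        assert est.cv_cm_s == pytest.approx(d_cm / dt_s)
        assert est.cv_cm_s == pytest.approx(18.2, rel=1e-9)

    def test_equal_activation_times_rejected(self):
        t = np.tile(np.arange(100.0), (100, 1))
        amap = synthetic_map(t)
        with pytest.raises(UndefinedVelocityError):
            cv_two_point(amap, (10, 20), (60, 20))

    def test_misalignment_warns(self):
        t = np.tile(np.arange(100.0), (100, 1)) + np.finfo(float).eps
        t = t + 1e-6 * np.arange(100)[:, None]  # tiny row gradient, times differ
        amap = synthetic_map(t)
        with pytest.warns(UserWarning, match="misaligned"):
            cv_two_point(amap, (10, 20), (80, 21))

    def test_auto_placement_recovers_planar_cv(self, organ):
        gt, tpl = organ
        amap = compute_activation_map(preprocess_movie(simulate_movie(gt, tpl)))
        est = cv_two_point(amap)
        assert est.cv_cm_s == pytest.approx(gt.v_long_cm_s, abs=0.3)
        # sites lie along the propagation direction
        ang = est.direction_deg % 180.0
        assert min(abs(ang - 30.0), 180 - abs(ang - 30.0)) < 15.0


class TestAnisotropyScan:
    def test_isotropic_ar_is_one(self):
        gt = TissueGroundTruth(v_long_cm_s=20.0, stim_site=(50, 50))
        _, tpl = get_preset("organ_explant")
        amap = compute_activation_map(preprocess_movie(simulate_movie(gt, tpl)))
        res = directional_cv_scan(amap, (50, 50))
        assert res.ar == pytest.approx(1.0, abs=0.05)
        assert res.ar >= 1.0

    def test_organ_explant_ar_recovered(self, organ_point_map):
        _, amap = organ_point_map
        res = directional_cv_scan(amap, (50, 50))
        assert res.ar == pytest.approx(2.5, abs=0.1)
        assert res.theta_max_deg == pytest.approx(30.0, abs=5.0)
        assert res.cv_max_cm_s == pytest.approx(18.2, abs=0.5)

    def test_rotation_equivariance(self):
        """Rotating the fiber by 30 degrees rotates theta_max by 30 degrees
        (within one scan step)."""
        _, tpl = get_preset("organ_explant")
        thetas = []
        for fiber in (30.0, 60.0):
            gt, _ = get_preset("organ_explant", fiber_angle_deg=fiber,
                               stim_site=(50, 50))
            amap = compute_activation_map(preprocess_movie(simulate_movie(gt, tpl)))
            thetas.append(directional_cv_scan(amap, (50, 50)).theta_max_deg)
        assert (thetas[1] - thetas[0]) % 180.0 == pytest.approx(30.0, abs=5.0)

    def test_ar_at_least_one_by_construction(self, organ_point_map):
        _, amap = organ_point_map
        for step in (5.0, 15.0):
            res = directional_cv_scan(amap, (50, 50), angle_step_deg=step)
            assert res.ar >= 1.0


class TestCapture:
    def _trace_with_beats(self, beat_times, stim_times, duration=3000.0):
        from cardiomap.containers import VoltageTrace
        from cardiomap.synthgen import get_preset

        _, tpl = get_preset("organ_explant")
        t = np.arange(0.0, duration, 1.0)
        v = np.full_like(t, tpl.rmp_mV)
        tab_t, tab_v = tpl.lookup_table()
        for tb in beat_times:
            v += tpl.apa_mV * np.interp(t - tb, tab_t, tab_v, left=0.0, right=0.0)
        return VoltageTrace(samples=v, sampling_interval_ms=1.0,
                            stim_times_ms=list(stim_times))

    def test_one_to_one(self):
        stims = list(np.arange(100.0, 3000.0, 280.0))
        rec = self._trace_with_beats(stims, stims)
        res = assess_capture([(280.0, rec)])
        row = res.rows[0]
        assert row["captured_1to1"] and row["n_propagated"] == row["n_assessed"]

    def test_two_to_one(self):
        stims = list(np.arange(100.0, 2500.0, 200.0))
        rec = self._trace_with_beats(stims[::2], stims)
        row = assess_capture([(200.0, rec)]).rows[0]
        assert not row["captured_1to1"]
        assert row["n_propagated"] == pytest.approx(row["n_assessed"] / 2, abs=1)

    def test_insufficient_stimuli(self):
        rec = self._trace_with_beats([100.0], [100.0, 600.0, 1100.0])
        with pytest.raises(InsufficientStimuliError):
            assess_capture([(500.0, rec)])

    def test_erp_rule_ordering_over_cycle_lengths(self):
        """With ERP 250 ms, capture is retained at CL >= 300 and lost below."""
        gt, tpl = get_preset("organ_explant", erp_ms=250.0,
                             pacing_cls_ms=[500, 400, 300, 200, 150, 100])
        run = simulate_pacing_run(gt, tpl, n_stimuli=6)
        res = assess_capture(run)
        for row in res.rows:
            assert row["captured_1to1"] == (row["cl_ms"] >= 300)
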