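"""Parameter-recovery benchmarks.

Each function regenerates synthetic recordings from a group preset (whose
ground truth is the published group value), runs the full analysis path on
them, and returns the recovered quantity. They are used both by the test
suite and by ``scripts/acceptance.py``; nothing here reads the expected
values — callers compare against them.
"""

from __future__ import annotations

import numpy as np

from .activation_mapping import (
    compute_activation_map,
    cv_two_point,
    directional_cv_scan,
    preprocess_movie,
)
from .containers import VoltageTrace
from .synthgen import get_preset, simulate_intracellular_trace, simulate_movie
from .trace_features import (
    detect_beats,
    extract_features,
    measure_apd,
    measure_diastolic,
    measure_upstroke,
    normalize_beat,
)

#: movie noise level used in the recovery studies (fraction of APA)
RECOVERY_NOISE_SD = 0.05
#: fiber orientation used for movies (off-axis, on the 5-degree scan grid)
RECOVERY_FIBER_ANGLE = 30.0


def _rng(seed, *key):
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def recover_cv(preset: str, *, n_seeds: int = 20, base_seed: int = 1,
               noise_sd: float = RECOVERY_NOISE_SD) -> dict:
    """Mean auto two-site CV over planar-wave movies (cm/s)."""
    values = []
    for i in range(n_seeds):
        gt, tpl = get_preset(
            preset, fiber_angle_deg=RECOVERY_FIBER_ANGLE, noise_sd=noise_sd, seed=i
        )
        movie = simulate_movie(gt, tpl, rng=_rng(base_seed, i))
        amap = compute_activation_map(preprocess_movie(movie))
        values.append(cv_two_point(amap).cv_cm_s)
    return {"value": float(np.mean(values)), "n": n_seeds, "per_seed": values}


def recover_ar(preset: str, *, n_seeds: int = 20, base_seed: int = 1,
               noise_sd: float = RECOVERY_NOISE_SD,
               angle_step_deg: float = 5.0) -> dict:
    """Mean anisotropy ratio from the directional CV scan around a central
    point stimulus."""
    values = []
    for i in range(n_seeds):
        gt, tpl = get_preset(
            preset, fiber_angle_deg=RECOVERY_FIBER_ANGLE, stim_site=(50, 50),
            noise_sd=noise_sd, seed=i,
        )
        movie = simulate_movie(gt, tpl, rng=_rng(base_seed, i))
        amap = compute_activation_map(preprocess_movie(movie))
        scan = directional_cv_scan(amap, (50, 50), angle_step_deg=angle_step_deg)
        values.append(scan.ar)
    return {"value": float(np.mean(values)), "n": n_seeds, "per_seed": values}


def _single_beat_trace(preset: str, sampling_interval_ms: float) -> VoltageTrace:
    """One noise-free template beat on a grid with a sample at ramp onset."""
    _, tpl = get_preset(preset)
    act = 100.0
    duration = act + tpl.t_end_ms + 100.0
    v = tpl.sample(duration, sampling_interval_ms, activation_ms=act)
    return VoltageTrace(samples=v, sampling_interval_ms=sampling_interval_ms,
                        stim_times_ms=[act])


def measure_template_apd(preset: str, fraction: int,
                         sampling_interval_ms: float) -> dict:
    """APD at ``fraction`` % repolarization on a noise-free preset template."""
    trace = _single_beat_trace(preset, sampling_interval_ms)
    beats, _, _ = detect_beats(trace)
    nb = normalize_beat(trace, beats[0])
    return {"value": float(measure_apd(nb, fraction)), "n": 1}


def measure_template_upstroke(preset: str,
                              sampling_interval_ms: float = 1.0) -> dict:
    """d(%APA)/dt_max on a noise-free preset template (%APA/ms)."""
    trace = _single_beat_trace(preset, sampling_interval_ms)
    beats, _, _ = detect_beats(trace)
    nb = normalize_beat(trace, beats[0])
    return {"value": float(measure_upstroke(nb)), "n": 1}


def recover_rmp(preset: str = "organ_explant") -> dict:
    """RMP from a noise-free quiescent paced trace (5 beats, CL 500 ms)."""
    gt, tpl = get_preset(preset)
    trace = simulate_intracellular_trace(
        gt, tpl, duration_ms=2700, cl_ms=500, n_stimuli=5
    )
    feats = extract_features(trace)
    assert feats.n_beats == 5 and not feats.phase4_flag
    return {"value": float(feats.mdp_or_rmp_mV), "n": feats.n_beats}


def phase4_flag_at(slope_mV_s: float, preset: str = "organ_explant") -> bool:
    """Phase-4 flag on a noise-free spontaneous trace with the given
    generator diastolic slope."""
    gt, tpl = get_preset(preset, diastolic_slope_mV_s=slope_mV_s)
    tau_ms = 0.1 * tpl.apa_mV / slope_mV_s * 1000.0
    duration = 3.0 * (tau_ms + tpl.t_end_ms)
    trace = simulate_intracellular_trace(gt, tpl, duration_ms=duration)
    beats, _, _ = detect_beats(trace)
    return measure_diastolic(trace, beats).phase4_flag


def phase4_boundary(*, lo: float = 2.0, hi: float = 8.0,
                    precision: float = 0.005) -> dict:
    """Locate the diastolic-slope classification boundary by bisection
    (mV/s; the flag must be true at and above the boundary)."""
    assert not phase4_flag_at(lo) and phase4_flag_at(hi)
    n = 0
    while hi - lo > precision:
        mid = 0.5 * (lo + hi)
        if phase4_flag_at(mid):
            hi = mid
        else:
            lo = mid
        n += 1
    return {"value": round(0.5 * (lo + hi), 2), "n": n}
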