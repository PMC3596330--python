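"""Synthetic excitable-tissue recordings with known ground truth.

The generator produces the two kinds of data the analysis consumes —
intracellular microelectrode traces and optical-mapping fluorescence movies —
from an action-potential template (:mod:`cardiomap.template`) and a
:class:`TissueGroundTruth` that fixes the propagation physics. Everything the
analysis estimates (RMP/MDP, diastolic slope, APD anchors, upstroke velocity,
conduction velocity, anisotropy ratio, capture) is a generator *input*, so
each downstream stage is testable by parameter recovery.

Propagation model
-----------------
Activation times are the anisotropic-eikonal solution for constant
velocities on a uniform sheet:

* planar wavefront travelling along the fiber axis:
  ``t(x) = (x . u) / v(theta)`` with the elliptical directional speed
  ``v(theta) = [ (cos d / v_L)^2 + (sin d / v_T)^2 ]^(-1/2)``,
  ``d = theta - fiber_angle`` and ``v_T = v_L / AR``;
* point stimulus: ``t = sqrt((xi / v_L)^2 + (eta / v_T)^2)`` with
  ``(xi, eta)`` coordinates along/across the fiber axis.

Each pixel's fluorescence is the template time-shifted by its activation
time, scaled to arbitrary units with a per-pixel gain jitter (so the
analysis is forced to normalize per pixel), integrated over the camera
frame interval, and corrupted by additive Gaussian noise per pixel per
frame. No ionic model, wavefront curvature effect or photophysics is
simulated.

Pacing capture is reduced to a refractory rule: a stimulus elicits a beat
iff the time since the last elicited beat is at least ``erp_ms``
(default APD90 + 20 ms), which reproduces the qualitative loss of 1:1
capture at short cycle lengths without ionic modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import INTRACELLULAR, OpticalMovie, VoltageTrace
from .errors import DurationError, ParameterError
from .template import APTemplate, make_template

PLANAR = "planar"

#: internal over-sampled resolution for movie synthesis (ms); decimation to
#: the camera interval by frame averaging models camera integration
INTERNAL_DT_MS = 0.1

#: spontaneous takeoff threshold, as a fraction of APA above the MDP
TAKEOFF_FRACTION = 0.1


@dataclass
class TissueGroundTruth:
    """Ground-truth tissue parameters for one synthetic preparation.

    ``stim_site`` is either the string ``"planar"`` (plane wave entering
    along the fiber axis, as with line stimulation at the tissue edge) or a
    ``(row, col)`` pixel for point stimulation.
    """

    v_long_cm_s: float
    anisotropy_ratio: float = 1.0
    fiber_angle_deg: float = 0.0
    stim_site: object = PLANAR
    grid_shape: tuple = (100, 100)
    pixel_pitch_cm: float = 0.01
    sampling_interval_ms: float = 1.0
    erp_ms: float = 250.0
    diastolic_slope_mV_s: float = 0.0
    pacing_cls_ms: list = field(default_factory=lambda: [500, 400, 300, 200, 150, 100])
    noise_sd: float = 0.0  # additive Gaussian SD as a fraction of APA
    seed: int = 0

    def __post_init__(self):
        if self.v_long_cm_s <= 0:
            raise ParameterError("v_long_cm_s must be > 0")
        if self.anisotropy_ratio < 1:
            raise ParameterError("anisotropy_ratio must be >= 1")
        if self.sampling_interval_ms not in (1, 2):
            raise ParameterError("sampling_interval_ms must be 1 or 2 ms")
        if self.pixel_pitch_cm <= 0:
            raise ParameterError("pixel_pitch_cm must be > 0")
        if self.erp_ms <= 0:
            raise ParameterError("erp_ms must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.stim_site != PLANAR:
            r, c = self.stim_site
            self.stim_site = (int(r), int(c))

    @property
    def v_trans_cm_s(self) -> float:
        """Transverse conduction velocity v_L / AR."""
        return self.v_long_cm_s / self.anisotropy_ratio


# ---------------------------------------------------------------------------
# group presets: published group-level values used as ground truth
# ---------------------------------------------------------------------------

GROUP_PRESETS = {
    # neonatal rat ventricular organ explant cultures (6-8 days in vitro)
    "organ_explant": dict(
        rmp_mV=-83.9,
        apa_mV=100.0,
        upstroke_velocity_pct_per_ms=46.8,
        apd_anchors_ms={20: 33.6, 50: 65.8, 70: 88.8, 90: 116.8},
        v_long_cm_s=18.2,
        anisotropy_ratio=2.5,
        sampling_interval_ms=1.0,
        spontaneous_cl_ms=468.0,
        spontaneous_fraction=0.20,
    ),
    # freshly isolated neonatal rat ventricular tissue
    "fresh_tissue": dict(
        rmp_mV=-80.5,
        apa_mV=100.0,
        upstroke_velocity_pct_per_ms=50.4,
        apd_anchors_ms={20: 35.0, 50: 61.5, 70: 79.1, 90: 107.5},
        v_long_cm_s=18.6,
        anisotropy_ratio=2.1,
        sampling_interval_ms=1.0,
        spontaneous_cl_ms=677.0,
        spontaneous_fraction=0.17,
    ),
    # confluent neonatal rat ventricular cardiomyocyte monolayers; imaged at
    # 0.5 kHz, near-isotropic conduction, long plateau.  APD20/APD50 and the
    # upstroke duration are not published for this group; the values here are
    # plausible plateau-shaped choices (see docs/methods.md).
    "monolayer": dict(
        rmp_mV=-60.9,
        apa_mV=100.0,
        t_upstroke_ms=4.0,
        apd_anchors_ms={20: 40.0, 50: 95.0, 70: 134.0, 90: 230.8},
        v_long_cm_s=24.3,
        anisotropy_ratio=1.2,
        sampling_interval_ms=2.0,
        spontaneous_cl_ms=582.0,
        spontaneous_fraction=0.82,
    ),
}


def get_preset(name: str, *, seed: int = 0, **overrides) -> tuple[TissueGroundTruth, APTemplate]:
    """Build ``(TissueGroundTruth, APTemplate)`` for a named group preset.

    ``overrides`` may contain any :class:`TissueGroundTruth` field (e.g.
    ``noise_sd=0.05``, ``stim_site=(50, 50)``, ``fiber_angle_deg=30``).
    The default effective refractory period is APD90 + 20 ms.
    """
    if name not in GROUP_PRESETS:
        raise ParameterError(
            f"unknown preset {name!r}; choose from {sorted(GROUP_PRESETS)}"
        )
    p = GROUP_PRESETS[name]
    tpl_kwargs = dict(
        rmp_mV=p["rmp_mV"], apa_mV=p["apa_mV"], apd_anchors_ms=p["apd_anchors_ms"]
    )
    if "t_upstroke_ms" in p:
        tpl_kwargs["t_upstroke_ms"] = p["t_upstroke_ms"]
    else:
        tpl_kwargs["upstroke_velocity_pct_per_ms"] = p["upstroke_velocity_pct_per_ms"]
    template = make_template(**tpl_kwargs)
    gt_kwargs = dict(
        v_long_cm_s=p["v_long_cm_s"],
        anisotropy_ratio=p["anisotropy_ratio"],
        sampling_interval_ms=p["sampling_interval_ms"],
        erp_ms=p["apd_anchors_ms"][90] + 20.0,
        seed=seed,
    )
    gt_kwargs.update(overrides)
    return TissueGroundTruth(**gt_kwargs), template


# ---------------------------------------------------------------------------
# eikonal ground truth
# ---------------------------------------------------------------------------

def directional_speed(gt: TissueGroundTruth, angle_deg) -> np.ndarray:
    """Elliptical directional speed v(theta) in cm/s."""
    d = np.deg2rad(np.asarray(angle_deg, dtype=float) - gt.fiber_angle_deg)
    s = np.sqrt((np.cos(d) / gt.v_long_cm_s) ** 2 + (np.sin(d) / gt.v_trans_cm_s) ** 2)
    return 1.0 / s


def activation_field(gt: TissueGroundTruth) -> np.ndarray:
    """Ground-truth activation-time field (ms), zero at the first-activated
    pixel, on the ``grid_shape`` grid."""
    rows, cols = gt.grid_shape
    y = np.arange(rows)[:, None] * gt.pixel_pitch_cm
    x = np.arange(cols)[None, :] * gt.pixel_pitch_cm
    phi = np.deg2rad(gt.fiber_angle_deg)
    if gt.stim_site == PLANAR:
        proj = x * np.cos(phi) + y * np.sin(phi)
        t_s = (proj - proj.min()) / directional_speed(gt, gt.fiber_angle_deg)
        t_s = np.broadcast_to(t_s, (rows, cols)).copy()
    else:
        r0, c0 = gt.stim_site
        dx = x - c0 * gt.pixel_pitch_cm
        dy = y - r0 * gt.pixel_pitch_cm
        xi = dx * np.cos(phi) + dy * np.sin(phi)
        eta = -dx * np.sin(phi) + dy * np.cos(phi)
        t_s = np.sqrt((xi / gt.v_long_cm_s) ** 2 + (eta / gt.v_trans_cm_s) ** 2)
    return t_s * 1000.0


def captured_stimuli(stim_times_ms, erp_ms: float) -> np.ndarray:
    """Apply the refractory capture rule; returns a boolean mask per stimulus
    (an uncaptured stimulus does not reset the refractory clock)."""
    captured = []
    last = -np.inf
    for t in stim_times_ms:
        ok = (t - last) >= erp_ms
        captured.append(ok)
        if ok:
            last = t
    return np.asarray(captured, dtype=bool)


# ---------------------------------------------------------------------------
# intracellular traces
# ---------------------------------------------------------------------------

def simulate_intracellular_trace(
    gt: TissueGroundTruth,
    template: APTemplate,
    duration_ms: float,
    *,
    cl_ms: float | None = None,
    n_stimuli: int | None = None,
    stim_start_ms: float = 100.0,
    sampling_interval_ms: float = 1.0,
    rng: np.random.Generator | None = None,
) -> VoltageTrace:
    """Simulate a single-site microelectrode recording in mV.

    Paced mode (``cl_ms`` given): stimuli at ``stim_start_ms + k * cl_ms``;
    each stimulus that passes the refractory rule emits one template beat at
    zero latency. Spontaneous mode (no stimuli, ``gt.diastolic_slope_mV_s``
    > 0): diastole ramps linearly from the MDP until it reaches
    MDP + 0.1 APA, then a beat fires from the matching point of the template
    upstroke (so the waveform is continuous). With neither, the trace is
    quiescent at the RMP. Additive Gaussian noise of SD
    ``gt.noise_sd * APA`` mV.
    """
    if duration_ms <= 0:
        raise ParameterError("duration_ms must be > 0")
    if rng is None:
        rng = np.random.default_rng(gt.seed)
    h = sampling_interval_ms
    t = np.arange(0.0, duration_ms + 0.5 * h, h)
    tab_t, tab_v = template.lookup_table()

    stim_times: list[float] = []
    if cl_ms is not None or n_stimuli is not None:
        if cl_ms is None:
            raise ParameterError("n_stimuli requires cl_ms")
        if gt.diastolic_slope_mV_s > 0:
            raise ParameterError("paced simulation requires diastolic_slope_mV_s == 0")
        if duration_ms < cl_ms:
            raise DurationError("duration must cover at least one cycle length")
        if n_stimuli is None:
            n_stimuli = int((duration_ms - stim_start_ms) // cl_ms) + 1
        stim_times = [stim_start_ms + k * cl_ms for k in range(n_stimuli)]
        if stim_times and stim_times[-1] > duration_ms:
            raise DurationError("stimuli extend beyond the record")
        cap = captured_stimuli(stim_times, gt.erp_ms)
        v = np.full_like(t, template.rmp_mV)
        for t_b in np.asarray(stim_times)[cap]:
            v += template.apa_mV * np.interp(t - t_b, tab_t, tab_v, left=0.0, right=0.0)
    elif gt.diastolic_slope_mV_s > 0:
        slope_mV_ms = gt.diastolic_slope_mV_s / 1000.0
        takeoff_mV = TAKEOFF_FRACTION * template.apa_mV
        tau = takeoff_mV / slope_mV_ms  # ramp duration, ms
        beat_ms = template.t_end_ms - TAKEOFF_FRACTION * template.t_upstroke_ms
        period = tau + beat_ms
        u = np.mod(t, period)
        ramp = u < tau
        v = np.empty_like(t)
        v[ramp] = template.rmp_mV + slope_mV_ms * u[ramp]
        tb = u[~ramp] - tau + TAKEOFF_FRACTION * template.t_upstroke_ms
        v[~ramp] = template.rmp_mV + template.apa_mV * np.interp(
            tb, tab_t, tab_v, left=0.0, right=0.0
        )
    else:
        v = np.full_like(t, template.rmp_mV)

    if gt.noise_sd > 0:
        v = v + rng.normal(0.0, gt.noise_sd * template.apa_mV, size=v.shape)
    return VoltageTrace(
        samples=v,
        sampling_interval_ms=h,
        stim_times_ms=stim_times,
        modality=INTRACELLULAR,
    )


# ---------------------------------------------------------------------------
# optical movies
# ---------------------------------------------------------------------------

def simulate_movie(
    gt: TissueGroundTruth,
    template: APTemplate,
    *,
    n_beats: int = 1,
    cl_ms: float | None = None,
    duration_ms: float | None = None,
    stim_start_ms: float = 10.0,
    baseline_au: float = 1000.0,
    gain_au: float = 500.0,
    gain_jitter: float = 0.1,
    rng: np.random.Generator | None = None,
) -> OpticalMovie:
    """Simulate an optical-mapping fluorescence movie in arbitrary units.

    The waveform is synthesized on a 0.1 ms internal grid and decimated to
    ``gt.sampling_interval_ms`` by frame averaging (camera integration).
    Per-pixel gain jitter of +/-``gain_jitter`` (uniform) and additive
    Gaussian noise of SD ``gt.noise_sd`` x (pixel amplitude) are applied.
    The returned movie carries the ground-truth activation field in
    ``movie.ground_truth["activation_field_ms"]`` for oracle tests.
    """
    if rng is None:
        rng = np.random.default_rng(gt.seed)
    field_ms = activation_field(gt)
    t_traverse = float(field_ms.max())

    if cl_ms is None:
        cl_ms = gt.pacing_cls_ms[0] if gt.pacing_cls_ms else 500.0
    stim_times = [stim_start_ms + k * cl_ms for k in range(n_beats)]
    cap = captured_stimuli(stim_times, gt.erp_ms)
    beat_times = np.asarray(stim_times)[cap]

    needed = stim_times[-1] + t_traverse + template.t_end_ms + 10.0
    if duration_ms is None:
        duration_ms = needed
    elif duration_ms < stim_times[0] + t_traverse + template.t_upstroke_ms:
        raise DurationError(
            f"record of {duration_ms} ms too short for the wave to traverse "
            f"the grid ({t_traverse:.1f} ms after the stimulus)"
        )

    h = gt.sampling_interval_ms
    decim = int(round(h / INTERNAL_DT_MS))
    n_frames = int(duration_ms // h)
    rows, cols = gt.grid_shape
    tab_t, tab_v = template.lookup_table()

    gains = gain_au * (1.0 + rng.uniform(-gain_jitter, gain_jitter, size=(rows, cols)))
    f0 = baseline_au * (1.0 + rng.uniform(-0.05, 0.05, size=(rows, cols)))

    frames = np.empty((n_frames, rows, cols), dtype=float)
    flat_field = field_ms.ravel()
    # cap the (internal samples x pixels) work matrix at ~8e6 elements
    chunk = max(1, int(8e6 // (flat_field.size * decim)))  # frames per block
    t_int = (np.arange(n_frames * decim) + 0.5) * INTERNAL_DT_MS
    for start in range(0, n_frames, chunk):
        stop = min(start + chunk, n_frames)
        tt = t_int[start * decim : stop * decim]
        # (T_int, P) matrix of normalized amplitudes, summed over beats
        rel = tt[:, None] - flat_field[None, :]
        s = np.zeros_like(rel)
        for t_b in beat_times:
            s += np.interp(rel - t_b, tab_t, tab_v, left=0.0, right=0.0)
        s = s.reshape(stop - start, decim, rows, cols).mean(axis=1)
        frames[start:stop] = f0 + gains * s
    if gt.noise_sd > 0:
        frames += rng.normal(0.0, gt.noise_sd, size=frames.shape) * gains

    return OpticalMovie(
        frames=frames,
        sampling_interval_ms=h,
        pixel_pitch_cm=gt.pixel_pitch_cm,
        stim_times_ms=list(stim_times),
        ground_truth={
            "activation_field_ms": field_ms,
            "v_long_cm_s": gt.v_long_cm_s,
            "anisotropy_ratio": gt.anisotropy_ratio,
            "fiber_angle_deg": gt.fiber_angle_deg,
            "stim_site": gt.stim_site,
            "beat_times_ms": beat_times.tolist(),
            "seed": gt.seed,
        },
    )


def simulate_pacing_run(
    gt: TissueGroundTruth,
    template: APTemplate,
    *,
    kind: str = "trace",
    n_stimuli: int = 8,
    rng: np.random.Generator | None = None,
) -> list:
    """One recording per pacing cycle length in ``gt.pacing_cls_ms``.

    ``kind`` selects intracellular traces (cheap; default) or optical movies.
    Capture follows the refractory rule, so short cycle lengths show 2:1 or
    worse patterns downstream.
    """
    if not gt.pacing_cls_ms:
        raise ParameterError("pacing_cls_ms is empty")
    if rng is None:
        rng = np.random.default_rng(gt.seed)
    out = []
    for cl in gt.pacing_cls_ms:
        if kind == "trace":
            duration = 100.0 + n_stimuli * cl + template.t_end_ms + 50.0
            rec = simulate_intracellular_trace(
                gt, template, duration, cl_ms=cl, n_stimuli=n_stimuli, rng=rng
            )
        elif kind == "movie":
            rec = simulate_movie(gt, template, n_beats=n_stimuli, cl_ms=cl, rng=rng)
        else:
            raise ParameterError("kind must be 'trace' or 'movie'")
        out.append((cl, rec))
    return out
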