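"""Per-trace, per-beat action-potential measurements.

Measurements implemented here mirror the classic microelectrode / optical
workflow for cultured cardiac tissue:

* beat detection from the (optionally smoothed) first difference of the
  voltage, with a refractory interval between accepted activations;
* MDP/RMP and phase-4 diastolic depolarization, flagged when the diastolic
  slope over the 50 ms window starting at the maximal diastolic potential is
  at least 5 mV/s;
* per-beat normalization (baseline 0, peak 100) so that amplitude-dependent
  quantities are invariant to optical gain;
* APD at 20/50/70/90 % repolarization, measured from the activation time
  (maximal upstroke velocity) to the linearly interpolated level crossing;
* maximal normalized upstroke velocity d(%APA)/dt_max, defined only at
  sampling intervals of 1 ms or less.

Activation times are refined to sub-sample precision: a parabolic fit
through the three derivative samples around the discrete maximum, or the
center of the plateau when neighbouring derivative samples tie (a linear
upstroke sampled finely produces such plateaus).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .containers import INTRACELLULAR, VoltageTrace
from .errors import (
    DegenerateBeatError,
    DiastoleError,
    NotMeasurableError,
    ParameterError,
    UnitError,
    UnmeasurableAPDError,
)

PHASE4_THRESHOLD_MV_S = 5.0
PHASE4_WINDOW_MS = 50.0
DEFAULT_REFRACTORY_MS = 50.0
STIM_LATENCY_MS = 20.0  # a beat within this latency of a stimulus is paced

APD_FRACTIONS = (20, 50, 70, 90)


@dataclass
class Beat:
    """One detected beat: half-open sample window, activation and peak."""

    start: int
    end: int
    act_idx: int
    t_act_ms: float
    peak_idx: int
    baseline: float

    def __post_init__(self):
        if not self.start <= self.act_idx <= self.peak_idx < self.end:
            raise ParameterError("beat indices must satisfy start <= act <= peak < end")


@dataclass
class NormalizedBeat:
    """A beat window mapped to the 0–100 %APA scale."""

    samples: np.ndarray
    sampling_interval_ms: float
    t_act_ms: float        # absolute time on the parent trace axis
    t0_ms: float           # absolute time of samples[0]
    peak_idx: int          # index into samples
    act_idx: int           # index into samples

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.samples.size) * self.sampling_interval_ms


@dataclass
class DiastolicResult:
    mdp_or_rmp_mV: float
    phase4_flag: bool
    phase4_slope_mV_s: float
    interval_slopes_mV_s: list = field(default_factory=list)
    mdps_mV: list = field(default_factory=list)


@dataclass
class APFeatures:
    """Aggregated per-trace measurement record."""

    is_spontaneous: bool
    n_beats: int
    cl_ms: float | None
    mdp_or_rmp_mV: float | None
    phase4_flag: bool | None
    phase4_slope_mV_s: float | None
    apd_ms: dict                 # fraction -> across-beat mean (ms)
    apd_per_beat: dict           # fraction -> list per beat (None if unmeasurable)
    dapadt_max_pct_per_ms: float | None
    group: str | None = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["apd_ms"] = {int(k): v for k, v in self.apd_ms.items()}
        d["apd_per_beat"] = {int(k): v for k, v in self.apd_per_beat.items()}
        return d


# ---------------------------------------------------------------------------
# activation refinement
# ---------------------------------------------------------------------------

def _refine_peak(d: np.ndarray, i: int, rtol: float = 1e-9) -> float:
    """Sub-sample position of the derivative maximum at discrete index ``i``.

    Returns a fractional index. Ties with neighbours (within ``rtol``)
    are resolved to the plateau center; otherwise a parabola through
    ``d[i-1], d[i], d[i+1]`` is used, clipped to half a sample.
    """
    tol = rtol * abs(d[i]) + 1e-12
    lo = i
    while lo > 0 and d[lo - 1] >= d[i] - tol:
        lo -= 1
    hi = i
    while hi < d.size - 1 and d[hi + 1] >= d[i] - tol:
        hi += 1
    if hi > lo:
        return 0.5 * (lo + hi)
    if 0 < i < d.size - 1:
        dm, d0, dp = d[i - 1], d[i], d[i + 1]
        den = dm - 2.0 * d0 + dp
        if den < -tol:
            delta = 0.5 * (dm - dp) / den
            return i + float(np.clip(delta, -0.5, 0.5))
    return float(i)


def _derivative(v: np.ndarray, h: float, smooth: bool) -> np.ndarray:
    if smooth and v.size >= 5:
        v = savgol_filter(v, window_length=5, polyorder=2)
    return np.diff(v) / h


# ---------------------------------------------------------------------------
# beat detection
# ---------------------------------------------------------------------------

def detect_beats(
    trace: VoltageTrace,
    derivative_threshold: float = 0.1,
    *,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
    smooth: bool = False,
) -> tuple[list[Beat], float | None, bool]:
    """Detect beats as suprathreshold maxima of the first difference.

    ``derivative_threshold`` is a fraction of the global maximal derivative.
    Returns ``(beats, cl_ms, is_spontaneous)``; ``cl_ms`` is the mean
    inter-activation interval (None with fewer than 2 beats). A beat with no
    stimulus in the preceding 20 ms marks the trace spontaneous; with no
    stimulus channel at all, any beat does.
    """
    if trace.n_samples < 3:
        raise ParameterError("trace too short for beat detection")
    v = trace.samples
    h = trace.sampling_interval_ms
    d = _derivative(v, h, smooth)
    dmax = d.max(initial=-np.inf)
    if not np.isfinite(dmax) or dmax <= 0 or np.ptp(v) == 0:
        return [], None, False

    thr = derivative_threshold * dmax
    candidates = np.flatnonzero(d >= thr)
    # greedy refractory pruning, strongest (earliest on ties) first
    order = candidates[np.argsort(-d[candidates], kind="stable")]
    min_gap = max(1, int(round(refractory_ms / h)))
    accepted: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_gap for j in accepted):
            accepted.append(int(i))
    accepted.sort()

    t_acts = np.array([(_refine_peak(d, i) + 0.5) * h for i in accepted])
    act_idx = np.minimum(np.floor(t_acts / h).astype(int), v.size - 1)

    beats: list[Beat] = []
    bounds = [0] + [int((a + b) // 2) for a, b in zip(act_idx[:-1], act_idx[1:])] + [v.size]
    base_w = max(1, int(round(20.0 / h)))
    for k, ai in enumerate(act_idx):
        start, end = bounds[k], bounds[k + 1]
        peak = ai + int(np.argmax(v[ai:end]))
        b0 = max(start, ai - base_w)
        baseline = float(np.median(v[b0:ai])) if ai > b0 else float(v[ai])
        beats.append(
            Beat(start=start, end=end, act_idx=int(ai), t_act_ms=float(t_acts[k]),
                 peak_idx=int(peak), baseline=baseline)
        )

    cl_ms = float(np.mean(np.diff(t_acts))) if len(beats) >= 2 else None
    if trace.stim_times_ms:
        stims = np.asarray(trace.stim_times_ms, dtype=float)
        spont = any(
            not np.any((stims >= b.t_act_ms - STIM_LATENCY_MS) & (stims <= b.t_act_ms))
            for b in beats
        )
    else:
        spont = len(beats) > 0
    return beats, cl_ms, spont


# ---------------------------------------------------------------------------
# diastolic measurements
# ---------------------------------------------------------------------------

def measure_diastolic(
    trace: VoltageTrace,
    beats: list[Beat],
    *,
    method: str = "regression",
    window_ms: float = PHASE4_WINDOW_MS,
) -> DiastolicResult:
    """MDP/RMP and the phase-4 depolarization flag.

    For each diastolic interval the MDP is its minimum voltage and the
    diastolic slope is fit over the ``window_ms`` interval starting there
    (least squares by default, first-to-last endpoint difference with
    ``method="endpoint"``). The preparation is flagged as showing phase-4
    depolarization when the median slope is at least 5 mV/s; the reported
    potential is then the mean MDP, otherwise the RMP (mean voltage over the
    final 50 ms before each upstroke).
    """
    if trace.modality != INTRACELLULAR:
        raise UnitError("diastolic potentials require calibrated intracellular mV data")
    if method not in ("regression", "endpoint"):
        raise ParameterError("method must be 'regression' or 'endpoint'")
    v = trace.samples
    h = trace.sampling_interval_ms
    w = int(round(window_ms / h))

    if beats:
        intervals = [(0, beats[0].act_idx)]
        intervals += [(beats[k].peak_idx, beats[k + 1].act_idx) for k in range(len(beats) - 1)]
        intervals += [(beats[-1].peak_idx, v.size)]
    else:
        intervals = [(0, v.size)]

    slopes, mdps = [], []
    for a, b in intervals:
        if b - a < 2:
            continue
        seg = v[a:b]
        i_mdp = a + int(np.argmin(seg))
        if i_mdp + w >= b:
            warnings.warn(
                f"diastolic interval [{a}, {b}) shorter than {window_ms} ms "
                "after the MDP; skipped",
                stacklevel=2,
            )
            continue
        y = v[i_mdp : i_mdp + w + 1]
        t_s = np.arange(y.size) * h / 1000.0
        if method == "regression":
            slope = float(np.polyfit(t_s, y, 1)[0])
        else:
            slope = float((y[-1] - y[0]) / t_s[-1])
        slopes.append(slope)
        mdps.append(float(v[i_mdp]))

    if not slopes:
        raise DiastoleError(f"no diastolic interval of >= {window_ms} ms found")
    med_slope = float(np.median(slopes))
    # inclusive threshold; the epsilon keeps an exactly-5 mV/s ramp on the
    # positive side of the float round-off in the least-squares fit
    flag = med_slope >= PHASE4_THRESHOLD_MV_S - 1e-9

    if flag:
        potential = float(np.mean(mdps))
    elif beats:
        pre = []
        for b in beats:
            a0 = max(b.start, b.act_idx - w)
            if b.act_idx > a0:
                pre.append(float(np.mean(v[a0 : b.act_idx])))
        potential = float(np.mean(pre)) if pre else float(np.mean(mdps))
    else:
        potential = float(np.mean(v))
    return DiastolicResult(
        mdp_or_rmp_mV=potential,
        phase4_flag=flag,
        phase4_slope_mV_s=med_slope,
        interval_slopes_mV_s=slopes,
        mdps_mV=mdps,
    )


# ---------------------------------------------------------------------------
# normalization and per-beat metrics
# ---------------------------------------------------------------------------

def normalize_beat(
    trace: VoltageTrace,
    beat: Beat,
    *,
    baseline_window_ms: float = 20.0,
    min_snr: float = 5.0,
) -> NormalizedBeat:
    """Affine-map one beat to baseline 0 / peak 100 (%APA).

    The baseline is the median of the ``baseline_window_ms`` before the
    upstroke; a beat whose amplitude is below ``min_snr`` times the baseline
    noise SD raises :class:`DegenerateBeatError`. Idempotent on beats that
    are already normalized.
    """
    v = trace.samples
    h = trace.sampling_interval_ms
    w = max(1, int(round(baseline_window_ms / h)))
    b0 = max(beat.start, beat.act_idx - w)
    pre = v[b0 : beat.act_idx] if beat.act_idx > b0 else v[beat.act_idx : beat.act_idx + 1]
    baseline = float(np.median(pre))
    noise_sd = float(np.std(pre))
    amplitude = float(v[beat.peak_idx] - baseline)
    if amplitude <= 0 or (noise_sd > 0 and amplitude < min_snr * noise_sd):
        raise DegenerateBeatError(
            f"beat amplitude {amplitude:.3g} below noise floor ({noise_sd:.3g} SD)"
        )
    window = v[beat.start : beat.end]
    samples = (window - baseline) / amplitude * 100.0
    return NormalizedBeat(
        samples=samples,
        sampling_interval_ms=h,
        t_act_ms=beat.t_act_ms,
        t0_ms=beat.start * h,
        peak_idx=beat.peak_idx - beat.start,
        act_idx=beat.act_idx - beat.start,
    )


def measure_apd(nbeat: NormalizedBeat, fraction: int) -> float:
    """APD at ``fraction`` % repolarization (ms).

    Time from the activation reference to the first downward crossing of
    the level ``100 - fraction``, linearly interpolated between the
    bracketing samples. Raises :class:`UnmeasurableAPDError` if the level is
    never crossed within the beat window.
    """
    if not 0 < fraction < 100:
        raise ParameterError("fraction must be in (0, 100)")
    level = 100.0 - fraction
    v = nbeat.samples
    h = nbeat.sampling_interval_ms
    for i in range(nbeat.peak_idx, v.size - 1):
        if v[i] >= level > v[i + 1]:
            frac = (v[i] - level) / (v[i] - v[i + 1])
            t_cross = nbeat.t0_ms + (i + frac) * h
            return float(t_cross - nbeat.t_act_ms)
    raise UnmeasurableAPDError(
        f"level {level:.0f} %APA never crossed within the beat window"
    )


def measure_upstroke(nbeat: NormalizedBeat) -> float:
    """Maximal d(%APA)/dt (%APA per ms).

    Maximum forward difference of the normalized beat divided by the
    sampling interval. Undefined (raises :class:`NotMeasurableError`) at
    sampling intervals above 1 ms, mirroring the acquisition-rate limit of
    0.5 kHz recordings.
    """
    h = nbeat.sampling_interval_ms
    if h > 1.0 + 1e-9:
        raise NotMeasurableError(
            f"d(%APA)/dt_max is not measurable at {h} ms sampling (needs <= 1 ms)"
        )
    return float(np.max(np.diff(nbeat.samples)) / h)


# ---------------------------------------------------------------------------
# trace-level aggregation
# ---------------------------------------------------------------------------

def extract_features(
    trace: VoltageTrace,
    *,
    derivative_threshold: float = 0.1,
    smooth: bool = False,
    group: str | None = None,
) -> APFeatures:
    """Full per-trace measurement record: beats, diastole, APDs, upstroke.

    Per-beat APDs that are unmeasurable are reported as ``None`` in
    ``apd_per_beat`` and excluded from the across-beat mean; the diastolic
    block is ``None`` for optical (uncalibrated) traces; the upstroke is
    ``None`` above 1 ms sampling.
    """
    beats, cl_ms, spont = detect_beats(
        trace, derivative_threshold=derivative_threshold, smooth=smooth
    )

    mdp = flag = slope = None
    if trace.modality == INTRACELLULAR:
        try:
            dia = measure_diastolic(trace, beats)
            mdp, flag, slope = dia.mdp_or_rmp_mV, dia.phase4_flag, dia.phase4_slope_mV_s
        except DiastoleError:
            pass

    apd_per_beat: dict[int, list] = {f: [] for f in APD_FRACTIONS}
    upstrokes: list[float] = []
    for beat in beats:
        try:
            nb = normalize_beat(trace, beat)
        except DegenerateBeatError:
            for f in APD_FRACTIONS:
                apd_per_beat[f].append(None)
            continue
        for f in APD_FRACTIONS:
            try:
                apd_per_beat[f].append(measure_apd(nb, f))
            except UnmeasurableAPDError:
                apd_per_beat[f].append(None)
        try:
            upstrokes.append(measure_upstroke(nb))
        except NotMeasurableError:
            pass

    apd_ms = {
        f: (float(np.mean([x for x in vals if x is not None]))
            if any(x is not None for x in vals) else None)
        for f, vals in apd_per_beat.items()
    }
    return APFeatures(
        is_spontaneous=spont,
        n_beats=len(beats),
        cl_ms=cl_ms,
        mdp_or_rmp_mV=mdp,
        phase4_flag=flag,
        phase4_slope_mV_s=slope,
        apd_ms=apd_ms,
        apd_per_beat=apd_per_beat,
        dapadt_max_pct_per_ms=float(np.mean(upstrokes)) if upstrokes else None,
        group=group,
    )
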