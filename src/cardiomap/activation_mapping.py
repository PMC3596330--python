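"""Movie-level analysis: activation maps, isochrones, conduction velocity,
anisotropy and pacing capture.

The workflow mirrors standard optical-mapping practice:

1. :func:`preprocess_movie` masks pixels without signal and normalizes each
   surviving pixel to the 0–100 %APA scale;
2. :func:`compute_activation_map` assigns each pixel the time of maximal
   temporal derivative (sub-sample refined) within a beat window;
3. conduction velocity is a two-site measurement along the propagation
   direction (:func:`cv_two_point`), and the anisotropy ratio is the maximal
   directional CV around a point stimulus divided by the CV perpendicular to
   it (:func:`directional_cv_scan`);
4. :func:`extract_isochrones` produces equal-activation-time contours;
5. :func:`assess_capture` checks 1:1 stimulus-to-activation capture per
   pacing cycle length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .containers import OpticalMovie, VoltageTrace
from .errors import (
    EmptyMaskError,
    InsufficientStimuliError,
    MapError,
    ParameterError,
    ScanError,
    UndefinedVelocityError,
)
from .trace_features import detect_beats

CAPTURE_LATENCY_MS = 50.0
CAPTURE_SKIP_STIMULI = 2  # rate-adaptation transient


@dataclass
class PreprocessedMovie:
    """Masked, per-pixel 0–100-normalized movie."""

    frames: np.ndarray  # %APA units, NaN outside mask
    mask: np.ndarray
    sampling_interval_ms: float
    pixel_pitch_cm: float
    stim_times_ms: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ActivationMap:
    """Per-pixel activation times (ms, relative to ``stim_ref_ms``)."""

    t_act_ms: np.ndarray  # NaN where undefined
    mask: np.ndarray      # pixels with a defined activation time
    gradient_deg: np.ndarray
    stim_ref_ms: float
    sampling_interval_ms: float
    pixel_pitch_cm: float

    @property
    def defined_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class CVEstimate:
    cv_cm_s: float
    site_a: tuple
    site_b: tuple
    direction_deg: float
    n_sites: int = 2


@dataclass
class AnisotropyResult:
    cv_max_cm_s: float
    cv_perp_cm_s: float
    ar: float
    theta_max_deg: float
    angles_deg: np.ndarray = None
    cv_profile_cm_s: np.ndarray = None


@dataclass
class CaptureResult:
    """Per-cycle-length capture assessment rows."""

    rows: list  # of dicts: cl_ms, n_stimuli, n_assessed, n_propagated, captured_1to1

    def captured_at(self, cl_ms: float) -> bool:
        for r in self.rows:
            if r["cl_ms"] == cl_ms:
                return r["captured_1to1"]
        raise KeyError(cl_ms)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_movie(
    movie: OpticalMovie,
    *,
    min_snr: float = 5.0,
    min_amplitude_fraction: float = 0.05,
    spatial_median: bool = False,
) -> PreprocessedMovie:
    """Mask silent pixels and normalize each pixel to 0–100 %APA.

    A pixel is kept when its beat amplitude exceeds ``min_snr`` times its
    temporal noise SD (robustly estimated from first differences) and
    ``min_amplitude_fraction`` of the in-mask median amplitude. The baseline
    is the pre-stimulus median (10th percentile when no stimulus precedes
    the record), the peak the frame maximum. An optional 3x3 spatial median
    filter is applied frame-wise after normalization.
    """
    if movie.n_frames < 2:
        raise ParameterError("movie needs at least 2 frames")
    F = movie.frames
    h = movie.sampling_interval_ms
    first_stim = min(movie.stim_times_ms) if movie.stim_times_ms else None
    n_base = int(first_stim // h) if first_stim is not None else 0
    if n_base >= 3:
        baseline = np.median(F[:n_base], axis=0)
    else:
        baseline = np.percentile(F, 10, axis=0)
    peak = F.max(axis=0)
    amplitude = peak - baseline
    # robust per-pixel temporal noise SD from first differences
    dF = np.diff(F, axis=0)
    noise_sd = 1.4826 * np.median(np.abs(dF - np.median(dF, axis=0)), axis=0) / np.sqrt(2.0)

    mask = movie.mask & (amplitude > 0) & (amplitude >= min_snr * noise_sd)
    if mask.any():
        amp_floor = min_amplitude_fraction * np.median(amplitude[mask])
        mask &= amplitude >= amp_floor
    if not mask.any():
        raise EmptyMaskError("preprocessing masked out every pixel")

    with np.errstate(divide="ignore", invalid="ignore"):
        norm = (F - baseline[None]) / amplitude[None] * 100.0
    norm[:, ~mask] = np.nan
    if spatial_median:
        filled = np.where(np.isnan(norm), 0.0, norm)
        for k in range(filled.shape[0]):
            filled[k] = ndimage.median_filter(filled[k], size=3)
        filled[:, ~mask] = np.nan
        norm = filled
    return PreprocessedMovie(
        frames=norm,
        mask=mask,
        sampling_interval_ms=h,
        pixel_pitch_cm=movie.pixel_pitch_cm,
        stim_times_ms=list(movie.stim_times_ms),
    )


# ---------------------------------------------------------------------------
# activation map
# ---------------------------------------------------------------------------

def _refine_argmax(d: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Vectorized sub-sample refinement of per-pixel derivative maxima.

    Plateau ties (exactly equal neighbours, the noise-free linear-ramp case)
    resolve to the plateau center; otherwise a clipped parabolic fit.
    """
    n = d.shape[0]
    flat = d.reshape(n, -1)
    cols = np.arange(flat.shape[1])
    i = idx.ravel()
    d0 = flat[i, cols]
    dm = np.where(i > 0, flat[np.maximum(i - 1, 0), cols], -np.inf)
    dp = np.where(i < n - 1, flat[np.minimum(i + 1, n - 1), cols], -np.inf)
    tol = 1e-9 * np.abs(d0) + 1e-12
    den = dm - 2.0 * d0 + dp
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(den < -tol, 0.5 * (dm - dp) / den, 0.0)
    delta = np.clip(np.nan_to_num(delta), -0.5, 0.5)
    # exact two-sample plateau: argmax returns the left member, center it
    plateau = np.abs(dp - d0) <= tol
    delta = np.where(plateau & (np.abs(dm - d0) > tol), 0.5, delta)
    return delta.reshape(idx.shape)


def compute_activation_map(
    pmovie: PreprocessedMovie,
    *,
    beat_window_ms: tuple | None = None,
    min_upstroke_fraction: float = 0.2,
) -> ActivationMap:
    """Per-pixel activation time = time of maximal temporal derivative.

    The discrete maximum within the beat window is refined to sub-sample
    precision by a parabolic fit through the three surrounding derivative
    samples. Pixels whose maximal derivative falls below
    ``min_upstroke_fraction`` times the in-mask median are left undefined;
    the map is invalid (:class:`MapError`) if more than half the masked
    pixels are undefined. Times are reported relative to the stimulus when
    one is recorded, else to the earliest activation.
    """
    F = pmovie.frames
    h = pmovie.sampling_interval_ms
    if beat_window_ms is not None:
        a = max(0, int(np.floor(beat_window_ms[0] / h)))
        b = min(F.shape[0], int(np.ceil(beat_window_ms[1] / h)) + 1)
    else:
        a, b = 0, F.shape[0]
    if b - a < 3:
        raise ParameterError("beat window must span at least 3 frames")
    seg = np.where(np.isnan(F[a:b]), 0.0, F[a:b])
    d = np.diff(seg, axis=0) / h
    idx = np.argmax(d, axis=0)
    dmax = np.take_along_axis(d, idx[None], axis=0)[0]

    defined = pmovie.mask & (dmax > 0)
    if defined.any():
        # reference the strongest upstrokes (99th percentile) so a movie in
        # which most pixels carry only noise still flags them as undefined
        thr = min_upstroke_fraction * np.percentile(dmax[defined], 99)
        defined &= dmax >= thr
    if not defined.any() or defined.sum() < 0.5 * pmovie.mask.sum():
        raise MapError(
            "activation map invalid: more than half the masked pixels have "
            "no suprathreshold upstroke"
        )

    delta = _refine_argmax(d, idx)
    t_act = (a + idx + 0.5 + delta) * h
    stim_ref = min(pmovie.stim_times_ms) if pmovie.stim_times_ms else float(np.min(t_act[defined]))
    t_act = t_act - stim_ref
    t_act = np.where(defined, t_act, np.nan)

    gy, gx = np.gradient(np.where(defined, t_act, np.nan))
    gradient_deg = np.degrees(np.arctan2(gy, gx))
    return ActivationMap(
        t_act_ms=t_act,
        mask=defined,
        gradient_deg=gradient_deg,
        stim_ref_ms=stim_ref,
        sampling_interval_ms=h,
        pixel_pitch_cm=pmovie.pixel_pitch_cm,
    )


# ---------------------------------------------------------------------------
# isochrones
# ---------------------------------------------------------------------------

def extract_isochrones(amap: ActivationMap, spacing_ms: float) -> dict:
    """Level sets of the activation time at multiples of ``spacing_ms``.

    Returns ``{level_ms: [polyline (N, 2) arrays in (row, col) pixels]}``.
    Undefined pixels are excluded; a spacing larger than the map's time
    range yields an empty set with a warning.
    """
    if spacing_ms <= 0:
        raise ParameterError("spacing_ms must be > 0")
    t = amap.t_act_ms
    tmin, tmax = np.nanmin(t), np.nanmax(t)
    levels = np.arange(np.ceil(tmin / spacing_ms), tmax / spacing_ms) * spacing_ms
    levels = levels[(levels > tmin) & (levels < tmax)]
    if levels.size == 0:
        warnings.warn(
            f"isochrone spacing {spacing_ms} ms exceeds the map's time range "
            f"({tmax - tmin:.1f} ms)",
            stacklevel=2,
        )
        return {}
    filled = np.where(np.isnan(t), tmax + 10 * spacing_ms, t)
    out = {}
    for lev in levels:
        contours = skmeasure.find_contours(filled, lev)
        out[float(lev)] = [c for c in contours if len(c) >= 2]
    return out


# ---------------------------------------------------------------------------
# conduction velocity
# ---------------------------------------------------------------------------

def _mean_gradient_direction(amap: ActivationMap) -> float:
    g = np.deg2rad(amap.gradient_deg[amap.mask])
    g = g[np.isfinite(g)]
    return float(np.degrees(np.arctan2(np.mean(np.sin(g)), np.mean(np.cos(g)))))


def _auto_sites(amap: ActivationMap, min_separation_px: int) -> tuple:
    """Place two sites along the mask-mean gradient through the centroid,
    as far apart as the mask allows (at least ``min_separation_px``)."""
    rows, cols = np.nonzero(amap.mask)
    r0, c0 = rows.mean(), cols.mean()
    theta = np.deg2rad(_mean_gradient_direction(amap))
    dc, dr = np.cos(theta), np.sin(theta)
    nr, nc = amap.mask.shape

    def _walk(sign):
        r, c, last = r0, c0, None
        for step in range(1, max(nr, nc)):
            rr = int(round(r0 + sign * step * dr))
            cc = int(round(c0 + sign * step * dc))
            if not (0 <= rr < nr and 0 <= cc < nc) or not amap.mask[rr, cc]:
                break
            last = (rr, cc)
        return last

    a, b = _walk(-1), _walk(+1)
    if a is None or b is None:
        raise MapError("could not place two-point CV sites inside the mask")
    if np.hypot(a[0] - b[0], a[1] - b[1]) < min_separation_px:
        raise MapError(
            f"mask supports no gradient-aligned site pair >= {min_separation_px} px apart"
        )
    return a, b


def cv_two_point(
    amap: ActivationMap,
    site_a: tuple | None = None,
    site_b: tuple | None = None,
    *,
    min_separation_px: int = 20,
    alignment_tol_deg: float = 15.0,
) -> CVEstimate:
    """Two-site conduction velocity along a line perpendicular to the
    isochrones (i.e. along the activation gradient).

    In auto mode (no sites given), the pair is placed along the mask-mean
    gradient direction through the map centroid, separated by at least
    ``min_separation_px`` pixels. CV is the Euclidean distance between the
    sites divided by their activation-time difference; equal activation
    times raise :class:`UndefinedVelocityError`, and a site line misaligned
    with the gradient by more than ``alignment_tol_deg`` degrees warns.
    """
    if (site_a is None) != (site_b is None):
        raise ParameterError("give both sites or neither")
    if site_a is None:
        site_a, site_b = _auto_sites(amap, min_separation_px)
    site_a, site_b = tuple(site_a), tuple(site_b)
    if site_a == site_b:
        raise ParameterError("sites must be distinct")
    for s in (site_a, site_b):
        if not amap.mask[s]:
            raise ParameterError(f"site {s} has no defined activation time")
    ta, tb = amap.t_act_ms[site_a], amap.t_act_ms[site_b]
    if tb == ta:
        raise UndefinedVelocityError("equal activation times at the two sites")
    if tb < ta:
        site_a, site_b, ta, tb = site_b, site_a, tb, ta
    dr = site_b[0] - site_a[0]
    dc = site_b[1] - site_a[1]
    dist_cm = np.hypot(dr, dc) * amap.pixel_pitch_cm
    direction = float(np.degrees(np.arctan2(dr, dc)))
    mean_grad = _mean_gradient_direction(amap)
    mis = abs((direction - mean_grad + 90) % 180 - 90)
    if mis > alignment_tol_deg:
        warnings.warn(
            f"site line ({direction:.0f} deg) misaligned with the mean "
            f"activation gradient ({mean_grad:.0f} deg) by {mis:.0f} deg",
            stacklevel=2,
        )
    cv = dist_cm / ((tb - ta) / 1000.0)
    return CVEstimate(cv_cm_s=float(cv), site_a=site_a, site_b=site_b,
                      direction_deg=direction)


def directional_cv_scan(
    amap: ActivationMap,
    stim_site: tuple,
    *,
    angle_step_deg: float = 5.0,
    r_inner_px: int = 10,
    min_separation_px: int = 20,
) -> AnisotropyResult:
    """CV versus direction around a point stimulus; anisotropy ratio.

    For each direction theta in [0, 180) the CV is measured between two
    sites on the ray from ``stim_site``: the innermost defined pixel at
    least ``r_inner_px`` out and the outermost defined pixel on the ray.
    Rays whose usable extent is shorter than ``min_separation_px`` are
    skipped; fewer than 8 usable directions raise :class:`ScanError`.
    The anisotropy ratio is CV(theta_max) / CV(theta_max + 90 deg), which
    is >= 1 by construction since theta_max maximizes the profile.
    """
    if 90.0 % angle_step_deg != 0:
        raise ParameterError("angle_step_deg must divide 90")
    nr, nc = amap.mask.shape
    r0, c0 = stim_site
    angles = np.arange(0.0, 180.0, angle_step_deg)
    cvs = np.full(angles.size, np.nan)
    rmax_px = int(np.hypot(nr, nc)) + 1

    for k, ang in enumerate(angles):
        th = np.deg2rad(ang)
        dc, dr = np.cos(th), np.sin(th)
        # sample both half-rays; each is an independent radial profile
        best = np.nan
        for sign in (+1, -1):
            inner = outer = None
            for step in range(r_inner_px, rmax_px):
                rr = int(round(r0 + sign * step * dr))
                cc = int(round(c0 + sign * step * dc))
                if not (0 <= rr < nr and 0 <= cc < nc):
                    break
                if not amap.mask[rr, cc]:
                    continue
                if inner is None:
                    inner = (rr, cc)
                outer = (rr, cc)
            if inner is None or outer is None or inner == outer:
                continue
            sep = np.hypot(outer[0] - inner[0], outer[1] - inner[1])
            if sep < min_separation_px:
                continue
            dt = amap.t_act_ms[outer] - amap.t_act_ms[inner]
            if dt <= 0:
                continue
            cv = sep * amap.pixel_pitch_cm / (dt / 1000.0)
            best = cv if np.isnan(best) else 0.5 * (best + cv)
        cvs[k] = best

    usable = np.isfinite(cvs)
    if usable.sum() < 8:
        raise ScanError(f"only {int(usable.sum())} usable directions (< 8)")
    k_max = int(np.nanargmax(cvs))
    k_perp = (k_max + int(round(90.0 / angle_step_deg))) % angles.size
    if not np.isfinite(cvs[k_perp]):
        raise ScanError("perpendicular direction unusable")
    ar = cvs[k_max] / cvs[k_perp]
    return AnisotropyResult(
        cv_max_cm_s=float(cvs[k_max]),
        cv_perp_cm_s=float(cvs[k_perp]),
        ar=float(ar),
        theta_max_deg=float(angles[k_max]),
        angles_deg=angles,
        cv_profile_cm_s=cvs,
    )


# ---------------------------------------------------------------------------
# pacing capture
# ---------------------------------------------------------------------------

def _activation_times_of(rec) -> tuple[np.ndarray, list]:
    """Activation times (ms) and stimulus times from a trace or a movie."""
    if isinstance(rec, VoltageTrace):
        beats, _, _ = detect_beats(rec)
        return np.array([b.t_act_ms for b in beats]), list(rec.stim_times_ms)
    if isinstance(rec, OpticalMovie):
        rows, cols = np.nonzero(rec.mask)
        trace = rec.pixel_trace(int(rows.mean()), int(cols.mean()))
        beats, _, _ = detect_beats(trace)
        return np.array([b.t_act_ms for b in beats]), list(rec.stim_times_ms)
    raise ParameterError(f"unsupported recording type {type(rec).__name__}")


def assess_capture(
    recordings: list,
    *,
    latency_ms: float = CAPTURE_LATENCY_MS,
    skip_stimuli: int = CAPTURE_SKIP_STIMULI,
) -> CaptureResult:
    """1:1 capture assessment over a pacing run.

    ``recordings`` is a list of ``(cl_ms, trace_or_movie)``. A stimulus is
    "propagated" when an activation follows it within ``latency_ms``; the
    first ``skip_stimuli`` stimuli of each recording are excluded as the
    rate-adaptation transient. Each recording needs at least 4 stimuli.
    """
    rows = []
    for cl, rec in recordings:
        acts, stims = _activation_times_of(rec)
        if len(stims) < 4:
            raise InsufficientStimuliError(
                f"CL {cl} ms: {len(stims)} stimuli (< 4) — cannot assess capture"
            )
        assessed = stims[skip_stimuli:]
        n_prop = sum(
            bool(np.any((acts >= s) & (acts <= s + latency_ms))) for s in assessed
        )
        rows.append(dict(
            cl_ms=cl,
            n_stimuli=len(stims),
            n_assessed=len(assessed),
            n_propagated=int(n_prop),
            captured_1to1=bool(n_prop == len(assessed)),
        ))
    return CaptureResult(rows=rows)
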