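"""Parametric action-potential waveform templates.

A template is the deterministic building block of every synthetic recording:
a resting baseline, a linear depolarization ramp, and a monotone repolarization
curve pinned to the four APD anchors (time to 20/50/70/90 % repolarization).

Design notes
------------
* The upstroke is a *linear* ramp of duration ``t_upstroke_ms``. Its maximal
  rise in normalized amplitude is exactly ``100 / t_upstroke_ms`` %APA/ms, and
  — because a forward difference across any window fully inside a linear ramp
  equals the true slope — that value is recovered exactly at any sampling
  interval up to half the ramp duration, independent of sampling phase.
* The activation-time convention is the *midpoint* of the maximal-slope
  segment: on a linear ramp the time of maximal upstroke velocity is the
  whole ramp, and a discrete maximal-derivative detector with plateau-aware
  sub-sample refinement lands at its center. APD anchors are times from that
  midpoint.
* Repolarization is a monotone piecewise-cubic (PCHIP) curve through the
  anchor points ``(APD_f, 1 - f/100)`` in normalized amplitude, extended to
  full repolarization shortly after APD90; it is non-increasing after the
  peak by construction.

The template's internal time axis starts at ramp *onset* (t = 0), so the
activation reference sits at ``t_upstroke_ms / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import ParameterError

APD_FRACTIONS = (20, 50, 70, 90)

#: native evaluation grid used to build the fast lookup table (ms)
_DENSE_DT = 0.01


@dataclass
class APTemplate:
    """Parametric single action potential.

    Parameters
    ----------
    rmp_mV : float
        Resting / baseline potential (mV; ignored sign-wise for optical use).
    apa_mV : float
        Action potential amplitude, peak minus baseline (> 0).
    t_upstroke_ms : float
        Duration of the linear depolarization ramp (> 0).
    apd_anchors_ms : dict
        ``{20: APD20, 50: APD50, 70: APD70, 90: APD90}`` in ms, measured
        from activation (mid-upstroke); strictly increasing and all greater
        than ``t_upstroke_ms``.
    dt_ms : float
        Native template resolution (<= 0.1 ms) used by :meth:`sample`.
    """

    rmp_mV: float
    apa_mV: float
    t_upstroke_ms: float
    apd_anchors_ms: dict
    dt_ms: float = 0.05
    _repol: PchipInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.apa_mV <= 0:
            raise ParameterError("apa_mV must be > 0")
        if self.t_upstroke_ms <= 0:
            raise ParameterError("t_upstroke_ms must be > 0")
        if not 0 < self.dt_ms <= 0.1:
            raise ParameterError("dt_ms must be in (0, 0.1]")
        missing = set(APD_FRACTIONS) - set(self.apd_anchors_ms)
        if missing:
            raise ParameterError(f"missing APD anchors: {sorted(missing)}")
        anchors = [float(self.apd_anchors_ms[f]) for f in APD_FRACTIONS]
        if any(b <= a for a, b in zip(anchors, anchors[1:])):
            raise ParameterError(
                "APD anchors must be strictly increasing in repolarization "
                f"fraction, got {anchors}"
            )
        if anchors[0] <= self.t_upstroke_ms:
            raise ParameterError(
                f"APD20 ({anchors[0]} ms) must exceed the upstroke duration "
                f"({self.t_upstroke_ms} ms)"
            )
        # knots of the repolarization curve in normalized amplitude (1 = peak);
        # anchor times are referenced to mid-upstroke, the internal axis to onset
        half_up = 0.5 * self.t_upstroke_ms
        t90 = anchors[-1]
        t70 = anchors[-2]
        self._t_end = half_up + t90 + max(t90 - t70, 2.0)  # full repolarization
        knots_t = np.array([self.t_upstroke_ms, *(half_up + np.asarray(anchors)), self._t_end])
        knots_v = np.array([1.0, 0.8, 0.5, 0.3, 0.1, 0.0])
        self._repol = PchipInterpolator(knots_t, knots_v, extrapolate=False)

    # -- derived quantities ------------------------------------------------

    @property
    def peak_mV(self) -> float:
        return self.rmp_mV + self.apa_mV

    @property
    def t_end_ms(self) -> float:
        """Time from ramp onset (internal axis) to full repolarization."""
        return self._t_end

    @property
    def upstroke_velocity_pct_per_ms(self) -> float:
        """Ground-truth maximal d(%APA)/dt of the linear ramp."""
        return 100.0 / self.t_upstroke_ms

    # -- evaluation --------------------------------------------------------

    def normalized(self, t_ms) -> np.ndarray:
        """Evaluate the waveform on a 0–1 amplitude scale at times ``t_ms``
        (ms from activation). Baseline is 0 before onset and after full
        repolarization."""
        t = np.asarray(t_ms, dtype=float)
        out = np.zeros_like(t)
        ramp = (t >= 0) & (t < self.t_upstroke_ms)
        out[ramp] = t[ramp] / self.t_upstroke_ms
        fall = (t >= self.t_upstroke_ms) & (t < self._t_end)
        out[fall] = self._repol(t[fall])
        return out

    def evaluate(self, t_ms) -> np.ndarray:
        """Evaluate in mV at times ``t_ms`` relative to activation."""
        return self.rmp_mV + self.apa_mV * self.normalized(t_ms)

    def lookup_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense ``(t, normalized amplitude)`` table for fast ``np.interp``."""
        t = np.arange(0.0, self._t_end + _DENSE_DT, _DENSE_DT)
        return t, self.normalized(t)

    def sample(self, duration_ms: float, sampling_interval_ms: float | None = None,
               activation_ms: float = 0.0) -> np.ndarray:
        """Sample one beat in mV on a uniform grid starting at t = 0.

        ``activation_ms`` places the ramp onset on the grid's absolute time
        axis; the default puts a sample exactly at onset.
        """
        h = self.dt_ms if sampling_interval_ms is None else sampling_interval_ms
        t = np.arange(0.0, duration_ms + 0.5 * h, h)
        return self.evaluate(t - activation_ms)


def make_template(*, rmp_mV: float, apa_mV: float = 100.0,
                  t_upstroke_ms: float | None = None,
                  upstroke_velocity_pct_per_ms: float | None = None,
                  apd_anchors_ms: dict, dt_ms: float = 0.05) -> APTemplate:
    """Build an :class:`APTemplate`, optionally from a target normalized
    upstroke velocity instead of a ramp duration.

    Exactly one of ``t_upstroke_ms`` / ``upstroke_velocity_pct_per_ms`` must
    be given; the latter sets ``t_upstroke_ms = 100 / velocity``.
    """
    if (t_upstroke_ms is None) == (upstroke_velocity_pct_per_ms is None):
        raise ParameterError(
            "give exactly one of t_upstroke_ms or upstroke_velocity_pct_per_ms"
        )
    if t_upstroke_ms is None:
        if upstroke_velocity_pct_per_ms <= 0:
            raise ParameterError("upstroke velocity must be > 0")
        t_upstroke_ms = 100.0 / upstroke_velocity_pct_per_ms
    return APTemplate(
        rmp_mV=rmp_mV,
        apa_mV=apa_mV,
        t_upstroke_ms=t_upstroke_ms,
        apd_anchors_ms=dict(apd_anchors_ms),
        dt_ms=dt_ms,
    )


def slope_for_cycle_length(template: APTemplate, cl_ms: float,
                           takeoff_fraction: float = 0.1) -> float:
    """Diastolic slope (mV/s) that yields spontaneous beating at ``cl_ms``.

    The spontaneous-beat model ramps linearly from the MDP until it reaches
    ``MDP + takeoff_fraction * APA``, then fires a beat; the emergent cycle
    length is the ramp time plus the beat duration (activation to full
    repolarization, less the part of the upstroke below takeoff).
    """
    beat_ms = template.t_end_ms - takeoff_fraction * template.t_upstroke_ms
    ramp_ms = cl_ms - beat_ms
    if ramp_ms <= 0:
        raise ParameterError(
            f"cycle length {cl_ms} ms shorter than the beat itself ({beat_ms:.1f} ms)"
        )
    return takeoff_fraction * template.apa_mV / (ramp_ms / 1000.0)
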