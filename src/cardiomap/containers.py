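"""In-memory recording containers shared by the generator, the analysis and I/O.

Conventions used throughout the package: times in ms, distances in cm,
intracellular voltages in mV, optical signals in arbitrary fluorescence
units; pixel coordinates are 0-based ``(row, col)``; angles are measured
from the +x (column) axis toward the +y (row) axis; windows are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, ParameterError

INTRACELLULAR = "intracellular"
OPTICAL = "optical"


@dataclass
class VoltageTrace:
    """A uniformly sampled single-site voltage recording.

    Parameters
    ----------
    samples : ndarray
        Voltage series — mV for ``intracellular``, arbitrary units for
        ``optical`` (e.g. a single pixel pulled out of a movie).
    sampling_interval_ms : float
        Sample spacing in ms.
    stim_times_ms : sequence of float
        Times of delivered pacing stimuli (may be empty for spontaneous or
        quiescent recordings). Every stimulus, captured or not, is listed.
    modality : str
        ``"intracellular"`` or ``"optical"``.
    """

    samples: np.ndarray
    sampling_interval_ms: float
    stim_times_ms: list = field(default_factory=list)
    modality: str = INTRACELLULAR

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ParameterError("trace needs a 1-D series of >= 2 samples")
        if self.sampling_interval_ms <= 0:
            raise ParameterError("sampling_interval_ms must be > 0")
        if self.modality not in (INTRACELLULAR, OPTICAL):
            raise ParameterError(f"unknown modality {self.modality!r}")
        dur = self.duration_ms
        for t in self.stim_times_ms:
            if not 0 <= t <= dur:
                raise ParameterError(f"stimulus at {t} ms outside record [0, {dur}]")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return (self.samples.size - 1) * self.sampling_interval_ms

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.sampling_interval_ms


@dataclass
class OpticalMovie:
    """A voltage-sensitive-dye fluorescence movie (T frames of H x W pixels).

    ``frames`` are raw arbitrary units; per-pixel normalization is the
    analysis' job. ``mask`` marks pixels that carry tissue signal.
    """

    frames: np.ndarray
    sampling_interval_ms: float
    pixel_pitch_cm: float
    mask: np.ndarray | None = None
    stim_times_ms: list = field(default_factory=list)
    ground_truth: dict | None = None  # populated by the generator, if any

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise FormatError("frames must be a T x H x W stack")
        if self.frames.shape[0] < 2:
            raise FormatError("movie needs at least 2 frames")
        if self.sampling_interval_ms <= 0:
            raise ParameterError("sampling_interval_ms must be > 0")
        if self.pixel_pitch_cm <= 0:
            raise ParameterError("pixel_pitch_cm must be > 0")
        if self.mask is None:
            self.mask = np.ones(self.frames.shape[1:], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.frames.shape[1:]:
                raise FormatError("mask shape must equal frame shape")

    @property
    def shape(self):
        return self.frames.shape

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_ms(self) -> float:
        return (self.n_frames - 1) * self.sampling_interval_ms

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.sampling_interval_ms

    def pixel_trace(self, row: int, col: int) -> VoltageTrace:
        """Extract one pixel as an optical :class:`VoltageTrace`."""
        return VoltageTrace(
            samples=self.frames[:, row, col],
            sampling_interval_ms=self.sampling_interval_ms,
            stim_times_ms=list(self.stim_times_ms),
            modality=OPTICAL,
        )
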