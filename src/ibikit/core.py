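"""Shared domain containers for the respiratory analysis pipeline.

The pipeline operates on uncalibrated chest impedance pneumograph (IP)
waveforms recorded alongside slow numeric vitals (heart rate in bpm,
SpO2 in %).  Containers here are deliberately thin: numpy arrays plus
sampling metadata, with validation of the physiological ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """A configuration value is invalid; the message names the field."""


class OverlapError(ValueError):
    """An injected interval collides with an existing one."""


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class PhysioRecording:
    """Synchronized IP / heart-rate / SpO2 channels for one subject.

    ``ip`` is sampled at ``ip_rate`` Hz; ``hr`` and ``spo2`` at
    ``numeric_rate`` Hz.  Missing numeric samples are NaN.  All channels
    start at ``start_time`` seconds and must cover the same span to
    within one numeric sample.
    """

    subject_id: str
    ip: np.ndarray
    ip_rate: float
    hr: np.ndarray
    spo2: np.ndarray
    numeric_rate: float = 1.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.ip = _as_float_array(self.ip)
        self.hr = _as_float_array(self.hr)
        self.spo2 = _as_float_array(self.spo2)
        if self.ip_rate <= 0:
            raise ConfigurationError("ip_rate must be > 0")
        if self.numeric_rate <= 0:
            raise ConfigurationError("numeric_rate must be > 0")
        dur = self.duration
        for name, arr, rate in (
            ("hr", self.hr, self.numeric_rate),
            ("spo2", self.spo2, self.numeric_rate),
        ):
            if arr.size and abs(arr.size / rate - dur) > 1.0 / rate + 1e-9:
                raise ConfigurationError(
                    f"{name} does not cover the IP time span "
                    f"({arr.size / rate:.2f} s vs {dur:.2f} s)"
                )
        fin = self.hr[np.isfinite(self.hr)]
        if fin.size and (fin.min() <= 0 or fin.max() >= 300):
            raise ConfigurationError("hr values must lie in (0, 300) bpm")
        fin = self.spo2[np.isfinite(self.spo2)]
        if fin.size and (fin.min() <= 0 or fin.max() > 100):
            raise ConfigurationError("spo2 values must lie in (0, 100] %")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.ip.size / self.ip_rate

    @property
    def ip_times(self) -> np.ndarray:
        return self.start_time + np.arange(self.ip.size) / self.ip_rate

    @property
    def numeric_times(self) -> np.ndarray:
        return self.start_time + np.arange(self.hr.size) / self.numeric_rate

    def crop(self, t0: float, t1: float) -> "PhysioRecording":
        """Return the sub-recording covering [t0, t1) in local seconds."""
        if not 0 <= t0 < t1 <= self.duration + 1e-9:
            raise ValueError(f"crop window [{t0}, {t1}) outside recording")
        i0, i1 = int(round(t0 * self.ip_rate)), int(round(t1 * self.ip_rate))
        j0 = int(round(t0 * self.numeric_rate))
        j1 = int(round(t1 * self.numeric_rate))
        return PhysioRecording(
            subject_id=self.subject_id,
            ip=self.ip[i0:i1].copy(),
            ip_rate=self.ip_rate,
            hr=self.hr[j0:j1].copy(),
            spo2=self.spo2[j0:j1].copy(),
            numeric_rate=self.numeric_rate,
            start_time=self.start_time + t0,
        )


@dataclass
class FilteredIP:
    """Zero-centred, cardiac-suppressed IP with a per-sample artefact mask.

    ``signal`` keeps the length and rate of the input IP; masked samples
    are unusable (set to zero) and excluded from downstream SD/RMS
    computations.  ``cardiac_freq_trace`` is the per-sample cardiac
    frequency (Hz) that drove the notch filtering.
    """

    signal: np.ndarray
    rate: float
    artefact_mask: np.ndarray
    cardiac_freq_trace: np.ndarray

    def __post_init__(self) -> None:
        self.signal = _as_float_array(self.signal)
        self.artefact_mask = np.asarray(self.artefact_mask, dtype=bool)
        self.cardiac_freq_trace = _as_float_array(self.cardiac_freq_trace)
        n = self.signal.size
        if self.artefact_mask.size != n or self.cardiac_freq_trace.size != n:
            raise ValueError("mask and cardiac trace must match signal length")

    @property
    def duration(self) -> float:
        return self.signal.size / self.rate


@dataclass
class BreathTrain:
    """Detected breath onset times plus the threshold in force per sample."""

    breath_times: np.ndarray
    threshold_trace: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.breath_times = _as_float_array(self.breath_times)
        self.threshold_trace = _as_float_array(self.threshold_trace)
        if self.breath_times.size and np.any(np.diff(self.breath_times) <= 0):
            raise ValueError("breath_times must be strictly increasing")

    def __len__(self) -> int:
        return self.breath_times.size


@dataclass
class IBISeries:
    """Intervals between consecutive detected breaths.

    ``valid`` is False when the interval overlaps masked artefact spans
    beyond the tolerance used at construction; invalid intervals are
    excluded from all distribution statistics.
    """

    start: np.ndarray = field(default_factory=lambda: np.empty(0))
    end: np.ndarray = field(default_factory=lambda: np.empty(0))
    valid: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def __post_init__(self) -> None:
        self.start = _as_float_array(self.start)
        self.end = _as_float_array(self.end)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.start.size == self.end.size == self.valid.size):
            raise ValueError("start, end, valid must have equal length")
        if np.any(self.end <= self.start):
            raise ValueError("interval durations must be positive")

    @property
    def duration(self) -> np.ndarray:
        return self.end - self.start

    @property
    def valid_durations(self) -> np.ndarray:
        return self.duration[self.valid]

    def __len__(self) -> int:
        return self.start.size
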