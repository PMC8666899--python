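"""Synthetic neonatal recordings with exhaustive ground truth.

Real impedance-pneumograph recordings from bedside monitors are not
publicly deposited, so every downstream stage of the pipeline is tested
against simulated recordings that emulate their salient features: a
quasi-periodic breathing waveform with slow amplitude drift, an additive
cardiac-frequency oscillation, white sensor noise, movement artefacts,
and injectable breathing pauses with optional bradycardia / desaturation
responses.

The breathing waveform is a phase-accumulator sinusoid: the
instantaneous breath rate is the configured mean modulated by a smooth
AR(1) jitter process, and the signal is ``envelope * sin(phase)``.  A
ground-truth "breath" is the upward zero-crossing of the breathing phase
(phase passing a multiple of 2*pi), which matches detection of breath
onsets by upward threshold crossing and gives exact breath times without
modelling airway mechanics.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .core import ConfigurationError, OverlapError, PhysioRecording

PAUSE_KINDS = (
    "apnoea-with-response",
    "apnoea-no-response",
    "low-amplitude-false-alarm",
    "pause",
)
#: Kinds during which breathing genuinely ceases (truth breaths removed).
CESSATION_KINDS = ("apnoea-with-response", "apnoea-no-response", "pause")
#: Minimum duration (s) for an interval to count as a central apnoea.
APNOEA_MIN_DURATION_S = 20.0

FEATURE_NAMES = ("rms_during", "rms_pre10", "rms_post10", "delta_hr60", "delta_spo2_60")

_EDGE_RAMP_S = 0.2  # raised-cosine ramp at pause edges, avoids step transients


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic recording.

    Units: ``duration`` s; ``ip_rate``/``numeric_rate`` Hz;
    ``breath_rate_mean`` breaths/min; ``breath_rate_jitter`` fractional
    rate modulation; amplitudes in arbitrary impedance units;
    ``amplitude_drift`` fractional envelope change per minute (RMS);
    ``cardiac_rate`` bpm; ``cardiac_amplitude_ratio`` fraction of the
    breath amplitude; ``noise_sd`` arbitrary units.
    """

    duration: float = 300.0
    ip_rate: float = 62.5
    numeric_rate: float = 1.0
    breath_rate_mean: float = 50.0
    breath_rate_jitter: float = 0.05
    breath_amplitude: float = 1.0
    amplitude_drift: float = 0.05
    cardiac_rate: float = 150.0
    cardiac_amplitude_ratio: float = 0.2
    noise_sd: float = 0.05
    hr_baseline: float = 150.0
    spo2_baseline: float = 97.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")
        if self.ip_rate <= 0:
            raise ConfigurationError("ip_rate must be > 0")
        if self.numeric_rate <= 0:
            raise ConfigurationError("numeric_rate must be > 0")
        if self.ip_rate < 4.0 * self.cardiac_rate / 60.0:
            raise ConfigurationError(
                "ip_rate must be >= 4x the cardiac frequency (cardiac_rate/60)"
            )
        if not 10.0 < self.breath_rate_mean < 120.0:
            raise ConfigurationError("breath_rate_mean must lie in (10, 120) breaths/min")
        for name in ("breath_amplitude", "cardiac_amplitude_ratio", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.breath_rate_jitter < 0:
            raise ConfigurationError("breath_rate_jitter must be >= 0")
        if self.amplitude_drift < 0:
            raise ConfigurationError("amplitude_drift must be >= 0")


@dataclass
class PauseInterval:
    start: float
    end: float
    kind: str

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class _Components:
    """Additive signal components; ``ip = breathing + cardiac + noise + extra``."""

    breathing: np.ndarray
    cardiac: np.ndarray
    noise: np.ndarray
    extra: np.ndarray
    config: SimulationConfig


@dataclass(eq=False)
class GroundTruth:
    """Exhaustive per-recording annotations produced by the simulator."""

    breath_times: np.ndarray
    pause_intervals: list[PauseInterval] = field(default_factory=list)
    artefact_intervals: list[tuple[float, float]] = field(default_factory=list)
    hr_events: list[tuple[float, float]] = field(default_factory=list)
    spo2_events: list[tuple[float, float]] = field(default_factory=list)
    _components: _Components | None = field(default=None, repr=False)

    def breaths_in(self, t0: float, t1: float) -> np.ndarray:
        bt = self.breath_times
        return bt[(bt >= t0) & (bt < t1)]


def simulate_recording(
    config: SimulationConfig, subject_id: str = "sim"
) -> tuple[PhysioRecording, GroundTruth]:
    """Generate one recording plus its ground truth.

    Deterministic: identical ``config`` (including ``seed``) gives
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rate = config.ip_rate
    n = int(round(config.duration * rate))
    dt = 1.0 / rate
    t = np.arange(n) * dt

    # Instantaneous breath rate: mean modulated by a unit-variance AR(1)
    # process (time constant 8 s) scaled by the jitter fraction.
    f0 = config.breath_rate_mean / 60.0
    if config.breath_rate_jitter > 0:
        rho = math.exp(-dt / 8.0)
        eps = rng.standard_normal(n)
        ar = lfilter([math.sqrt(1.0 - rho**2)], [1.0, -rho], eps)
    else:
        ar = np.zeros(n)
        rng.standard_normal(n)  # keep stream alignment across jitter settings
    f_inst = np.clip(f0 * (1.0 + config.breath_rate_jitter * ar), 0.1 * f0, None)

    phi0 = rng.uniform(0.0, 2.0 * math.pi)
    phase = phi0 + 2.0 * math.pi * np.cumsum(f_inst) * dt

    # Slow multiplicative amplitude drift: smoothed random walk on a 1 s
    # grid whose increment SD over one minute equals amplitude_drift.
    n_coarse = max(2, int(math.ceil(config.duration)) + 1)
    steps = rng.standard_normal(n_coarse) * (config.amplitude_drift / math.sqrt(60.0))
    walk = gaussian_filter1d(np.cumsum(steps), sigma=5.0, mode="nearest")
    env_factor = np.clip(1.0 + walk, 0.2, 2.0)
    envelope = config.breath_amplitude * np.interp(t, np.arange(n_coarse, dtype=float), env_factor)

    breathing = envelope * np.sin(phase)
    phc = rng.uniform(0.0, 2.0 * math.pi)
    cardiac = (
        config.cardiac_amplitude_ratio
        * config.breath_amplitude
        * np.sin(2.0 * math.pi * (config.cardiac_rate / 60.0) * t + phc)
    )
    noise = config.noise_sd * rng.standard_normal(n)
    ip = breathing + cardiac + noise

    # Ground-truth breaths: times where the accumulated phase crosses 2*pi*k.
    k_lo = math.ceil(phase[0] / (2.0 * math.pi) + 1e-12)
    k_hi = math.floor(phase[-1] / (2.0 * math.pi))
    targets = 2.0 * math.pi * np.arange(k_lo, k_hi + 1)
    breath_times = np.interp(targets, phase, t)

    n_num = int(round(config.duration * config.numeric_rate))
    hr = np.full(n_num, float(config.hr_baseline))
    spo2 = np.full(n_num, float(config.spo2_baseline))

    rec = PhysioRecording(
        subject_id=subject_id,
        ip=ip,
        ip_rate=rate,
        hr=hr,
        spo2=spo2,
        numeric_rate=config.numeric_rate,
    )
    truth = GroundTruth(
        breath_times=breath_times,
        _components=_Components(breathing, cardiac, noise, np.zeros(n), config),
    )
    return rec, truth


def _require_components(truth: GroundTruth) -> _Components:
    if truth._components is None:
        raise ValueError("recording was not produced by simulate_recording; cannot inject")
    return truth._components


def _suppression_window(n: int, rate: float, i0: int, i1: int) -> np.ndarray:
    """Multiplier that ramps 1 -> 0 over the first ramp, 0 inside, 0 -> 1 at end."""
    w = np.ones(n)
    ramp = max(1, int(round(_EDGE_RAMP_S * rate)))
    span = i1 - i0
    ramp = min(ramp, span // 2)
    w[i0:i1] = 0.0
    if ramp > 0:
        x = np.linspace(0.0, 1.0, ramp, endpoint=False)
        w[i0 : i0 + ramp] = 0.5 * (1.0 + np.cos(math.pi * x))
        w[i1 - ramp : i1] = 0.5 * (1.0 - np.cos(math.pi * x))
    return w


def _event_dip(times: np.ndarray, start: float, baseline: np.ndarray, nadir: float) -> np.ndarray:
    """Raised-cosine dip reaching ``nadir`` at start+30 s, recovered by start+90 s."""
    tp = times - start
    shape = np.zeros_like(times)
    rising = (tp >= 0) & (tp < 30.0)
    shape[rising] = 0.5 * (1.0 - np.cos(math.pi * tp[rising] / 30.0))
    falling = (tp >= 30.0) & (tp <= 90.0)
    shape[falling] = 0.5 * (1.0 + np.cos(math.pi * (tp[falling] - 30.0) / 60.0))
    depth = baseline - nadir
    return baseline - np.maximum(depth, 0.0) * shape


def inject_pause(
    recording: PhysioRecording,
    truth: GroundTruth,
    start: float,
    duration: float,
    kind: str,
    hr_response: float | None = None,
    spo2_response: float | None = None,
    low_amplitude_fraction: float = 0.1,
    cardiac_retention: float = 0.5,
) -> tuple[PhysioRecording, GroundTruth]:
    """Insert a breathing pause (or low-amplitude false-alarm segment).

    For cessation kinds the breathing component is removed over
    [start, end] (cardiac retained at ``cardiac_retention`` of its
    amplitude, noise untouched) and ground-truth breaths inside are
    deleted.  The end is snapped forward to the next ground-truth breath
    onset so that breathing resumes with an inspiration rather than
    mid-cycle (the recorded interval may therefore be up to one breath
    period longer than requested).  For ``low-amplitude-false-alarm``
    the breathing amplitude is scaled to ``low_amplitude_fraction`` but
    the breaths remain in the truth: they are real, just undetectable.
    Optional HR / SpO2 responses carve smooth dips reaching the nadir
    30 s after onset.
    """
    comps = _require_components(truth)
    if kind not in PAUSE_KINDS:
        raise ConfigurationError(f"unknown pause kind {kind!r}")
    if duration <= 0:
        raise ConfigurationError("duration must be > 0")
    if kind.startswith("apnoea") and duration < APNOEA_MIN_DURATION_S:
        raise ConfigurationError(
            f"kind {kind!r} requires duration >= {APNOEA_MIN_DURATION_S} s"
        )
    end = start + duration
    if start < 0 or end > recording.duration + 1e-9:
        raise ValueError("pause interval extends outside the recording")
    onset = start  # physiological onset; HR/SpO2 responses anchor here
    if kind in CESSATION_KINDS:
        # Leave the last pre-pause breath room to be detected (its
        # threshold crossing comes shortly after the onset) ...
        before = truth.breath_times[truth.breath_times <= start]
        if before.size:
            start = max(start, float(before[-1]) + 0.5)
        # ... and resume on an inspiration onset, keeping at least the
        # requested duration.
        later = truth.breath_times[truth.breath_times > end]
        for b in later:
            if float(b) - start >= duration:
                end = float(b)
                break
    for p in truth.pause_intervals:
        if start < p.end and end > p.start:
            raise OverlapError(
                f"pause [{start}, {end}] overlaps existing [{p.start}, {p.end}]"
            )

    rec = copy.deepcopy(recording)
    new_truth = copy.deepcopy(truth)
    comps = _require_components(new_truth)
    rate = rec.ip_rate
    n = rec.ip.size
    i0, i1 = int(round(start * rate)), min(n, int(round(end * rate)))
    w = _suppression_window(n, rate, i0, i1)

    if kind in CESSATION_KINDS:
        comps.breathing *= w
        comps.cardiac *= w + cardiac_retention * (1.0 - w)
        bt = new_truth.breath_times
        new_truth.breath_times = bt[(bt < start) | (bt >= end)]
    else:
        comps.breathing *= w + low_amplitude_fraction * (1.0 - w)

    tn = rec.numeric_times - rec.start_time
    if hr_response is not None:
        rec.hr = _event_dip(tn, onset, rec.hr, float(hr_response))
        new_truth.hr_events.append((onset, float(hr_response)))
    if spo2_response is not None:
        rec.spo2 = _event_dip(tn, onset, rec.spo2, float(spo2_response))
        new_truth.spo2_events.append((onset, float(spo2_response)))

    new_truth.pause_intervals.append(PauseInterval(start, end, kind))
    new_truth.pause_intervals.sort(key=lambda p: p.start)
    rec.ip = comps.breathing + comps.cardiac + comps.noise + comps.extra
    return rec, new_truth


def inject_movement_artefact(
    recording: PhysioRecording,
    truth: GroundTruth,
    start: float,
    duration: float,
    magnitude: float,
) -> tuple[PhysioRecording, GroundTruth]:
    """Add a large low-frequency excursion emulating infant movement.

    The excursion is a plateau of ``magnitude`` times the breath
    amplitude with 0.25 s raised-cosine ramps and a mild slow wobble —
    the signature of an electrode shift.  ``magnitude`` must be >= 3 so
    the artefact is unambiguous relative to breathing.
    """
    comps = _require_components(truth)
    if magnitude < 3:
        raise ConfigurationError("magnitude must be >= 3 breath amplitudes")
    if duration <= 0:
        raise ConfigurationError("duration must be > 0")
    end = start + duration
    if start < 0 or end > recording.duration + 1e-9:
        raise ValueError("artefact interval extends outside the recording")

    rec = copy.deepcopy(recording)
    new_truth = copy.deepcopy(truth)
    comps = _require_components(new_truth)
    rate = rec.ip_rate
    i0, i1 = int(round(start * rate)), min(rec.ip.size, int(round(end * rate)))
    m = i1 - i0
    tloc = np.arange(m) / rate
    ramp = max(1, min(int(round(0.25 * rate)), m // 2))
    plateau = np.ones(m)
    x = np.linspace(0.0, 1.0, ramp, endpoint=False)
    plateau[:ramp] = 0.5 * (1.0 - np.cos(math.pi * x))
    plateau[m - ramp :] = 0.5 * (1.0 + np.cos(math.pi * x))
    wobble = 1.0 + 0.1 * np.sin(2.0 * math.pi * 0.3 * tloc)
    amp = 1.05 * magnitude * comps.config.breath_amplitude
    comps.extra[i0:i1] += amp * plateau * wobble

    new_truth.artefact_intervals.append((start, end))
    new_truth.artefact_intervals.sort()
    rec.ip = comps.breathing + comps.cardiac + comps.noise + comps.extra
    return rec, new_truth


# --- synthetic classifier feature sets -------------------------------------

_FEATURE_CENTER = np.array([0.10, 0.50, 0.50, -12.0, -4.0])
_FEATURE_SCALE = np.array([0.05, 0.15, 0.15, 8.0, 3.0])
# Class-difference direction (true apnoea minus false alarm, unit norm):
# lower RMS during the episode, higher RMS before/after, deeper HR and
# SpO2 drops.  False alarms sit on the opposite side: uniformly low RMS
# and near-zero vital-sign deltas.
_FEATURE_DIRECTION = np.array([-0.2, 1.0, 1.0, -1.0, -1.0])
_FEATURE_DIRECTION = _FEATURE_DIRECTION / np.linalg.norm(_FEATURE_DIRECTION)


def simulate_feature_set(
    n_true: int,
    n_false: int,
    separation: float,
    seed: int = 0,
    n_subjects: int = 15,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a labelled apnoea-feature sample from two Gaussian classes.

    The two classes are unit-covariance Gaussians in a standardised
    5-feature space whose means are ``separation`` SD apart along a fixed
    direction; ``separation = 0`` makes the classes indistinguishable.
    Returns ``(X, labels, subject_ids)`` where ``X`` columns follow
    :data:`FEATURE_NAMES`, labels are 1 for true apnoea / 0 for false
    alarm, and subjects are assigned round-robin for
    leave-one-subject-out evaluation.
    """
    if n_true < 1 or n_false < 1:
        raise ConfigurationError("n_true and n_false must be >= 1")
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    half = 0.5 * separation * _FEATURE_DIRECTION
    z_true = rng.standard_normal((n_true, 5)) + half
    z_false = rng.standard_normal((n_false, 5)) - half
    z = np.vstack([z_true, z_false])
    X = _FEATURE_CENTER + _FEATURE_SCALE * z
    X[:, :3] = np.maximum(X[:, :3], 0.0)  # RMS features are non-negative
    y = np.concatenate([np.ones(n_true, dtype=int), np.zeros(n_false, dtype=int)])
    order = rng.permutation(n_true + n_false)
    X, y = X[order], y[order]
    subjects = np.arange(n_true + n_false) % n_subjects
    return X, y, subjects


# --- cohort construction ----------------------------------------------------


def simulate_epoch_pair_cohort(
    n_subjects: int = 15,
    epoch_duration: float = 600.0,
    seed: int = 0,
    pauses_before: int = 2,
    pauses_after: int = 6,
    after_rate_factor: float = 0.85,
    pause_duration_range: tuple[float, float] = (6.0, 14.0),
    base_config: SimulationConfig | None = None,
    apnoeas_after: int = 0,
    false_alarms_after: int = 0,
) -> list[tuple[PhysioRecording, GroundTruth, tuple[float, float], tuple[float, float]]]:
    """Cohort of recordings with a before and an after epoch per subject.

    Emulates a respiratory-depressant exposure: in the after epoch the
    breath rate is reduced by ``after_rate_factor`` and the number of
    injected breathing pauses is increased (defaults triple it).
    Optionally each after epoch also receives ``apnoeas_after`` full
    apnoeas (>= 20 s, with bradycardia/desaturation responses) and
    ``false_alarms_after`` low-amplitude false-alarm segments, so that
    candidate classification has material to work on.  Each element is
    ``(recording, truth, epoch_before, epoch_after)`` where the
    recording is the concatenation of the two simulated epochs.
    """
    ss = np.random.SeedSequence(seed)
    out = []
    base = base_config or SimulationConfig(duration=epoch_duration)
    for s, child in enumerate(ss.spawn(n_subjects)):
        sub_rng = np.random.default_rng(child)
        rate = sub_rng.uniform(42.0, 48.0)
        seeds = sub_rng.integers(0, 2**31 - 1, size=2)
        cfg_before = replace(base, duration=epoch_duration, breath_rate_mean=rate, seed=int(seeds[0]))
        cfg_after = replace(
            base,
            duration=epoch_duration,
            breath_rate_mean=rate * after_rate_factor,
            seed=int(seeds[1]),
        )
        halves = []
        for half_idx, (cfg, n_pauses) in enumerate(
            ((cfg_before, pauses_before), (cfg_after, pauses_after))
        ):
            rec, truth = simulate_recording(cfg, subject_id=f"subj{s:02d}")
            extras: list[tuple[str, float, dict]] = []
            if half_idx == 1:
                for _ in range(apnoeas_after):
                    extras.append(
                        (
                            "apnoea-with-response",
                            sub_rng.uniform(22.0, 28.0),
                            {"hr_response": 90.0, "spo2_response": 75.0},
                        )
                    )
                for _ in range(false_alarms_after):
                    extras.append(
                        ("low-amplitude-false-alarm", sub_rng.uniform(22.0, 28.0), {})
                    )
            for _ in range(n_pauses):
                extras.append(("pause", sub_rng.uniform(*pause_duration_range), {}))
            for kind, dur, kwargs in extras:
                hi = epoch_duration - dur - 30.0
                if hi <= 30.0:
                    continue  # epoch too short for this event
                for _attempt in range(50):
                    t0 = sub_rng.uniform(30.0, hi)
                    try:
                        rec, truth = inject_pause(rec, truth, t0, dur, kind, **kwargs)
                        break
                    except OverlapError:
                        continue
            halves.append((rec, truth))
        (rb, tb), (ra, ta) = halves
        combined = PhysioRecording(
            subject_id=rb.subject_id,
            ip=np.concatenate([rb.ip, ra.ip]),
            ip_rate=rb.ip_rate,
            hr=np.concatenate([rb.hr, ra.hr]),
            spo2=np.concatenate([rb.spo2, ra.spo2]),
            numeric_rate=rb.numeric_rate,
        )
        truth = GroundTruth(
            breath_times=np.concatenate([tb.breath_times, ta.breath_times + epoch_duration]),
            pause_intervals=(
                tb.pause_intervals
                + [
                    PauseInterval(p.start + epoch_duration, p.end + epoch_duration, p.kind)
                    for p in ta.pause_intervals
                ]
            ),
        )
        out.append((combined, truth, (0.0, epoch_duration), (epoch_duration, 2 * epoch_duration)))
    return out
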