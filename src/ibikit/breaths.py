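"""Adaptive-threshold breath detection and interbreath-interval series.

A breath onset is the point at which the filtered IP signal crosses an
adaptive amplitude threshold upward.  The threshold is ``alpha`` times
the SD of the non-masked filtered signal spanning the most recent
``n_breaths`` detected breaths (defaults alpha=0.4, n_breaths=15); until
that many breaths have accumulated, the SD is taken over the trailing
``init_window_s`` seconds of signal.  Because the threshold only updates
when a breath is accepted, it freezes during breathing pauses — noise in
an apnoeic segment stays below the pre-pause threshold — and during
masked artefact spans, where detection is suspended entirely.

Exact update contract (mirrored by the brute-force oracle used in the
tests): the threshold in force at sample ``i`` is the value computed at
the most recent update event (initialisation at the start of the
recording, or an accepted breath at some sample ``j < i``).  At an
accepted breath at sample ``j`` the new value is ``alpha * std`` over
the unmasked samples of ``[idx of (n_breaths)-th most recent breath, j]``
(population SD), or over ``[j - init_window + 1 sample, j]`` while fewer
than ``n_breaths`` breaths exist; if that window is empty or has zero
SD the previous threshold is retained.  The new value takes effect from
sample ``j + 1``.  A crossing at sample ``i`` requires samples ``i-1``
and ``i`` unmasked, ``signal[i-1] < thr <= signal[i]``, at least
``refractory_s`` since the last accepted breath, and the detector to be
armed: after each accepted breath (and after any masked sample) the
signal must first fall below ``rearm_fraction * thr`` before another
crossing counts.  The hysteresis prevents noise riding on the falling
limb of a breath from re-crossing the threshold and double-counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BreathTrain, FilteredIP, IBISeries


@dataclass(frozen=True)
class ThresholdParams:
    """Adaptive-threshold parameters; defaults are the validated optimum."""

    alpha: float = 0.4
    n_breaths: int = 15
    refractory_s: float = 0.3
    init_window_s: float = 15.0
    rearm_fraction: float = 0.5

    def validate(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.n_breaths < 1:
            raise ValueError("n_breaths must be >= 1")
        if self.refractory_s <= 0:
            raise ValueError("refractory_s must be > 0")
        if self.init_window_s <= 0:
            raise ValueError("init_window_s must be > 0")
        if not 0 <= self.rearm_fraction <= 1:
            raise ValueError("rearm_fraction must lie in [0, 1]")


def _window_std(x: np.ndarray, mask: np.ndarray, j0: int, j1: int) -> float:
    """Population SD of unmasked x[j0:j1+1]; 0.0 if the window is empty."""
    seg = x[j0 : j1 + 1][~mask[j0 : j1 + 1]]
    if seg.size == 0:
        return 0.0
    return float(seg.std())


def detect_breaths(
    filtered: FilteredIP, params: ThresholdParams | None = None
) -> BreathTrain:
    """Detect breath onsets as upward crossings of the adaptive threshold."""
    p = params or ThresholdParams()
    p.validate()
    x = filtered.signal
    mask = filtered.artefact_mask
    rate = filtered.rate
    dt = 1.0 / rate
    n = x.size
    init_samps = int(round(p.init_window_s * rate))
    if n < init_samps:
        raise ValueError(
            f"signal ({n * dt:.1f} s) shorter than init_window ({p.init_window_s} s)"
        )
    refr_samps = p.refractory_s * rate

    thr = p.alpha * _window_std(x, mask, 0, init_samps - 1)
    trace = np.empty(n)
    trace[0] = thr
    breaths: list[int] = []
    armed = True
    for i in range(1, n):
        trace[i] = thr
        if mask[i] or mask[i - 1]:
            armed = False
            continue
        if not armed:
            armed = x[i] < p.rearm_fraction * thr
            continue
        if not (x[i - 1] < thr <= x[i]):
            continue
        if breaths and (i - breaths[-1]) < refr_samps:
            continue
        breaths.append(i)
        armed = False
        if len(breaths) >= p.n_breaths:
            j0 = breaths[-p.n_breaths]
        else:
            j0 = max(0, i - init_samps + 1)
        sd = _window_std(x, mask, j0, i)
        if sd > 0:
            thr = p.alpha * sd
    return BreathTrain(
        breath_times=np.asarray(breaths, dtype=float) / rate,
        threshold_trace=trace,
        rate=rate,
    )


def compute_ibis(
    train: BreathTrain,
    mask: np.ndarray,
    rate: float | None = None,
    max_artefact_overlap: float = 0.1,
) -> IBISeries:
    """One interval per consecutive breath pair, invalidated by artefacts.

    An interval is ``valid=False`` when masked samples cover more than
    ``max_artefact_overlap`` of it — prolonged loss of signal is thereby
    distinguished from a genuine breathing pause.
    """
    rate = rate if rate is not None else train.rate
    mask = np.asarray(mask, dtype=bool)
    bt = train.breath_times
    if bt.size < 2:
        return IBISeries()
    starts, ends = bt[:-1], bt[1:]
    valid = np.empty(starts.size, dtype=bool)
    for k, (a, b) in enumerate(zip(starts, ends)):
        i0, i1 = int(round(a * rate)), int(round(b * rate))
        frac = float(mask[i0:i1].mean()) if i1 > i0 else 0.0
        valid[k] = frac <= max_artefact_overlap
    return IBISeries(start=starts, end=ends, valid=valid)


def detect_pauses(ibis: IBISeries, min_duration_s: float) -> list[tuple[float, float, float]]:
    """Valid intervals at least ``min_duration_s`` long, in order.

    With ``min_duration_s=5`` this is the breathing-pause set; with 20 it
    is the candidate central-apnoea set.
    """
    if min_duration_s <= 0:
        raise ValueError("min_duration_s must be > 0")
    out = []
    for a, b, v in zip(ibis.start, ibis.end, ibis.valid):
        if v and (b - a) >= min_duration_s:
            out.append((float(a), float(b), float(b - a)))
    return out


def respiratory_rate(
    train: BreathTrain,
    duration: float,
    window_s: float = 30.0,
    step_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Trailing-window respiratory rate trace in breaths/min.

    At grid time ``t`` the rate is ``60 * count / w`` where ``count`` is
    the number of breaths in ``(t - w, t]`` and ``w = min(t, window_s)``
    (the covered span, so the warm-up is unbiased).  Zero where no
    breaths have occurred.
    """
    if window_s <= 0 or step_s <= 0:
        raise ValueError("window_s and step_s must be > 0")
    times = np.arange(step_s, duration + 1e-9, step_s)
    bt = train.breath_times
    rates = np.zeros(times.size)
    for k, t in enumerate(times):
        w = min(t, window_s)
        count = np.count_nonzero((bt > t - w) & (bt <= t))
        rates[k] = 60.0 * count / w
    return times, rates


@dataclass(frozen=True)
class BreathMatch:
    """Detected-vs-reference breath matching summary."""

    n_matched: int
    n_missed: int
    n_spurious: int

    @property
    def sensitivity(self) -> float:
        total = self.n_matched + self.n_missed
        return self.n_matched / total if total else 0.0

    @property
    def false_discovery_rate(self) -> float:
        total = self.n_matched + self.n_spurious
        return self.n_spurious / total if total else 0.0


def match_breaths(
    detected: np.ndarray, reference: np.ndarray, tolerance_s: float = 0.25
) -> BreathMatch:
    """Greedy one-to-one matching of sorted breath-time sequences."""
    det = np.sort(np.asarray(detected, dtype=float))
    ref = np.sort(np.asarray(reference, dtype=float))
    i = j = matched = 0
    while i < det.size and j < ref.size:
        if abs(det[i] - ref[j]) <= tolerance_s:
            matched += 1
            i += 1
            j += 1
        elif det[i] < ref[j]:
            i += 1
        else:
            j += 1
    return BreathMatch(
        n_matched=matched,
        n_missed=ref.size - matched,
        n_spurious=det.size - matched,
    )


class BreathDetector:
    """sklearn-style stateless transformer wrapping :func:`detect_breaths`."""

    def __init__(
        self,
        alpha: float = 0.4,
        n_breaths: int = 15,
        refractory_s: float = 0.3,
        init_window_s: float = 15.0,
        max_artefact_overlap: float = 0.1,
    ):
        self.alpha = alpha
        self.n_breaths = n_breaths
        self.refractory_s = refractory_s
        self.init_window_s = init_window_s
        self.max_artefact_overlap = max_artefact_overlap

    def get_params(self, deep: bool = True) -> dict:
        return {
            "alpha": self.alpha,
            "n_breaths": self.n_breaths,
            "refractory_s": self.refractory_s,
            "init_window_s": self.init_window_s,
            "max_artefact_overlap": self.max_artefact_overlap,
        }

    def set_params(self, **params) -> "BreathDetector":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "BreathDetector":
        return self

    def transform(self, filtered: FilteredIP) -> BreathTrain:
        params = ThresholdParams(
            alpha=self.alpha,
            n_breaths=self.n_breaths,
            refractory_s=self.refractory_s,
            init_window_s=self.init_window_s,
        )
        return detect_breaths(filtered, params)

    def transform_ibis(self, filtered: FilteredIP) -> IBISeries:
        """Convenience: detect breaths and derive the IBI series."""
        train = self.transform(filtered)
        return compute_ibis(
            train, filtered.artefact_mask, filtered.rate, self.max_artefact_overlap
        )
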