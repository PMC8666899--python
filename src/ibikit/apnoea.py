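"""Central-apnoea candidate extraction, features and SVM classification.

A candidate apnoea is any valid interbreath interval of at least 20 s.
Low-amplitude IP segments (poor electrode contact, shallow breathing)
produce such candidates without any true cessation of breathing, so a
linear support-vector machine separates true central apnoeas from these
false alarms using five features: the RMS of the filtered IP during the
episode, in the 10 s before it and the 10 s after it, and the change in
heart rate and in oxygen saturation over the 60 s from onset (window
minimum minus the 10 s pre-onset median; negative = drop).

Evaluation follows leave-one-subject-out cross-validation with accuracy,
false-positive rate, false-negative rate and Matthews correlation
coefficient.  Utilities for bradycardia (<100 bpm, episodes >= 15 s) and
desaturation (<80 %) co-occurrence are included.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import LeaveOneGroupOut
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .core import FilteredIP, IBISeries

APNOEA_IBI_THRESHOLD_S = 20.0
BRADYCARDIA_BPM = 100.0
DESATURATION_PCT = 80.0


@dataclass(frozen=True)
class ApnoeaCandidate:
    """An IBI >= 20 s episode, in recording-local seconds."""

    subject_id: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.duration < APNOEA_IBI_THRESHOLD_S - 1e-9:
            raise ValueError("candidate apnoeas require duration >= 20 s")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class ApnoeaFeatures:
    """Five classifier features; NaN marks a window with <50 % coverage."""

    rms_during: float
    rms_pre10: float
    rms_post10: float
    delta_hr60: float
    delta_spo2_60: float

    @property
    def missing(self) -> bool:
        return not np.all(np.isfinite(self.as_array()))

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.rms_during, self.rms_pre10, self.rms_post10, self.delta_hr60, self.delta_spo2_60]
        )


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: float
    fpr: float
    fnr: float
    mcc: float
    tp: int
    fp: int
    fn: int
    tn: int


def extract_candidates(
    ibis: IBISeries,
    threshold_s: float = APNOEA_IBI_THRESHOLD_S,
    subject_id: str = "",
) -> list[ApnoeaCandidate]:
    """All valid intervals with duration >= ``threshold_s`` (inclusive)."""
    out = []
    for a, b, v in zip(ibis.start, ibis.end, ibis.valid):
        if v and (b - a) >= threshold_s - 1e-12:
            out.append(ApnoeaCandidate(subject_id=subject_id, start=float(a), end=float(b)))
    return out


def _masked_rms(x: np.ndarray, mask: np.ndarray, i0: int, i1: int, n: int) -> tuple[float, float]:
    """RMS over unmasked samples of [i0, i1) and the usable coverage fraction."""
    width = i1 - i0
    lo, hi = max(0, i0), min(n, i1)
    if width <= 0 or hi <= lo:
        return math.nan, 0.0
    seg = x[lo:hi][~mask[lo:hi]]
    coverage = seg.size / width
    rms = float(np.sqrt(np.mean(seg**2))) if seg.size else math.nan
    return rms, coverage


def _numeric_window(x: np.ndarray, rate: float, t0: float, t1: float) -> tuple[np.ndarray, float]:
    width = int(round((t1 - t0) * rate))
    lo, hi = int(round(t0 * rate)), int(round(t1 * rate))
    lo2, hi2 = max(0, lo), min(x.size, hi)
    if width <= 0 or hi2 <= lo2:
        return np.empty(0), 0.0
    seg = x[lo2:hi2]
    fin = seg[np.isfinite(seg)]
    return fin, fin.size / width


def extract_features(
    candidate: ApnoeaCandidate,
    filtered: FilteredIP,
    hr: np.ndarray,
    spo2: np.ndarray,
    numeric_rate: float = 1.0,
    pre_window_s: float = 10.0,
    post_window_s: float = 10.0,
    response_window_s: float = 60.0,
    min_coverage: float = 0.5,
) -> ApnoeaFeatures:
    """Compute the five features; windows under ``min_coverage`` give NaN."""
    x = filtered.signal
    mask = filtered.artefact_mask
    rate = filtered.rate
    n = x.size
    s, e = candidate.start, candidate.end

    def rms_or_nan(t0: float, t1: float) -> float:
        val, cov = _masked_rms(x, mask, int(round(t0 * rate)), int(round(t1 * rate)), n)
        return val if cov >= min_coverage else math.nan

    rms_during = rms_or_nan(s, e)
    rms_pre = rms_or_nan(s - pre_window_s, s)
    rms_post = rms_or_nan(e, e + post_window_s)

    hr = np.asarray(hr, dtype=float)
    spo2 = np.asarray(spo2, dtype=float)

    def delta_or_nan(chan: np.ndarray) -> float:
        win, cov_w = _numeric_window(chan, numeric_rate, s, s + response_window_s)
        base, cov_b = _numeric_window(chan, numeric_rate, s - pre_window_s, s)
        if cov_w < min_coverage or cov_b < min_coverage:
            return math.nan
        return float(np.min(win) - np.median(base))

    return ApnoeaFeatures(
        rms_during=rms_during,
        rms_pre10=rms_pre,
        rms_post10=rms_post,
        delta_hr60=delta_or_nan(hr),
        delta_spo2_60=delta_or_nan(spo2),
    )


class ApnoeaClassifier(ClassifierMixin, BaseEstimator):
    """Linear soft-margin SVM over standardised apnoea features.

    Deterministic given the data.  After fitting, predictions use only
    the stored linear parameters (``weights_``, ``bias_``,
    ``feature_means_``, ``feature_scales_``), so a model round-tripped
    through its JSON representation predicts identically.
    """

    def __init__(self, C: float = 1.0, standardise: bool = True):
        self.C = C
        self.standardise = standardise

    def fit(self, X, y) -> "ApnoeaClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain NaN/inf; drop incomplete candidates first")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("training data must contain exactly two classes")
        if self.standardise:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            mu = np.zeros(X.shape[1])
            sd = np.ones(X.shape[1])
        svc = SVC(kernel="linear", C=self.C)
        svc.fit((X - mu) / sd, y)
        self.classes_ = svc.classes_
        self.weights_ = svc.coef_.ravel().copy()
        self.bias_ = float(svc.intercept_[0])
        self.feature_means_ = mu
        self.feature_scales_ = sd
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        Z = (X - self.feature_means_) / self.feature_scales_
        return Z @ self.weights_ + self.bias_

    def predict(self, X) -> np.ndarray:
        dec = self.decision_function(X)
        return self.classes_[(dec > 0).astype(int)]

    def to_dict(self) -> dict:
        check_is_fitted(self, "weights_")
        return {
            "weights": self.weights_.tolist(),
            "bias": self.bias_,
            "feature_means": self.feature_means_.tolist(),
            "feature_scales": self.feature_scales_.tolist(),
            "classes": self.classes_.tolist(),
            "C": self.C,
            "standardise": self.standardise,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ApnoeaClassifier":
        model = cls(C=d.get("C", 1.0), standardise=d.get("standardise", True))
        model.weights_ = np.asarray(d["weights"], dtype=float)
        model.bias_ = float(d["bias"])
        model.feature_means_ = np.asarray(d["feature_means"], dtype=float)
        model.feature_scales_ = np.asarray(d["feature_scales"], dtype=float)
        model.classes_ = np.asarray(d["classes"])
        model.n_features_in_ = model.weights_.size
        return model

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load_json(cls, path) -> "ApnoeaClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_classifier(
    features: np.ndarray, labels: np.ndarray, standardise: bool = True, C: float = 1.0
) -> ApnoeaClassifier:
    """Fit a linear SVM on (complete) feature rows."""
    return ApnoeaClassifier(C=C, standardise=standardise).fit(features, labels)


def compute_metrics(predicted, actual) -> ClassificationMetrics:
    """Confusion-matrix metrics with the positive class being 1/True.

    MCC is reported as 0 when any confusion-matrix marginal is zero
    (the undefined-denominator convention); FPR/FNR are 0 when their
    denominators are empty.
    """
    pred = np.asarray(predicted).astype(int)
    act = np.asarray(actual).astype(int)
    if pred.shape != act.shape:
        raise ValueError("predicted and actual must have equal length")
    tp = int(np.sum((pred == 1) & (act == 1)))
    fp = int(np.sum((pred == 1) & (act == 0)))
    fn = int(np.sum((pred == 0) & (act == 1)))
    tn = int(np.sum((pred == 0) & (act == 0)))
    total = tp + fp + fn + tn
    accuracy = (tp + tn) / total if total else 0.0
    fpr = fp / (fp + tn) if (fp + tn) else 0.0
    fnr = fn / (fn + tp) if (fn + tp) else 0.0
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
    return ClassificationMetrics(accuracy, fpr, fnr, mcc, tp, fp, fn, tn)


def loso_cv(
    features: np.ndarray,
    labels: np.ndarray,
    subject_ids: np.ndarray,
    C: float = 1.0,
    standardise: bool = True,
) -> ClassificationMetrics:
    """Leave-one-subject-out cross-validation, metrics pooled over folds.

    A training fold that degenerates to a single class predicts that
    class for the held-out subject.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    groups = np.asarray(subject_ids)
    if np.unique(groups).size < 2:
        raise ValueError("leave-one-subject-out requires at least two subjects")
    pred = np.empty_like(y)
    for train_idx, test_idx in LeaveOneGroupOut().split(X, y, groups):
        if np.unique(y[train_idx]).size < 2:
            pred[test_idx] = y[train_idx][0]
            continue
        model = ApnoeaClassifier(C=C, standardise=standardise).fit(X[train_idx], y[train_idx])
        pred[test_idx] = model.predict(X[test_idx])
    return compute_metrics(pred, y)


@dataclass(frozen=True)
class AnnotatedPause:
    start: float
    end: float
    bradycardia: bool
    desaturation: bool

    @property
    def duration(self) -> float:
        return self.end - self.start


def cooccurrence_events(
    pauses,
    hr: np.ndarray,
    spo2: np.ndarray,
    numeric_rate: float = 1.0,
    hr_threshold: float = BRADYCARDIA_BPM,
    spo2_threshold: float = DESATURATION_PCT,
    extension_s: float = 60.0,
) -> list[AnnotatedPause]:
    """Flag each pause for bradycardia / desaturation co-occurrence.

    A pause is bradycardic if HR drops below ``hr_threshold`` at any
    point during [start, end + extension_s]; desaturation likewise for
    SpO2 below ``spo2_threshold``.
    """
    hr = np.asarray(hr, dtype=float)
    spo2 = np.asarray(spo2, dtype=float)
    out = []
    for p in pauses:
        start, end = float(p[0]), float(p[1])
        lo = max(0, int(round(start * numeric_rate)))
        hi = int(round((end + extension_s) * numeric_rate)) + 1
        hseg = hr[lo:hi]
        sseg = spo2[lo:hi]
        brady = bool(np.any(hseg[np.isfinite(hseg)] < hr_threshold))
        desat = bool(np.any(sseg[np.isfinite(sseg)] < spo2_threshold))
        out.append(AnnotatedPause(start, end, brady, desat))
    return out


def find_bradycardias(
    hr: np.ndarray,
    numeric_rate: float = 1.0,
    threshold_bpm: float = BRADYCARDIA_BPM,
    min_duration_s: float = 15.0,
) -> list[tuple[float, float]]:
    """Maximal runs of HR < threshold lasting at least ``min_duration_s``.

    A run of k consecutive sub-threshold samples covers k/rate seconds.
    """
    hr = np.asarray(hr, dtype=float)
    below = np.isfinite(hr) & (hr < threshold_bpm)
    out = []
    i = 0
    n = below.size
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            duration = (j - i) / numeric_rate
            if duration >= min_duration_s - 1e-12:
                out.append((i / numeric_rate, j / numeric_rate))
            i = j
        else:
            i += 1
    return out
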