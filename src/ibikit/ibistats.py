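"""IBI-distribution summaries and paired before/after epoch comparisons.

Six metrics summarise a subject's respiratory state over an epoch: the
time-averaged respiratory rate and, over the valid interbreath
intervals, the mean, median and SD plus the proportions of IBIs longer
than 5 s and longer than 10 s (strict inequalities).  Before/after
comparisons use a paired non-parametric t-test: the statistic is the
paired t on the per-subject differences and its null distribution is
built by random sign flips of the difference vector (10 000 permutations
by default; the full 2^n enumeration when it fits inside the permutation
budget, making the test exact).  P-values across the six metrics are
adjusted with Hochberg's step-up method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .breaths import ThresholdParams, compute_ibis, detect_breaths, respiratory_rate
from .core import IBISeries, PhysioRecording
from .preprocess import PreprocessParams, preprocess

EPOCH_METRICS = ("mean_rr", "mean_ibi", "median_ibi", "sd_ibi", "prop_gt5", "prop_gt10")


@dataclass(frozen=True)
class IBISummary:
    """Distribution summary over the valid IBIs of one epoch."""

    mean_ibi: float
    median_ibi: float
    sd_ibi: float
    prop_gt5: float
    prop_gt10: float
    mean_rr: float
    n_ibis: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_rr": self.mean_rr,
            "mean_ibi": self.mean_ibi,
            "median_ibi": self.median_ibi,
            "sd_ibi": self.sd_ibi,
            "prop_gt5": self.prop_gt5,
            "prop_gt10": self.prop_gt10,
        }


@dataclass(frozen=True)
class PermutationResult:
    t_statistic: float
    p_uncorrected: float
    n_permutations: int
    seed: int
    exact: bool
    p_corrected: float = math.nan


@dataclass
class EpochComparison:
    """Per-metric permutation results plus per-subject epoch summaries."""

    per_subject: pd.DataFrame
    results: dict[str, PermutationResult]
    group_means: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric in EPOCH_METRICS:
            r = self.results[metric]
            rows.append(
                {
                    "metric": metric,
                    "mean_before": self.group_means.loc[metric, "before"],
                    "mean_after": self.group_means.loc[metric, "after"],
                    "t_statistic": r.t_statistic,
                    "p_uncorrected": r.p_uncorrected,
                    "p_corrected": r.p_corrected,
                }
            )
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        df = self.to_frame()
        lines = [
            "| Metric | Mean before | Mean after | t-statistic | Uncorrected p | Corrected p |",
            "| --- | --- | --- | --- | --- | --- |",
        ]
        for _, row in df.iterrows():
            lines.append(
                f"| {row['metric']} | {row['mean_before']:.4g} | {row['mean_after']:.4g} "
                f"| {row['t_statistic']:.3g} | {row['p_uncorrected']:.4g} "
                f"| {row['p_corrected']:.4g} |"
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def ibi_summary(ibis: IBISeries, rr_trace: tuple[np.ndarray, np.ndarray] | None = None) -> IBISummary:
    """Summarise valid IBIs; proportions use strict 'longer than' rules."""
    d = ibis.valid_durations
    if d.size == 0:
        raise ValueError("no valid IBIs to summarise")
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    mean_rr = float(np.mean(rr_trace[1])) if rr_trace is not None else math.nan
    return IBISummary(
        mean_ibi=float(np.mean(d)),
        median_ibi=float(np.median(d)),
        sd_ibi=sd,
        prop_gt5=float(np.mean(d > 5.0)),
        prop_gt10=float(np.mean(d > 10.0)),
        mean_rr=mean_rr,
        n_ibis=int(d.size),
    )


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t statistic along the last axis; 0/0 -> 0, m/0 -> signed inf."""
    d = np.atleast_2d(diffs)
    n = d.shape[-1]
    m = d.mean(axis=-1)
    s = d.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / math.sqrt(n))
        t = np.where(s == 0, np.where(m == 0, 0.0, np.sign(m) * np.inf), t)
    return t if diffs.ndim > 1 else t[0]


def paired_permutation_test(
    before: Sequence[float],
    after: Sequence[float],
    n_perm: int = 10000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> PermutationResult:
    """Sign-flip permutation test on paired differences (after - before).

    When ``2**n <= n_perm`` every sign assignment is enumerated and the
    test is exact (p = count / 2**n, identity included); otherwise
    ``n_perm`` random sign vectors are drawn and the "+1" convention
    ``p = (1 + count) / (1 + n_perm)`` guarantees validity and p > 0.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape or b.ndim != 1:
        raise ValueError("before and after must be equal-length 1-D vectors")
    n = b.size
    if n < 2:
        raise ValueError("need at least two pairs")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be two-sided, greater or less")
    d = a - b
    t_obs = float(_paired_t(d))

    exact = 2**n <= n_perm
    if exact:
        total = 2**n
        bits = (np.arange(total)[:, None] >> np.arange(n)) & 1
        signs = 2.0 * bits - 1.0
    else:
        total = n_perm
        rng = np.random.default_rng(seed)
        signs = rng.integers(0, 2, size=(n_perm, n)) * 2.0 - 1.0
    t_perm = _paired_t(signs * d)

    tol = 1e-12 * max(1.0, abs(t_obs) if np.isfinite(t_obs) else 1.0)
    if alternative == "two-sided":
        count = int(np.sum(np.abs(t_perm) >= abs(t_obs) - tol))
    elif alternative == "greater":
        count = int(np.sum(t_perm >= t_obs - tol))
    else:
        count = int(np.sum(t_perm <= t_obs + tol))
    p = count / total if exact else (1 + count) / (1 + total)
    return PermutationResult(
        t_statistic=t_obs,
        p_uncorrected=float(p),
        n_permutations=total,
        seed=seed,
        exact=exact,
    )


def hochberg_correct(p_values: Sequence[float]) -> np.ndarray:
    """Hochberg step-up adjusted p-values (order-preserving, capped at 1).

    With ascending p_(1) <= ... <= p_(m): adj_(m) = p_(m) and
    adj_(i) = min(adj_(i+1), (m - i + 1) * p_(i)).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj = np.empty(m)
    adj[m - 1] = sorted_p[m - 1]
    for i in range(m - 2, -1, -1):
        adj[i] = min(adj[i + 1], (m - i) * sorted_p[i])
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def epoch_summary(
    recording: PhysioRecording,
    epoch: tuple[float, float],
    preprocess_params: PreprocessParams | None = None,
    threshold_params: ThresholdParams | None = None,
    max_artefact_overlap: float = 0.1,
    rr_window_s: float = 30.0,
) -> IBISummary:
    """Run the full pipeline on one epoch of a recording."""
    sub = recording.crop(*epoch)
    filtered = preprocess(sub, preprocess_params)
    train = detect_breaths(filtered, threshold_params)
    ibis = compute_ibis(train, filtered.artefact_mask, filtered.rate, max_artefact_overlap)
    rr = respiratory_rate(train, sub.duration, window_s=rr_window_s)
    return ibi_summary(ibis, rr_trace=rr)


def compare_summaries(
    before: Mapping[str, IBISummary],
    after: Mapping[str, IBISummary],
    n_perm: int = 10000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> EpochComparison:
    """Paired comparison of per-subject epoch summaries across metrics."""
    if set(before) != set(after):
        raise ValueError("subject sets differ between epochs")
    subjects = sorted(before)
    if len(subjects) < 2:
        raise ValueError("need at least two subjects")
    rows = []
    for s in subjects:
        for epoch, summ in (("before", before[s]), ("after", after[s])):
            rows.append({"subject": s, "epoch": epoch, **summ.as_dict()})
    per_subject = pd.DataFrame(rows)

    metric_seeds = np.random.SeedSequence(seed).generate_state(len(EPOCH_METRICS))
    results: dict[str, PermutationResult] = {}
    means = {}
    for k, metric in enumerate(EPOCH_METRICS):
        b = np.array([before[s].as_dict()[metric] for s in subjects])
        a = np.array([after[s].as_dict()[metric] for s in subjects])
        results[metric] = paired_permutation_test(
            b, a, n_perm=n_perm, seed=int(metric_seeds[k] % 2**31), alternative=alternative
        )
        means[metric] = {"before": float(b.mean()), "after": float(a.mean())}
    corrected = hochberg_correct([results[m].p_uncorrected for m in EPOCH_METRICS])
    for k, metric in enumerate(EPOCH_METRICS):
        results[metric] = replace(results[metric], p_corrected=float(corrected[k]))
    group_means = pd.DataFrame(means).T.loc[list(EPOCH_METRICS)]
    return EpochComparison(per_subject=per_subject, results=results, group_means=group_means)


def compare_epochs(
    recordings: Sequence[PhysioRecording],
    epoch_before: tuple[float, float],
    epoch_after: tuple[float, float],
    n_perm: int = 10000,
    seed: int = 0,
    alternative: str = "two-sided",
    preprocess_params: PreprocessParams | None = None,
    threshold_params: ThresholdParams | None = None,
    max_artefact_overlap: float = 0.1,
    rr_window_s: float = 30.0,
) -> EpochComparison:
    """Full-pipeline before/after comparison for a cohort of recordings."""
    before: dict[str, IBISummary] = {}
    after: dict[str, IBISummary] = {}
    for rec in recordings:
        if rec.subject_id in before:
            raise ValueError(f"duplicate subject id {rec.subject_id!r}")
        for store, epoch in ((before, epoch_before), (after, epoch_after)):
            try:
                store[rec.subject_id] = epoch_summary(
                    rec,
                    epoch,
                    preprocess_params,
                    threshold_params,
                    max_artefact_overlap,
                    rr_window_s,
                )
            except ValueError as err:
                raise ValueError(
                    f"subject {rec.subject_id!r}, epoch {epoch}: {err}"
                ) from err
    return compare_summaries(before, after, n_perm=n_perm, seed=seed, alternative=alternative)
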