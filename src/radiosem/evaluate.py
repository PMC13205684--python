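"""Evaluation protocol primitives: subject-level K-fold splits, 10-s/5-s
segmenting, percentile bootstrap confidence intervals, and correlation
reports with two-sided tests under the zero-correlation null."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats


@dataclass
class EvalProtocol:
    k_folds: int = 7
    segment_s: float = 10.0
    stride_s: float = 5.0
    bootstrap_B: int = 2000
    alpha_level: float = 0.001
    seed: int = 0


def kfold_split(subject_ids, k: int = 7, seed: int = 0) -> dict[str, int]:
    """Deterministic subject-disjoint partition into k folds.

    Fold sizes differ by at most one; every subject lands in exactly one
    fold.
    """
    subjects = list(subject_ids)
    if len(set(subjects)) != len(subjects):
        raise ValueError("duplicate subject ids")
    if len(subjects) < k:
        raise ValueError(f"cannot split {len(subjects)} subjects into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    assignment = {}
    for pos, idx in enumerate(order):
        assignment[subjects[idx]] = pos % k
    return assignment


def assert_no_leakage(train_subjects, test_subjects) -> None:
    overlap = set(train_subjects) & set(test_subjects)
    if overlap:
        raise RuntimeError(f"subject leakage between folds: {sorted(overlap)[:5]}")


def segment_starts(duration_s: float, segment_s: float = 10.0, stride_s: float = 5.0) -> np.ndarray:
    """Start times of half-open [t, t+segment) windows at the given stride;
    trailing partial windows are dropped."""
    starts = []
    t = 0.0
    while t + segment_s <= duration_s + 1e-9:
        starts.append(t)
        t += stride_s
    return np.array(starts)


def segment_stream(
    waveform: np.ndarray,
    fs_hz: float,
    segment_s: float = 10.0,
    stride_s: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Slice a (..., T) stream into 10-s segments every 5 s.

    Returns (segments, start_times); segments stack along a new first
    axis.
    """
    w = np.asarray(waveform)
    n = w.shape[-1]
    seg_len = int(round(segment_s * fs_hz))
    step = int(round(stride_s * fs_hz))
    starts_idx = range(0, n - seg_len + 1, step)
    segs = np.stack([w[..., s : s + seg_len] for s in starts_idx]) if n >= seg_len else np.empty((0,) + w.shape[:-1] + (seg_len,))
    return segs, np.array([s / fs_hz for s in starts_idx])


def bootstrap_ci(
    values: np.ndarray,
    B: int = 2000,
    level: float = 0.95,
    statistic=np.mean,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of a statistic over the given values."""
    v = np.asarray(values, dtype=float)
    if B < 1:
        raise ValueError("bootstrap_B must be >= 1")
    if v.size == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    stats = np.array(
        [statistic(v[rng.integers(0, v.size, v.size)]) for _ in range(B)]
    )
    lo = (1 - level) / 2
    return (
        float(np.quantile(stats, lo)),
        float(np.quantile(stats, 1 - lo)),
    )


def correlation_report(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Pearson R with a two-sided p-value under the zero-correlation null."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size != truth.size:
        raise ValueError("length mismatch")
    if pred.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    r, p = sp_stats.pearsonr(pred, truth)
    return float(r), float(p)
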