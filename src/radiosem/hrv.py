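"""Rhythm analysis: R-peak detection, inter-beat intervals, HRV metrics,
Poincare pairs, windowed trends and the daily-life outlier filter.

The detector is a Pan-Tompkins-family pipeline (band-pass, derivative,
squaring, moving-window integration, adaptive threshold with a 200 ms
refractory period). It is self-contained; ``detect_r_peaks`` accepts an
optional ``detector`` callable as an adapter hook for external toolkits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

log = logging.getLogger(__name__)

IBI_GUARD_MS = (250.0, 3000.0)  # physiological plausibility guard


@dataclass
class HRVSummary:
    ibi_ms: np.ndarray
    mean_hr_bpm: float
    rmssd_ms: float
    sdnn_ms: float
    pnn50_pct: float
    window: tuple[float, float] | None = None


def detect_r_peaks(
    ecg: np.ndarray,
    fs_hz: float,
    refractory_s: float = 0.2,
    detector=None,
) -> np.ndarray:
    """Detect R-peak times (seconds) in a single-lead ECG.

    Adaptive (quantile-based) thresholding makes detection invariant to
    amplitude scaling; candidate peaks closer than the refractory period
    are fused, keeping the larger one.
    """
    ecg = np.asarray(ecg, dtype=float).ravel()
    if ecg.size / fs_hz < 2.0:
        raise ValueError("need at least 2 s of signal")
    if detector is not None:
        return np.asarray(detector(ecg, fs_hz), dtype=float)
    if np.ptp(ecg) == 0:
        warnings.warn("flat signal: no beats detected", stacklevel=2)
        return np.array([])

    nyq = fs_hz / 2
    high = min(35.0, 0.9 * nyq)
    sos = sp_signal.butter(2, [5.0 / nyq, high / nyq], btype="bandpass", output="sos")
    xf = sp_signal.sosfiltfilt(sos, ecg)
    deriv = np.gradient(xf)
    sq = deriv**2
    win = max(1, int(round(0.15 * fs_hz)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    thr = 0.2 * np.quantile(integ, 0.99)
    dist = max(1, int(round(refractory_s * fs_hz)))
    locs, _ = sp_signal.find_peaks(integ, height=thr, distance=dist)
    if locs.size == 0:
        warnings.warn("no beats above threshold", stacklevel=2)
        return np.array([])

    # refine each candidate to the raw-signal maximum nearby
    half = int(round(0.10 * fs_hz))
    refined = []
    for loc in locs:
        lo, hi = max(0, loc - half), min(ecg.size, loc + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.array(sorted(set(refined)))

    # enforce refractory after refinement: keep the larger of fused peaks
    keep: list[int] = []
    for r in refined:
        if keep and (r - keep[-1]) < dist:
            if ecg[r] > ecg[keep[-1]]:
                keep[-1] = r
        else:
            keep.append(r)
    return np.array(keep) / fs_hz


def compute_ibi(beat_times: np.ndarray) -> np.ndarray:
    """Successive inter-beat intervals in milliseconds."""
    bt = np.asarray(beat_times, dtype=float)
    if bt.size < 2:
        raise ValueError("insufficient beats: need at least 2")
    if not np.all(np.diff(bt) > 0):
        raise ValueError("beat times must be strictly increasing")
    return np.diff(bt) * 1000.0


def hrv_metrics(
    ibi_ms: np.ndarray,
    window: tuple[float, float] | None = None,
    sdnn_ddof: int = 0,
    apply_guard: bool = True,
) -> HRVSummary:
    """Standard time-domain HRV statistics from an IBI series.

    rmssd = sqrt(mean(diff^2)); sdnn = population SD (``sdnn_ddof=0``;
    switchable to the sample SD); pnn50 = percent of successive
    differences strictly exceeding 50 ms; mean HR = 60000 / mean IBI.
    Intervals outside the physiological guard (250-3000 ms) are dropped
    first when ``apply_guard`` is set.
    """
    ibi = np.asarray(ibi_ms, dtype=float)
    if ibi.size == 0:
        raise ValueError("empty IBI series")
    if apply_guard:
        ok = (ibi > IBI_GUARD_MS[0]) & (ibi < IBI_GUARD_MS[1])
        ibi = ibi[ok]
        if ibi.size == 0:
            raise ValueError("no physiologically plausible intervals")
    diffs = np.diff(ibi)
    rmssd = float(np.sqrt(np.mean(diffs**2))) if diffs.size else 0.0
    sdnn = float(ibi.std(ddof=sdnn_ddof))
    pnn50 = float(100.0 * np.count_nonzero(np.abs(diffs) > 50.0) / diffs.size) if diffs.size else 0.0
    return HRVSummary(
        ibi_ms=ibi,
        mean_hr_bpm=float(60000.0 / ibi.mean()),
        rmssd_ms=rmssd,
        sdnn_ms=sdnn,
        pnn50_pct=pnn50,
        window=window,
    )


def poincare_pairs(ibi_ms: np.ndarray) -> np.ndarray:
    """Successive (IBI_k, IBI_{k+1}) pairs for a Poincare plot; shape (n-1, 2)."""
    ibi = np.asarray(ibi_ms, dtype=float)
    if ibi.size < 2:
        return np.empty((0, 2))
    return np.stack([ibi[:-1], ibi[1:]], axis=1)


def windowed_hrv(
    beat_times: np.ndarray,
    window_s: float = 300.0,
    step_s: float = 300.0,
    duration_s: float | None = None,
) -> list[HRVSummary]:
    """HRV summaries over half-open windows [start, start + window_s).

    A beat landing exactly on a boundary belongs to the later window.
    Windows containing fewer than 2 beats are skipped (logged).
    """
    bt = np.asarray(beat_times, dtype=float)
    end = duration_s if duration_s is not None else (bt[-1] if bt.size else 0.0)
    out: list[HRVSummary] = []
    start = 0.0
    while start + window_s <= end + 1e-9:
        sel = bt[(bt >= start) & (bt < start + window_s)]
        if sel.size >= 2:
            out.append(
                hrv_metrics(compute_ibi(sel), window=(start, start + window_s))
            )
        else:
            log.info("window [%s, %s) skipped: fewer than 2 beats", start, start + window_s)
        start += step_s
    return out


def filter_window_outliers(values: np.ndarray) -> np.ndarray:
    """One-sided 1.5xIQR rule on per-window predictions.

    Values strictly above Q3 + 1.5*IQR are discarded; low values are
    always retained. Quartiles use linear interpolation.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 windows for the IQR rule")
    q1, q3 = np.percentile(v, [25, 75])
    bound = q3 + 1.5 * (q3 - q1)
    return v[v <= bound]
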