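"""Segmentation and cleaning of labeled ECG records.

The pipeline is: choose a segment duration that divides the record evenly
(durations 7, 11, 13, 14, 16, 17 and 19 s do not divide a 30-minute
record and are excluded), cut non-overlapping consecutive segments,
detect and validate R-peaks, drop segments with fewer than two validated
QRS complexes, and z-score each surviving segment.

The R-peak detector is a Pan-Tompkins-family heuristic: a per-window
dynamic amplitude threshold (mean + k·sd over a sliding window) selects
candidate local maxima, candidates inside a refractory period are merged
keeping the larger, and each survivor must pass a QRS validation check on
prominence (relative to the window's max-minus-median swing) and width.
All four constants are configurable through :class:`RPeakParams`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sp_signal

from .io_ecg import ECGRecord, Segment, SegmentSet

__all__ = [
    "valid_durations",
    "segment_record",
    "RPeakParams",
    "RPeakResult",
    "detect_rpeaks",
    "filter_segments",
    "DegenerateSegmentError",
    "NormalizedSegment",
    "zscore",
    "zscore_set",
    "match_peaks",
]


def valid_durations(record_seconds: int, dmin: int = 2, dmax: int = 20) -> list[int]:
    """Durations in [dmin, dmax] seconds that divide the record evenly.

    For a 30-minute (1800 s) record and the 2-20 s sweep this yields the
    twelve usable durations; 7, 11, 13, 14, 16, 17 and 19 s are excluded
    because 1800 is not divisible by them.
    """
    if record_seconds <= 0 or dmin <= 0 or dmax <= 0:
        raise ValueError("record_seconds, dmin and dmax must all be positive")
    if not dmin <= dmax <= record_seconds:
        raise ValueError(f"need 0 < dmin <= dmax <= record_seconds, got "
                         f"({record_seconds}, {dmin}, {dmax})")
    return [d for d in range(dmin, dmax + 1) if record_seconds % d == 0]


def segment_record(record: ECGRecord, duration_s: int) -> SegmentSet:
    """Cut a record into non-overlapping consecutive fixed-duration segments.

    The trailing remainder shorter than one segment is dropped; labels are
    inherited from the record.  A record shorter than one segment yields
    an empty set with a warning.
    """
    seg_len = int(round(duration_s * record.fs))
    if seg_len < 2:
        raise ValueError(f"segment of {duration_s}s at {record.fs} Hz has <2 samples")
    n_seg = len(record.samples) // seg_len
    if n_seg == 0:
        warnings.warn(
            f"record {record.subject_id} ({record.duration_s:.0f}s) is shorter than "
            f"one {duration_s}s segment; returning an empty set",
            stacklevel=2,
        )
    segments = [
        Segment(
            samples=record.samples[i * seg_len : (i + 1) * seg_len],
            fs=record.fs,
            subject_id=record.subject_id,
            start=i * seg_len,
            label=record.label,
        )
        for i in range(n_seg)
    ]
    return SegmentSet(segments=segments, duration_s=duration_s, fs=record.fs)


# --------------------------------------------------------------------------
# R-peak detection
# --------------------------------------------------------------------------

@dataclass
class RPeakParams:
    """Detector settings; defaults follow standard QRS-detection practice."""

    window_s: float = 1.5        # sliding window for the dynamic threshold
    threshold_k: float = 1.0     # threshold = window mean + k * window sd
    refractory_s: float = 0.2    # minimum R-R separation; merged keeping the larger
    prominence_frac: float = 0.5 # QRS must rise >= frac * (window max - window median)
    max_qrs_width_s: float = 0.16  # half-prominence width bound for a QRS
    t_wave_window_s: float = 0.36  # T-wave discrimination lookback after a QRS
    t_wave_ratio: float = 0.5      # reject if < ratio * previous QRS height in window


@dataclass
class RPeakResult:
    """Detected peaks: merged candidates, validated QRS subset, thresholds."""

    peak_indices: np.ndarray       # refractory-merged candidate peaks
    qrs_indices: np.ndarray        # the validated QRS subset
    threshold_trace: np.ndarray    # per-window dynamic threshold values
    n_valid_qrs: int = field(init=False)

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        self.qrs_indices = np.asarray(self.qrs_indices, dtype=int)
        if np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        self.n_valid_qrs = len(self.qrs_indices)


def detect_rpeaks(segment: Segment, params: Optional[RPeakParams] = None) -> RPeakResult:
    """Dynamic-threshold R-peak detection with refractory merge and QRS validation.

    Deterministic for a fixed input and parameter set.  An all-constant
    signal yields zero peaks (not an error).
    """
    params = params or RPeakParams()
    x = np.asarray(segment.samples, dtype=float)
    fs = segment.fs
    win = max(2, int(round(params.window_s * fs)))
    n = len(x)
    if n < 2:
        raise ValueError("segment shorter than one sliding window")

    # per-window dynamic threshold over consecutive windows (tail padded
    # into the last full window's statistics)
    n_win = max(1, int(np.ceil(n / win)))
    thresholds = np.empty(n_win)
    window_max = np.empty(n_win)
    window_median = np.empty(n_win)
    for w in range(n_win):
        lo = w * win
        hi = min(n, lo + win)
        if hi - lo < 2:  # degenerate tail: reuse previous window stats
            thresholds[w] = thresholds[w - 1]
            window_max[w] = window_max[w - 1]
            window_median[w] = window_median[w - 1]
            continue
        xv = x[lo:hi]
        thresholds[w] = xv.mean() + params.threshold_k * xv.std()
        window_max[w] = xv.max()
        window_median[w] = np.median(xv)
    per_sample_thr = thresholds[np.minimum(np.arange(n) // win, n_win - 1)]

    candidates, _ = sp_signal.find_peaks(x)
    candidates = candidates[x[candidates] > per_sample_thr[candidates]]

    # refractory merge: within refractory_s keep the larger peak
    refractory = int(round(params.refractory_s * fs))
    merged: list[int] = []
    for p in candidates:
        if merged and p - merged[-1] < refractory:
            if x[p] > x[merged[-1]]:
                merged[-1] = int(p)
        else:
            merged.append(int(p))
    merged_arr = np.asarray(merged, dtype=int)

    # QRS validation: prominence and width checks per peak
    if len(merged_arr):
        prominences = sp_signal.peak_prominences(x, merged_arr)[0]
        widths = sp_signal.peak_widths(x, merged_arr, rel_height=0.5)[0]
        w_idx = np.minimum(merged_arr // win, n_win - 1)
        swing = window_max[w_idx] - window_median[w_idx]
        ok = (prominences >= params.prominence_frac * swing) & (
            widths <= params.max_qrs_width_s * fs
        )
        survivors = merged_arr[ok]
        # T-wave discrimination: a much smaller peak shortly after an
        # accepted QRS is a T wave, not a second QRS
        t_win = int(round(params.t_wave_window_s * fs))
        medians = window_median[np.minimum(survivors // win, n_win - 1)] if len(
            survivors
        ) else np.empty(0)
        kept: list[int] = []
        last_height = 0.0
        for p, med in zip(survivors, medians):
            height = x[p] - med
            if kept and p - kept[-1] < t_win and height < params.t_wave_ratio * last_height:
                continue
            kept.append(int(p))
            last_height = height
        qrs = np.asarray(kept, dtype=int)
    else:
        qrs = merged_arr
    return RPeakResult(
        peak_indices=merged_arr, qrs_indices=qrs, threshold_trace=thresholds
    )


def match_peaks(
    truth: np.ndarray, detected: np.ndarray, tol_samples: int
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected peaks to ground truth.

    Returns (true positives, false negatives, false positives) under the
    given sample tolerance.
    """
    truth = np.asarray(truth, dtype=int)
    detected = np.asarray(detected, dtype=int)
    used = np.zeros(len(detected), dtype=bool)
    tp = 0
    for t in truth:
        if len(detected) == 0:
            break
        d = np.abs(detected - t)
        d[used] = tol_samples + 1
        j = int(np.argmin(d))
        if d[j] <= tol_samples:
            used[j] = True
            tp += 1
    fn = len(truth) - tp
    fp = int((~used).sum())
    return tp, fn, fp


def filter_segments(
    segment_set: SegmentSet,
    min_peaks: int = 2,
    params: Optional[RPeakParams] = None,
) -> tuple[SegmentSet, int]:
    """Keep segments with at least ``min_peaks`` validated QRS complexes.

    Ensures every retained segment contains at least two complete QRS
    waves (with the default ``min_peaks=2``).  Returns the retained set
    and the number dropped; retained + dropped always equals the input
    count.
    """
    if min_peaks <= 0:
        return segment_set, 0
    params = params or RPeakParams()
    retained = [
        seg for seg in segment_set.segments
        if detect_rpeaks(seg, params).n_valid_qrs >= min_peaks
    ]
    dropped = len(segment_set) - len(retained)
    return (
        SegmentSet(segments=retained, duration_s=segment_set.duration_s,
                   fs=segment_set.fs),
        dropped,
    )


# --------------------------------------------------------------------------
# Z-score normalization
# --------------------------------------------------------------------------

class DegenerateSegmentError(ValueError):
    """Raised for a constant segment (zero spread: no QRS to normalize)."""


@dataclass
class NormalizedSegment:
    """A z-scored segment: x' = (x_i - mu) / sigma, with mu/sigma recorded."""

    samples: np.ndarray
    mu: float
    sigma: float
    source: Segment


def zscore(segment: Segment) -> NormalizedSegment:
    """Z-score one segment to zero mean and unit (population) sd.

    sigma is the population standard deviation (ddof=0) of the segment; a
    constant segment raises :class:`DegenerateSegmentError` rather than
    silently emitting zeros — a flat segment has no QRS and should already
    have been filtered out.
    """
    x = np.asarray(segment.samples, dtype=float)
    if len(x) < 2:
        raise ValueError("z-score requires at least 2 samples")
    mu = float(x.mean())
    sigma = float(x.std(ddof=0))
    if sigma == 0.0 or not np.isfinite(sigma):
        raise DegenerateSegmentError(
            f"segment {segment.subject_id}@{segment.start} is constant (sigma=0)"
        )
    return NormalizedSegment(samples=(x - mu) / sigma, mu=mu, sigma=sigma, source=segment)


def zscore_set(segment_set: SegmentSet) -> tuple[np.ndarray, np.ndarray]:
    """Z-score every segment; returns (X, y) arrays ready for the classifier."""
    X = np.stack([zscore(seg).samples for seg in segment_set.segments]).astype(np.float32)
    y = segment_set.labels()
    return X, y
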