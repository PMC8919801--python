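"""Signal conditioning: landmark tracks -> clean z-scored tapping signal.

The chain mirrors how markerless-tracking output is prepared for kinematic
analysis: per-frame index–thumb distance, leave-one-out cubic outlier
rejection, short-gap cubic interpolation, downsampling to a common 30 Hz,
zero-phase FIR low-pass at 10 Hz to suppress frame-to-frame prediction
jitter, and z-scoring to cancel camera-distance scaling.  Derivatives up to
jerk are taken by central finite differences.

Stage order is deliberate: quality control acts on raw pixel-scale frames
(z-scoring first would corrupt the robust scale estimates the outlier
threshold relies on), and normalization comes last.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import (
    DegenerateSignalError,
    InsufficientDataError,
    UnsupportedRateError,
)
from .recording import LandmarkRecording, QCReport, TappingSignal

TARGET_FS = 30


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing parameters.

    ``outlier_mult`` is the deviance threshold in multiples of a robust
    scale; ``outlier_floor_frac`` anchors that scale to the signal's own
    frame-to-frame dynamics so legitimate sharp troughs survive (see
    :func:`detect_outliers`).  ``lowpass`` and ``auto_trim`` can be turned
    off for analytic tests on clean signals.
    """

    confidence_floor: float = 0.1
    outlier_mult: float = 6.0
    outlier_floor_frac: float = 0.2
    max_gap_s: float = 0.5
    lowpass: bool = True
    lowpass_cutoff_hz: float = 10.0
    auto_trim: bool = False
    trim_window_s: float = 1.0
    trim_range_frac: float = 0.25


def compute_distance_series(rec: LandmarkRecording) -> np.ndarray:
    """Per-frame Euclidean index–thumb distance in pixels.

    Frames where either landmark is missing are NaN in the output.  Raises
    if fewer than half the frames have both landmarks.
    """
    idx = rec.xy["index_tip"]
    thumb = rec.xy["thumb_tip"]
    d = np.hypot(idx[:, 0] - thumb[:, 0], idx[:, 1] - thumb[:, 1])
    coverage = np.mean(np.isfinite(d))
    if coverage < 0.5:
        raise InsufficientDataError(
            f"index/thumb landmarks present in only {coverage:.0%} of frames (need >= 50%)"
        )
    return d


def _loo_cubic_estimate(t: np.ndarray, y: np.ndarray, i: int, valid: np.ndarray) -> float:
    """Cubic estimate of sample i from its 4 nearest valid neighbors.

    Local support keeps a spike from leaking into its own estimate; a
    degree-3 polynomial through 4 points reproduces cubics exactly.
    """
    cand = np.nonzero(valid)[0]
    cand = cand[cand != i]
    if len(cand) < 2:
        return np.nan
    order = np.argsort(np.abs(t[cand] - t[i]), kind="stable")
    near = cand[order[:4]]
    deg = min(3, len(near) - 1)
    # Shift to local coordinates for numerical stability.
    coeffs = np.polyfit(t[near] - t[i], y[near], deg)
    return float(np.polyval(coeffs, 0.0))


def detect_outliers(
    series: np.ndarray,
    threshold_mult: float = 6.0,
    floor_frac: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out cubic outlier deviance and mask.

    For each valid sample, the deviance is |value - estimate| where the
    estimate is a cubic interpolation from the 4 nearest valid neighbors
    with the sample held out (one-sided near the boundaries).  A sample is
    masked when its deviance exceeds

        threshold_mult * max(median(deviance), floor_frac * p95(|diff|))

    The median term expresses the threshold in robust units of the typical
    deviance; the floor term, anchored to the 95th percentile of the
    frame-to-frame increments, prevents the corner-like tap troughs of a
    clean signal (whose median deviance is ~0) from being flagged.

    Returns ``(deviance, mask)``; deviance is NaN at missing samples.
    """
    y = np.asarray(series, dtype=float)
    valid = np.isfinite(y)
    if valid.sum() < 8:
        raise InsufficientDataError(
            f"need >= 8 valid samples for outlier detection, got {int(valid.sum())}"
        )
    t = np.arange(len(y), dtype=float)
    dev = np.full(len(y), np.nan)
    for i in np.nonzero(valid)[0]:
        est = _loo_cubic_estimate(t, y, i, valid)
        if np.isfinite(est):
            dev[i] = abs(y[i] - est)

    finite_dev = dev[np.isfinite(dev)]
    diffs = np.abs(np.diff(y[valid]))
    p95 = np.percentile(diffs, 95) if len(diffs) else 0.0
    scale = max(np.median(finite_dev), floor_frac * p95)
    if scale <= 0:  # flat series: nothing can be an outlier
        return dev, np.zeros(len(y), dtype=bool)
    threshold = threshold_mult * scale

    # Peel outliers one at a time, worst first, re-estimating neighbors
    # after each removal so one spike cannot drag its neighbors over the
    # threshold through their corrupted estimates.
    mask = np.zeros(len(y), dtype=bool)
    work_dev = dev.copy()
    work_valid = valid.copy()
    for _ in range(max(len(y) // 10, 8)):
        candidates = np.where(work_valid & np.isfinite(work_dev), work_dev, -np.inf)
        worst = int(np.argmax(candidates))
        if candidates[worst] <= threshold:
            break
        mask[worst] = True
        work_valid[worst] = False
        work_dev[worst] = np.nan
        near = np.nonzero(work_valid)[0]
        near = near[np.abs(near - worst) <= 6]
        for j in near:
            est = _loo_cubic_estimate(t, y, j, work_valid)
            work_dev[j] = abs(y[j] - est) if np.isfinite(est) else np.nan
    return dev, mask


def interpolate_gaps(
    series: np.ndarray,
    fs: int,
    max_gap_s: float = 0.5,
) -> tuple[np.ndarray, dict]:
    """Fill missing runs of <= ``max_gap_s`` seconds by local cubic fits.

    Each fillable gap is interpolated with a cubic through the two nearest
    valid samples on each side (exact for cubic polynomials).  Longer gaps
    and leading/trailing runs are left missing and flagged.

    Returns ``(filled, info)`` with ``info`` counting interpolated samples
    and unrecoverable gaps.
    """
    y = np.asarray(series, dtype=float).copy()
    valid = np.isfinite(y)
    if not valid.any():
        raise InsufficientDataError("all samples missing")
    t = np.arange(len(y), dtype=float)
    max_len = int(round(max_gap_s * fs))
    info = {"interpolated": 0, "unrecoverable_gaps": 0, "unrecoverable_samples": 0}

    # Locate missing runs.
    missing = ~valid
    edges = np.flatnonzero(np.diff(np.concatenate([[0], missing.view(np.int8), [0]])))
    for start, stop in zip(edges[::2], edges[1::2]):
        run = stop - start
        left = np.nonzero(valid[:start])[0]
        right = np.nonzero(valid[stop:])[0] + stop
        if len(left) == 0 or len(right) == 0 or run > max_len:
            info["unrecoverable_gaps"] += 1
            info["unrecoverable_samples"] += run
            continue
        support = np.concatenate([left[-2:], right[:2]])
        deg = min(3, len(support) - 1)
        mid = t[start]
        coeffs = np.polyfit(t[support] - mid, y[support], deg)
        y[start:stop] = np.polyval(coeffs, t[start:stop] - mid)
        info["interpolated"] += run
    return y, info


def resample_to_30(series: np.ndarray, fs_in: int) -> np.ndarray:
    """Downsample 60 Hz input to the common 30 Hz rate (identity at 30 Hz).

    60 Hz input is anti-alias FIR filtered and decimated by 2, giving
    ceil(n/2) output samples.
    """
    y = np.asarray(series, dtype=float)
    if fs_in == TARGET_FS:
        return y.copy()
    if fs_in == 60:
        if np.any(~np.isfinite(y)):
            raise InsufficientDataError("resampling requires a gap-free series")
        return sps.decimate(y, 2, ftype="fir", zero_phase=True)
    raise UnsupportedRateError(f"unsupported sampling rate {fs_in}; expected 30 or 60")


def design_lowpass(fs: int = TARGET_FS, cutoff_hz: float = 10.0, taps_s: float = 2.0) -> np.ndarray:
    """Linear-phase windowed-sinc low-pass, order ~ ``taps_s`` seconds."""
    numtaps = int(taps_s * fs) + 1
    return sps.firwin(numtaps, cutoff_hz, fs=fs)


def lowpass_10hz(series: np.ndarray, fs: int = TARGET_FS, cutoff_hz: float = 10.0) -> np.ndarray:
    """Zero-phase FIR low-pass; unity DC gain, output length preserved."""
    y = np.asarray(series, dtype=float)
    if np.any(~np.isfinite(y)):
        raise InsufficientDataError("low-pass filtering requires a gap-free series")
    b = design_lowpass(fs, cutoff_hz)
    if len(y) < 3 * len(b):
        raise InsufficientDataError(
            f"series of {len(y)} samples too short for a {len(b)}-tap zero-phase filter"
        )
    return sps.filtfilt(b, [1.0], y)


def zscore(series: np.ndarray) -> np.ndarray:
    """(x - mean) / std; raises on constant input (no tapping present)."""
    y = np.asarray(series, dtype=float)
    sd = y.std()
    if not sd > 0:
        raise DegenerateSignalError("constant distance series: no tapping to normalize")
    return (y - y.mean()) / sd


def derivatives(amplitude: np.ndarray, fs: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Velocity, acceleration, jerk by central differences (one-sided edges)."""
    v = np.gradient(amplitude) * fs
    a = np.gradient(v) * fs
    j = np.gradient(a) * fs
    return v, a, j


def auto_trim_window(series: np.ndarray, fs: int, window_s: float, range_frac: float) -> tuple[int, int]:
    """Longest window whose rolling 1 s amplitude range exceeds a fraction
    of the global range — a fallback when no task-segment annotation exists."""
    y = np.asarray(series, dtype=float)
    finite = y[np.isfinite(y)]
    if len(finite) == 0:
        return 0, len(y)
    global_range = finite.max() - finite.min()
    if global_range == 0:
        return 0, len(y)
    w = max(int(window_s * fs), 2)
    active = np.zeros(len(y), dtype=bool)
    for i in range(len(y)):
        lo, hi = max(0, i - w // 2), min(len(y), i + w // 2 + 1)
        seg = y[lo:hi]
        seg = seg[np.isfinite(seg)]
        if len(seg) and seg.max() - seg.min() > range_frac * global_range:
            active[i] = True
    if not active.any():
        return 0, len(y)
    # Longest contiguous active run.
    edges = np.flatnonzero(np.diff(np.concatenate([[0], active.view(np.int8), [0]])))
    runs = list(zip(edges[::2], edges[1::2]))
    start, stop = max(runs, key=lambda r: r[1] - r[0])
    return int(start), int(stop)


def preprocess_recording(
    rec: LandmarkRecording,
    config: PreprocessConfig | None = None,
) -> TappingSignal:
    """Full conditioning chain for one landmark recording.

    Order: trim to task segment -> distance -> outlier removal -> gap
    interpolation -> resample to 30 Hz -> low-pass 10 Hz -> z-score ->
    derivatives.  QC counters record outliers, interpolated samples and
    unrecoverable gaps; unrecoverable interior gaps are bridged linearly so
    the filter has a contiguous series, but remain flagged.
    """
    cfg = config or PreprocessConfig()

    # Confidence below the floor is treated as missing.
    rec_xy = {}
    for name, arr in rec.xy.items():
        arr = arr.copy()
        low = rec.confidence[name] < cfg.confidence_floor
        arr[low] = np.nan
        rec_xy[name] = arr
    work = LandmarkRecording(
        fs=rec.fs,
        frames=rec.frames,
        xy=rec_xy,
        confidence=rec.confidence,
        hand=rec.hand,
        subject_id=rec.subject_id,
        session_id=rec.session_id,
        segment=rec.segment,
    )

    d = compute_distance_series(work)
    qc = QCReport()

    if rec.segment is not None:
        a, b = rec.segment
        qc.trimmed_samples = len(d) - (b - a)
        d = d[a:b]
    elif cfg.auto_trim:
        a, b = auto_trim_window(d, rec.fs, cfg.trim_window_s, cfg.trim_range_frac)
        qc.trimmed_samples = len(d) - (b - a)
        d = d[a:b]

    _, mask = detect_outliers(d, cfg.outlier_mult, cfg.outlier_floor_frac)
    qc.outlier_count = int(mask.sum())
    d = d.copy()
    d[mask] = np.nan

    d, gap_info = interpolate_gaps(d, rec.fs, cfg.max_gap_s)
    qc.interpolated_count = gap_info["interpolated"]
    qc.unrecoverable_gap_count = gap_info["unrecoverable_gaps"]
    qc.unrecoverable_sample_count = gap_info["unrecoverable_samples"]

    # Bridge any remaining missing samples (flagged above) so the filter
    # sees a contiguous series; drop unfillable leading/trailing runs.
    finite = np.flatnonzero(np.isfinite(d))
    if len(finite) == 0:
        raise InsufficientDataError("no valid samples after quality control")
    d = d[finite[0] : finite[-1] + 1]
    bad = ~np.isfinite(d)
    if bad.any():
        t = np.arange(len(d))
        d[bad] = np.interp(t[bad], t[~bad], d[~bad])

    d = resample_to_30(d, rec.fs)
    if cfg.lowpass:
        d = lowpass_10hz(d, TARGET_FS, cfg.lowpass_cutoff_hz)
    amp = zscore(d)
    v, a, j = derivatives(amp, TARGET_FS)
    if qc.unrecoverable_gap_count:
        warnings.warn(
            f"{rec.session_id}/{rec.hand}: {qc.unrecoverable_gap_count} gap(s) "
            "exceeded the interpolation limit and were bridged linearly",
            stacklevel=2,
        )
    return TappingSignal(
        fs=TARGET_FS,
        amplitude=amp,
        velocity=v,
        acceleration=a,
        jerk=j,
        qc=qc,
        hand=rec.hand,
        subject_id=rec.subject_id,
        session_id=rec.session_id,
    )
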