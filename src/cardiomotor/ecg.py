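"""ECG preprocessing and R-peak detection.

The processing chain mirrors a standard three-electrode setup: the raw
recordings are combined into a single bipolar lead, high-pass filtered at
0.01 Hz to remove slow drift, resampled to 1000 Hz so every time stamp is an
integer millisecond, and thresholded to locate the R-wave of each heartbeat
as a local maximum. Successive R-peak differences are the R-R intervals that
all downstream alignment (time windows, cardiac phase) is referenced to.

All peak times are encoded as integer milliseconds; sub-millisecond timing is
deliberately not represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Any

import numpy as np
from scipy import ndimage, signal

from .errors import EmptyTrainError, InvalidParameterError, QCError

__all__ = [
    "ECGRecording",
    "RPeakTrain",
    "QCReport",
    "bipolar_combine",
    "highpass_filter",
    "resample_to_1khz",
    "orient_polarity",
    "detect_rpeaks",
    "qc_rr",
    "round_ms",
]

#: hard physiological bounds on a plausible R-R interval, in ms
RR_BOUNDS_MS = (300.0, 2000.0)


def round_ms(x):
    """Round times to integer milliseconds, halves away from zero-free (half-up)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


@dataclass
class ECGRecording:
    """A voltage recording: ``data`` is (n_samples,) or (n_samples, n_channels).

    ``fs`` is the sampling rate in Hz and ``t0`` the time of the first sample
    in milliseconds.
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (1, 2):
            raise InvalidParameterError("ECG data must be 1- or 2-dimensional")
        if self.fs <= 0:
            raise InvalidParameterError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 1 else self.data.shape[1]

    def channel(self, i: int = 0) -> np.ndarray:
        return self.data if self.data.ndim == 1 else self.data[:, i]

    def times_ms(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) * (1000.0 / self.fs)


@dataclass
class RPeakTrain:
    """Ordered R-peak times for one subject/block, integer milliseconds."""

    times: np.ndarray
    subject: Any = None
    block: Any = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        if self.times.ndim != 1:
            raise InvalidParameterError("R-peak times must be a 1-d array")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("R-peak times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def intervals(self) -> np.ndarray:
        """R-R intervals in ms (length n-1)."""
        return np.diff(self.times)


@dataclass
class QCReport:
    """Automated stand-in for visual inspection of the detected beat train.

    ``flagged_intervals`` lists (interval index, interval ms, reason); interval
    ``i`` spans ``times[i]`` to ``times[i+1]``. Events falling inside a flagged
    interval are excluded from alignment downstream.
    """

    flagged_intervals: list = field(default_factory=list)
    n_beats: int = 0
    mean_rr: float = float("nan")

    @property
    def flagged_indices(self) -> np.ndarray:
        return np.asarray([i for i, _, _ in self.flagged_intervals], dtype=np.int64)

    def flagged_spans(self, train: RPeakTrain) -> np.ndarray:
        """(k, 2) array of [start_ms, end_ms] for each flagged interval."""
        idx = self.flagged_indices
        if idx.size == 0:
            return np.empty((0, 2), dtype=np.int64)
        return np.stack([train.times[idx], train.times[idx + 1]], axis=1)


def bipolar_combine(rec: ECGRecording) -> ECGRecording:
    """Combine three monopolar electrodes into one bipolar lead.

    Output is the mean of (ch2 - ch1) and (ch3 - ch1); common-mode signal on
    the shared reference electrode cancels exactly.
    """
    if rec.n_channels != 3:
        raise InvalidParameterError(
            f"bipolar_combine requires exactly 3 channels, got {rec.n_channels}"
        )
    ch1, ch2, ch3 = rec.data[:, 0], rec.data[:, 1], rec.data[:, 2]
    out = 0.5 * ((ch2 - ch1) + (ch3 - ch1))
    return ECGRecording(out, rec.fs, rec.t0)


def highpass_filter(rec: ECGRecording, cutoff: float = 0.01, order: int = 2) -> ECGRecording:
    """Zero-phase Butterworth high-pass; default 0.01 Hz removes linear drift.

    The filter runs forward and backward (``sosfiltfilt``) so that peak timing
    is not shifted; the measurand here is the *time* of each R-wave.
    """
    if cutoff <= 0 or cutoff >= rec.fs / 2:
        raise InvalidParameterError(
            f"cutoff must lie in (0, fs/2) = (0, {rec.fs / 2}), got {cutoff}"
        )
    sos = signal.butter(order, cutoff, btype="highpass", fs=rec.fs, output="sos")
    # a cutoff this low has transients of tens of seconds; pad generously so
    # edge effects decay before they reach the data
    padlen = min(rec.n_samples - 1, int(60.0 * rec.fs))
    out = signal.sosfiltfilt(sos, rec.data, axis=0, padlen=padlen)
    return ECGRecording(out, rec.fs, rec.t0)


def resample_to_1khz(rec: ECGRecording) -> ECGRecording:
    """Resample to 1000 Hz so sample index equals elapsed milliseconds.

    Polyphase resampling with the exact rational ratio 1000/fs; the output is
    trimmed to ``round(n * 1000 / fs)`` samples.
    """
    if rec.fs == 1000.0:
        return ECGRecording(rec.data.copy(), 1000.0, rec.t0)
    if float(rec.fs).is_integer():
        frac = Fraction(1000, int(rec.fs))
    else:
        frac = Fraction(1000.0 / rec.fs).limit_denominator(100000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=0)
    target_len = int(round(rec.n_samples * 1000.0 / rec.fs))
    out = out[:target_len]
    return ECGRecording(out, 1000.0, rec.t0)


def orient_polarity(rec: ECGRecording) -> ECGRecording:
    """Flip the signal if the dominant deflections are negative.

    The R-peak detector assumes upright R-waves; this inverts the lead when
    the 99th percentile of -x exceeds that of x.
    """
    x = rec.channel(0)
    if np.percentile(-x, 99) > np.percentile(x, 99):
        return ECGRecording(-rec.data, rec.fs, rec.t0)
    return ECGRecording(rec.data.copy(), rec.fs, rec.t0)


def detect_rpeaks(
    rec: ECGRecording,
    refractory_ms: float = 250.0,
    threshold_frac: float = 0.5,
    smooth_ms: float = 11.0,
    subject: Any = None,
    block: Any = None,
) -> RPeakTrain:
    """Threshold-and-local-maximum R-peak detector.

    The signal is smoothed with a short symmetric moving average (default
    11 ms) so that wideband noise cannot create spurious threshold crossings;
    a symmetric window leaves the location of a symmetric QRS maximum
    unchanged. The threshold is adaptive: ``threshold_frac`` times the 99th
    percentile of the absolute smoothed signal, which makes detection
    invariant to amplitude scaling and robust to isolated artifacts. Each
    contiguous suprathreshold excursion yields one peak (its local maximum),
    and a refractory period (default 250 ms, i.e. 240 bpm) suppresses double
    detections of a single QRS complex, keeping the larger peak.

    The detector is polarity-sensitive: only positive excursions are
    considered, so an inverted lead raises :class:`EmptyTrainError`. Use
    :func:`orient_polarity` first.
    """
    if rec.n_channels != 1:
        raise InvalidParameterError("detect_rpeaks expects a single-channel recording")
    x = rec.channel(0)
    w = max(1, int(round(smooth_ms * rec.fs / 1000.0)))
    if w % 2 == 0:
        w += 1
    xs = ndimage.uniform_filter1d(x, size=w, mode="nearest") if w > 1 else x

    thr = threshold_frac * np.percentile(np.abs(xs), 99)
    above = xs > thr
    if not above.any():
        raise EmptyTrainError("no suprathreshold samples; check signal polarity and gain")

    # one local maximum per contiguous suprathreshold excursion
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    peak_idx = np.array(
        [s + int(np.argmax(xs[s:e])) for s, e in zip(starts, ends)], dtype=np.int64
    )
    peak_amp = xs[peak_idx]

    # refractory enforcement: among peaks closer than refractory_ms keep the larger
    min_gap = refractory_ms * rec.fs / 1000.0
    kept_idx: list[int] = []
    kept_amp: list[float] = []
    for i, a in zip(peak_idx, peak_amp):
        if kept_idx and i - kept_idx[-1] < min_gap:
            if a > kept_amp[-1]:
                kept_idx[-1], kept_amp[-1] = int(i), float(a)
        else:
            kept_idx.append(int(i))
            kept_amp.append(float(a))
    times = round_ms(rec.t0 + np.asarray(kept_idx) * (1000.0 / rec.fs))

    if times.size >= 10:
        median_rr = float(np.median(np.diff(times)))
        if median_rr < 60000.0 / 250.0:
            raise QCError(
                f"sustained rate above 250 bpm (median R-R {median_rr:.0f} ms); "
                "detection is unreliable"
            )
    return RPeakTrain(times, subject=subject, block=block)


def qc_rr(
    train: RPeakTrain,
    bounds_ms: tuple[float, float] = RR_BOUNDS_MS,
    local_window: int = 11,
    max_rel_dev: float = 0.40,
) -> QCReport:
    """Flag implausible R-R intervals (automated beat-train inspection).

    Flags intervals outside ``bounds_ms`` and intervals deviating from the
    local median (centered window of ``local_window`` intervals) by more than
    ``max_rel_dev``. Flagged intervals are excluded from event alignment by
    the window and phase modules.
    """
    if len(train) < 2:
        raise InvalidParameterError("qc_rr requires at least 2 peaks")
    rr = train.intervals.astype(float)
    local_med = ndimage.median_filter(rr, size=min(local_window, rr.size), mode="nearest")
    flagged: list[tuple[int, float, str]] = []
    for i, (iv, med) in enumerate(zip(rr, local_med)):
        if iv < bounds_ms[0]:
            flagged.append((i, float(iv), "below_min"))
        elif iv > bounds_ms[1]:
            flagged.append((i, float(iv), "above_max"))
        elif med > 0 and abs(iv - med) / med > max_rel_dev:
            flagged.append((i, float(iv), "local_outlier"))
    return QCReport(flagged_intervals=flagged, n_beats=len(train), mean_rr=float(rr.mean()))
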