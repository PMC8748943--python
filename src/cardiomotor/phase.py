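"""Phase-domain analysis: cardiac phase of each movement endpoint and the
circular statistics built on it.

An endpoint at time t_e inside the R-R interval [prev_r, next_r) has cardiac
phase (t_e - prev_r) / (next_r - prev_r) * 360 degrees, so 0 degrees is the
R-peak and the phase wraps once per heartbeat. On these phases the module
provides circular means with resultant lengths, Rayleigh tests of uniformity
(z = n * Rbar^2 with the standard small-sample p approximation), 20-bin
normalized circular histograms (bin edges at multiples of 18 degrees, giving
bin centers 9, 27, ..., 351), circular three-bin smoothing, and per-bin
one-sample t-tests of subject proportions against the uniform expectation of
1/20 = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .ecg import QCReport, RPeakTrain
from .errors import DegenerateDataError, InvalidParameterError

__all__ = [
    "N_BINS",
    "UNIFORM_PROP",
    "PhaseAssignment",
    "CircularHistogram",
    "RayleighResult",
    "event_phase",
    "assign_phases",
    "circular_mean",
    "rayleigh_test",
    "circular_histogram",
    "smooth_circular",
    "per_bin_uniformity_tests",
    "group_rayleigh_on_subject_means",
]

N_BINS = 20
BIN_WIDTH_DEG = 360.0 / N_BINS
UNIFORM_PROP = 1.0 / N_BINS
BIN_CENTERS_DEG = BIN_WIDTH_DEG / 2 + BIN_WIDTH_DEG * np.arange(N_BINS)


@dataclass
class PhaseAssignment:
    """One endpoint's position in its R-R interval."""

    t_e: int
    prev_r: int
    next_r: int

    def __post_init__(self) -> None:
        if not self.prev_r < self.t_e < self.next_r:
            raise InvalidParameterError(
                f"event {self.t_e} must lie strictly inside ({self.prev_r}, {self.next_r})"
            )

    @property
    def rr(self) -> int:
        return self.next_r - self.prev_r

    @property
    def phase(self) -> float:
        return (self.t_e - self.prev_r) / self.rr * 360.0


@dataclass
class CircularHistogram:
    """20-bin normalized phase distribution for one subject x condition."""

    props: np.ndarray
    smoothed: bool = False
    subject: Any = None
    condition: str = ""
    bin_centers: np.ndarray = field(default_factory=lambda: BIN_CENTERS_DEG.copy())

    def __post_init__(self) -> None:
        self.props = np.asarray(self.props, dtype=float)
        if self.props.shape != (N_BINS,):
            raise InvalidParameterError(f"histogram must have {N_BINS} bins")
        if (self.props < -1e-12).any() or abs(self.props.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("bin proportions must be >= 0 and sum to 1")


@dataclass
class RayleighResult:
    """Rayleigh uniformity test: z = n * Rbar^2."""

    n: int
    rbar: float
    z: float
    p: float


def event_phase(t_e: float, prev_r: float, next_r: float) -> float:
    """Cardiac phase in degrees of an event inside one R-R interval."""
    if next_r <= prev_r:
        raise InvalidParameterError("next_r must exceed prev_r")
    if not prev_r < t_e < next_r:
        raise InvalidParameterError("t_e must lie strictly between the flanking R-peaks")
    return (t_e - prev_r) / (next_r - prev_r) * 360.0


def assign_phases(
    events_ms: np.ndarray, train: RPeakTrain, qc: QCReport | None = None
) -> pd.DataFrame:
    """Phase of every endpoint against one subject's R-peak train.

    Endpoints inside QC-flagged intervals are dropped, as are endpoints whose
    quantized time coincides exactly with an R-peak (the phase is undefined at
    the fiducial itself; at 1 ms resolution such ties affect ~0.1% of events).
    Returns a table with columns event_time_ms, prev_r_ms, next_r_ms, rr_ms,
    phase_deg.
    """
    events = np.asarray(events_ms, dtype=np.int64)
    rt = train.times
    if rt.size < 2:
        raise InvalidParameterError("R-peak train must contain at least 2 peaks")
    if events.size and (events.min() < rt[0] or events.max() > rt[-1]):
        raise InvalidParameterError("event outside the span of the R-peak train")
    idx = np.searchsorted(rt, events, side="right") - 1
    on_peak = (events == rt[np.clip(idx, 0, rt.size - 1)]) | (idx >= rt.size - 1)
    if on_peak.any():
        events, idx = events[~on_peak], idx[~on_peak]
    if qc is not None and qc.flagged_intervals:
        keep = ~np.isin(idx, qc.flagged_indices)
        events, idx = events[keep], idx[keep]
    prev = rt[idx]
    nxt = rt[idx + 1]
    rr = (nxt - prev).astype(float)
    phase = (events - prev) / rr * 360.0
    return pd.DataFrame(
        {
            "event_time_ms": events,
            "prev_r_ms": prev,
            "next_r_ms": nxt,
            "rr_ms": rr.astype(np.int64),
            "phase_deg": phase,
        }
    )


def circular_mean(phases_deg) -> tuple[float, float]:
    """Circular mean direction and resultant length of phases in degrees.

    Returns (mean_deg in [0, 360), rbar). When the resultant length is below
    1e-12 the mean direction is undefined and NaN is returned for it.
    """
    phases = np.asarray(phases_deg, dtype=float)
    if phases.size == 0:
        raise InvalidParameterError("circular_mean requires at least one phase")
    rad = np.radians(phases)
    c, s = np.cos(rad).mean(), np.sin(rad).mean()
    rbar = float(np.hypot(c, s))
    if rbar < 1e-12:
        return float("nan"), rbar
    mean = float(np.degrees(np.arctan2(s, c)) % 360.0)
    if mean >= 360.0:  # floating-point wrap of angles infinitesimally below 0
        mean = 0.0
    return mean, rbar


def rayleigh_test(phases_deg) -> RayleighResult:
    """Rayleigh test of circular uniformity.

    z = n * Rbar^2; the p-value uses the standard small-sample correction
    p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)) with R = n * Rbar,
    accurate for n >= 4 (hence the precondition).
    """
    phases = np.asarray(phases_deg, dtype=float)
    n = phases.size
    if n < 4:
        raise InvalidParameterError("rayleigh_test requires n >= 4")
    _, rbar = circular_mean(phases)
    z = n * rbar * rbar
    big_r = n * rbar
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - big_r * big_r)) - (1.0 + 2.0 * n))
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return RayleighResult(n=int(n), rbar=rbar, z=float(z), p=p)


def circular_histogram(phases_deg, subject: Any = None, condition: str = "") -> CircularHistogram:
    """Normalized 20-bin histogram; bins are half-open [18k, 18(k+1))."""
    phases = np.asarray(phases_deg, dtype=float)
    if phases.size == 0:
        raise InvalidParameterError("circular_histogram requires at least one phase")
    if (phases < 0).any() or (phases >= 360).any():
        phases = phases % 360.0
        phases[phases >= 360.0] = 0.0
    bins = np.clip(np.floor(phases / BIN_WIDTH_DEG).astype(np.int64), 0, N_BINS - 1)
    counts = np.bincount(bins, minlength=N_BINS).astype(float)
    return CircularHistogram(counts / phases.size, smoothed=False, subject=subject, condition=condition)


def smooth_circular(hist: CircularHistogram) -> CircularHistogram:
    """Average each bin with its two circular neighbors (mass-preserving)."""
    if hist.smoothed:
        raise InvalidParameterError("histogram is already smoothed")
    p = hist.props
    out = (np.roll(p, 1) + p + np.roll(p, -1)) / 3.0
    return CircularHistogram(out, smoothed=True, subject=hist.subject, condition=hist.condition)


def per_bin_uniformity_tests(
    props: np.ndarray | pd.DataFrame,
    family: int = N_BINS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided one-sample t-tests of per-subject bin proportions vs 0.05.

    ``props`` is (n_subjects, 20) — one (typically smoothed) histogram row
    per subject for a single condition. Bonferroni correction multiplies p by
    ``family`` (20 bins within a condition by default; pass 40 to pool the
    two conditions into one family). Bins with zero variance across subjects
    get a NaN statistic and an explicit flag.
    """
    mat = np.asarray(props, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != N_BINS:
        raise InvalidParameterError(f"props must be (n_subjects, {N_BINS})")
    n = mat.shape[0]
    if n < 3:
        raise InvalidParameterError("need at least 3 subjects per condition")
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    zero_var = sd <= 1e-12  # proportions are O(1); anything below is numerical dust
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - UNIFORM_PROP) / (sd / np.sqrt(n))
    t[zero_var] = np.nan
    p_unc = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p_bonf = np.minimum(1.0, family * p_unc)
    return pd.DataFrame(
        {
            "bin_center_deg": BIN_CENTERS_DEG,
            "mean_prop": mean,
            "t": t,
            "df": n - 1,
            "p_unc": p_unc,
            "p_bonf": p_bonf,
            "sig_unc": np.where(np.isnan(t), False, p_unc < alpha),
            "sig_bonf": np.where(np.isnan(t), False, p_bonf < alpha),
            "zero_variance": zero_var,
        }
    )


def group_rayleigh_on_subject_means(means_deg) -> RayleighResult:
    """Rayleigh test across per-subject circular mean phases (one condition).

    Subjects whose mean direction is undefined (NaN) are excluded with a
    warning; fewer than 4 usable subjects raises.
    """
    means = np.asarray(means_deg, dtype=float)
    usable = means[~np.isnan(means)]
    if usable.size < means.size:
        warnings.warn(
            f"excluded {means.size - usable.size} subject(s) with undefined mean phase",
            stacklevel=2,
        )
    if usable.size < 4:
        raise DegenerateDataError("fewer than 4 usable subject means")
    return rayleigh_test(usable)
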