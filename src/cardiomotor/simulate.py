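"""Synthetic dyadic cardiac + movement data with known ground truth.

Emulates the study design the package analyzes: pairs of subjects take turns
executing a memorized six-movement sequence while both ECGs are recorded.
Turn-taking occurs by block (one subject executes a whole block of ten trials
while the partner observes, then they swap), heartbeats have a mean R-R
interval near 825 ms, and the two subjects of a dyad adopt correlated
movement speeds.

Ground truth is explicit: the generator knows every R-peak time, every kept
movement endpoint, and the cardiac phase at which each endpoint occurred, so
every downstream stage (detection, window assignment, phase statistics,
group inference) can be validated without any external recording.

Three coupling modes control how endpoints relate to the executing subject's
heart:

``uniform``
    endpoint phases drawn uniformly on [0, 360) — the global null;
``von_mises``
    endpoint phases drawn from a von Mises distribution with preferred phase
    ``mu`` and concentration ``kappa``, then mapped into the containing R-R
    interval — a phase-locked effect;
``time_suppression``
    candidate endpoints are thinned near the R-peak: a candidate whose
    latency to the *nearest* R-peak lies within ±``suppression_halfwidth`` of
    ``suppression_center`` is kept with probability ``suppression_factor`` —
    a time-locked deficit around the heartbeat, the pattern the time-domain
    analysis is designed to detect.

All event and peak times are integer milliseconds; ground-truth phases are
recomputed from the quantized times, so they agree exactly with the phase
module's assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .ecg import ECGRecording, RPeakTrain, RR_BOUNDS_MS, round_ms
from .errors import EmptyTrainError, InvalidParameterError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "DyadDataset",
    "generate_rr_train",
    "generate_events",
    "synthesize_ecg",
    "synthesize_three_lead",
    "generate_dyad_dataset",
    "generate_cohort",
    "COUPLING_MODES",
]

COUPLING_MODES = ("uniform", "von_mises", "time_suppression")

#: quiet lead-in before the first trial and gaps between trials/blocks, ms
LEAD_IN_MS = 2000.0
INTER_TRIAL_GAP_MS = 3000.0
INTER_BLOCK_GAP_MS = 10000.0


@dataclass
class SimulationConfig:
    """Parameters of a simulated dyadic session.

    Defaults reproduce the emulated study conditions: two blocks of ten
    trials per dyad, six movement endpoints per trial, mean R-R 825 ms with
    40 ms beat-to-beat spread, and self-paced movements averaging ~1.25 s
    between endpoints.
    """

    n_dyads: int = 1
    blocks_per_dyad: int = 2
    trials_per_block: int = 10
    events_per_trial: int = 6
    mean_rr: float = 825.0
    sd_rr: float = 40.0
    coupling_mode: str = "uniform"
    mu: float = 0.0
    kappa: float = 0.0
    suppression_center: float = 0.0
    suppression_halfwidth: float = 100.0
    suppression_factor: float = 1.0
    movement_time_mean: float = 1250.0
    movement_time_sd: float = 200.0
    movement_time_within_sd: float = 150.0
    movement_time_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyads < 1:
            raise InvalidParameterError("n_dyads must be >= 1")
        if self.blocks_per_dyad < 2 or self.blocks_per_dyad % 2:
            raise InvalidParameterError(
                "blocks_per_dyad must be even and >= 2 so roles counterbalance"
            )
        if min(self.trials_per_block, self.events_per_trial) < 1:
            raise InvalidParameterError("trials_per_block and events_per_trial must be >= 1")
        for name in ("mean_rr", "movement_time_mean"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        for name in ("sd_rr", "movement_time_sd", "movement_time_within_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if self.coupling_mode not in COUPLING_MODES:
            raise InvalidParameterError(
                f"coupling_mode must be one of {COUPLING_MODES}, got {self.coupling_mode!r}"
            )
        if self.kappa < 0:
            raise InvalidParameterError("kappa must be >= 0")
        if not 0.0 <= self.suppression_factor <= 1.0:
            raise InvalidParameterError("suppression_factor must lie in [0, 1]")
        if self.suppression_halfwidth < 0:
            raise InvalidParameterError("suppression_halfwidth must be >= 0")
        if abs(self.movement_time_corr) > 1:
            raise InvalidParameterError("movement_time_corr must lie in [-1, 1]")


@dataclass
class GroundTruth:
    """What the generator knows: peak times, kept endpoints, their phases."""

    true_rpeaks: np.ndarray
    true_events: np.ndarray
    true_phases: np.ndarray
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        self.true_rpeaks = np.asarray(self.true_rpeaks, dtype=np.int64)
        self.true_events = np.asarray(self.true_events, dtype=np.int64)
        self.true_phases = np.asarray(self.true_phases, dtype=float)


@dataclass
class DyadDataset:
    """One simulated cohort: R-peak trains, the event table, and ground truth.

    ``events`` has columns dyad_id, subject_id, block, trial, role,
    event_time_ms; each executed endpoint appears twice, once labeled
    ``execution`` for the executing subject and once ``observation`` for the
    partner (same physical time). ``truth`` carries the executing subject's
    injected phases. ``movement_times`` holds the drawn per-subject mean
    inter-endpoint interval.
    """

    config: SimulationConfig
    rpeaks: dict = field(default_factory=dict)
    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    movement_times: pd.DataFrame = field(default_factory=pd.DataFrame)


def _rng(seed, rng):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def _draw_rr_intervals(n: int, mean_rr: float, sd_rr: float, rng) -> np.ndarray:
    if sd_rr == 0:
        return np.full(n, mean_rr)
    a = (RR_BOUNDS_MS[0] - mean_rr) / sd_rr
    b = (RR_BOUNDS_MS[1] - mean_rr) / sd_rr
    return stats.truncnorm.rvs(a, b, loc=mean_rr, scale=sd_rr, size=n, random_state=rng)


def generate_rr_train(
    n_beats: int,
    mean_rr: float = 825.0,
    sd_rr: float = 40.0,
    seed: int | None = None,
    rng=None,
    t0: float = 0.0,
    subject: Any = None,
    block: Any = None,
) -> RPeakTrain:
    """i.i.d. truncated-normal R-R intervals, truncated to [300, 2000] ms.

    Serial heart-rate-variability structure is deliberately absent: every
    downstream analysis is local to one or two consecutive intervals.
    """
    if n_beats < 2:
        raise InvalidParameterError("n_beats must be >= 2")
    if mean_rr <= 0 or sd_rr < 0:
        raise InvalidParameterError("durations must be positive (sd_rr >= 0)")
    if sd_rr > 0 and mean_rr <= 4 * sd_rr:
        raise InvalidParameterError("require mean_rr > 4*sd_rr for a well-behaved train")
    if not RR_BOUNDS_MS[0] <= mean_rr <= RR_BOUNDS_MS[1]:
        raise InvalidParameterError(f"mean_rr must lie within {RR_BOUNDS_MS}")
    r = _rng(seed, rng)
    intervals = _draw_rr_intervals(n_beats - 1, mean_rr, sd_rr, r)
    times = round_ms(t0 + np.concatenate([[0.0], np.cumsum(intervals)]))
    return RPeakTrain(times, subject=subject, block=block)


def _rr_times_spanning(span_ms: float, mean_rr: float, sd_rr: float, rng) -> np.ndarray:
    """R-peak times from 0 to beyond span_ms (integer ms)."""
    out = [0.0]
    t = 0.0
    while t <= span_ms:
        chunk = _draw_rr_intervals(max(16, int(span_ms / mean_rr) + 4), mean_rr, sd_rr, rng)
        for iv in chunk:
            t += iv
            out.append(t)
            if t > span_ms:
                break
    return round_ms(np.asarray(out))


def _enforce_strict(t: np.ndarray, rtimes: np.ndarray) -> np.ndarray:
    """Sort, break ties by +1 ms, and keep events off the R-peaks themselves."""
    t = np.sort(t)
    for _ in range(1000):
        ok = True
        for i in range(1, t.size):
            if t[i] <= t[i - 1]:
                t[i] = t[i - 1] + 1
                ok = False
        idx = np.clip(np.searchsorted(rtimes, t, side="right") - 1, 0, rtimes.size - 1)
        on_peak = t == rtimes[idx]
        if on_peak.any():
            t[on_peak] += 1
            ok = False
        if ok:
            return t
    raise InvalidParameterError("could not place events strictly between R-peaks")


def _place_events(
    rtimes: np.ndarray,
    targets: np.ndarray,
    cfg: SimulationConfig,
    rng,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map paced target times to endpoint times per the coupling mode.

    Returns (times int ms, phases deg, kept mask over targets). Phases are
    recomputed from the quantized times so that ground truth matches the
    phase module exactly.
    """
    targets = np.asarray(targets, dtype=float)
    n = targets.size
    if rtimes.size < 2:
        raise EmptyTrainError("R-peak train is empty or has a single peak")
    if targets.size and (targets.min() <= rtimes[0] or targets.max() >= rtimes[-1]):
        raise InvalidParameterError("R-peak train does not span the requested events")

    if cfg.coupling_mode in ("uniform", "von_mises"):
        idx = np.searchsorted(rtimes, targets, side="right") - 1
        if cfg.coupling_mode == "uniform":
            phases = rng.uniform(0.0, 360.0, n)
        else:
            phases = np.degrees(rng.vonmises(np.radians(cfg.mu), cfg.kappa, n)) % 360.0
        prev = rtimes[idx]
        rr = rtimes[idx + 1] - prev
        t = round_ms(prev + phases / 360.0 * rr)
        t = np.clip(t, prev + 1, prev + rr - 1)
        kept = np.ones(n, dtype=bool)
    else:  # time_suppression
        t = round_ms(targets)
        idx = np.searchsorted(rtimes, t, side="right") - 1
        t = np.clip(t, rtimes[idx] + 1, rtimes[idx + 1] - 1)
        lat_prev = t - rtimes[idx]
        lat_next = t - rtimes[idx + 1]  # negative
        lam = np.where(lat_prev <= -lat_next, lat_prev, lat_next)
        in_window = np.abs(lam - cfg.suppression_center) <= cfg.suppression_halfwidth
        kept = ~in_window | (rng.uniform(size=n) < cfg.suppression_factor)
        t = t[kept]

    t = _enforce_strict(np.asarray(t, dtype=np.int64), rtimes)
    idx = np.searchsorted(rtimes, t, side="right") - 1
    prev = rtimes[idx]
    rr = (rtimes[idx + 1] - prev).astype(float)
    phases_true = (t - prev) / rr * 360.0
    return t, phases_true, kept


def _paced_targets(start_ms: float, n: int, gap_mean: float, gap_sd: float, rng) -> np.ndarray:
    gaps = rng.normal(gap_mean, gap_sd, n) if gap_sd > 0 else np.full(n, gap_mean)
    gaps = np.maximum(gaps, 200.0)  # no two endpoints closer than 200 ms
    return start_ms + np.cumsum(gaps)


def generate_events(
    rpeaks: RPeakTrain,
    n_events: int,
    config: SimulationConfig,
    seed: int | None = None,
    rng=None,
) -> tuple[np.ndarray, GroundTruth]:
    """Generate movement-endpoint times against one R-peak train.

    Candidate endpoints are paced by the movement-time process (mean
    ``movement_time_mean``, sd ``movement_time_within_sd``) and then placed
    according to ``config.coupling_mode``. Under ``time_suppression`` fewer
    than ``n_events`` endpoints may survive thinning. Returns the kept event
    times and the :class:`GroundTruth` record.
    """
    if len(rpeaks) < 2:
        raise EmptyTrainError("R-peak train must contain at least 2 peaks")
    if n_events < 1:
        raise InvalidParameterError("n_events must be >= 1")
    r = _rng(seed, rng)
    targets = _paced_targets(
        rpeaks.times[0] + LEAD_IN_MS, n_events, config.movement_time_mean,
        config.movement_time_within_sd, r,
    )
    t, phases, _ = _place_events(rpeaks.times, targets, config, r)
    truth = GroundTruth(rpeaks.times, t, phases, config)
    return t, truth


def synthesize_ecg(
    rpeaks: RPeakTrain,
    fs: float = 1000.0,
    noise_sd: float = 0.0,
    drift_slope: float = 0.0,
    seed: int | None = None,
    rng=None,
    template_width_ms: float = 20.0,
) -> ECGRecording:
    """Single-lead synthetic ECG: a narrow unit-amplitude QRS-like bump per beat.

    The template is a raised-cosine (Hann) pulse of ``template_width_ms``
    total width whose maximum sample coincides with the R-peak time to the
    nearest sample; Gaussian noise (``noise_sd``) and a linear drift
    (``drift_slope`` volts/second) are added on top. Peak signal-to-noise is
    therefore 1/``noise_sd``.
    """
    if fs < 250:
        raise InvalidParameterError("fs must be >= 250 Hz")
    rtimes = rpeaks.times
    if rtimes.size >= 2 and np.min(np.diff(rtimes)) < template_width_ms:
        raise InvalidParameterError("R-R interval shorter than the QRS template width")
    r = _rng(seed, rng)
    t_start = float(rtimes[0] - 100)
    t_end = float(rtimes[-1] + 100)
    n = int(round((t_end - t_start) / 1000.0 * fs)) + 1
    x = np.zeros(n)
    half = max(1, int(round(template_width_ms / 2.0 * fs / 1000.0)))
    k = np.arange(-half, half + 1)
    template = 0.5 * (1.0 + np.cos(np.pi * k / half))
    centers = np.asarray(np.round((rtimes - t_start) * fs / 1000.0), dtype=np.int64)
    for c in centers:
        lo, hi = c - half, c + half + 1
        s = slice(max(lo, 0), min(hi, n))
        x[s] += template[(s.start - lo) : (s.stop - lo)]
    if drift_slope:
        x = x + drift_slope * (np.arange(n) / fs)
    if noise_sd:
        x = x + r.normal(0.0, noise_sd, n)
    return ECGRecording(x, fs, t0=t_start)


def synthesize_three_lead(
    rpeaks: RPeakTrain,
    fs: float = 1000.0,
    noise_sd: float = 0.0,
    drift_slope: float = 0.0,
    seed: int | None = None,
    rng=None,
) -> ECGRecording:
    """Three-electrode recording whose bipolar combination recovers the ECG.

    Channel 1 is the shared reference (independent noise only); channels 2
    and 3 carry the cardiac signal, the drift, and their own noise. After
    :func:`bipolar_combine` the residual noise standard deviation is
    ``noise_sd * sqrt(1.5)``.
    """
    r = _rng(seed, rng)
    clean = synthesize_ecg(rpeaks, fs=fs, noise_sd=0.0, drift_slope=0.0, rng=r)
    n = clean.n_samples
    drift = drift_slope * (np.arange(n) / fs)
    common = 0.3  # common-mode offset, cancels in the bipolar combination
    ch1 = common + r.normal(0.0, noise_sd, n) if noise_sd else np.full(n, common)
    sig = clean.data + drift
    ch2 = common + sig + (r.normal(0.0, noise_sd, n) if noise_sd else 0.0)
    ch3 = common + sig + (r.normal(0.0, noise_sd, n) if noise_sd else 0.0)
    return ECGRecording(np.stack([ch1, ch2, ch3], axis=1), fs, t0=clean.t0)


def generate_dyad_dataset(config: SimulationConfig, seed: int | None = None) -> DyadDataset:
    """Simulate a full cohort of dyads.

    Per dyad: the two subjects' mean inter-endpoint intervals are drawn from
    a bivariate normal with correlation ``movement_time_corr``; the executing
    role alternates by block (so each subject executes exactly half of the
    blocks); the executor's endpoints are placed against the executor's own
    R-peak train per the coupling mode and mirrored to the partner as
    observation events. Seeding fans out deterministically from the master
    seed by (dyad, subject) offsets, so the same seed reproduces the dataset
    byte for byte.
    """
    if seed is None:
        seed = config.seed
    cfg = config
    all_events: list[tuple] = []
    all_truth: list[tuple] = []
    mt_rows: list[tuple] = []
    rpeaks: dict = {}

    for d in range(cfg.n_dyads):
        rng_d = np.random.default_rng(np.random.SeedSequence([int(seed), 2 * d]))
        s_ids = (2 * d, 2 * d + 1)
        cov = (cfg.movement_time_sd ** 2) * np.array(
            [[1.0, cfg.movement_time_corr], [cfg.movement_time_corr, 1.0]]
        )
        m = rng_d.multivariate_normal(
            [cfg.movement_time_mean] * 2, cov, check_valid="ignore"
        )
        m = np.maximum(m, 300.0)
        for s, mi in zip(s_ids, m):
            mt_rows.append((d, s, float(mi)))

        # pace all trials on a shared timeline; executor alternates by block
        trials: list[tuple[int, int, int, np.ndarray]] = []  # (block, trial, executor, targets)
        cursor = LEAD_IN_MS
        for b in range(cfg.blocks_per_dyad):
            executor = s_ids[b % 2]
            me = m[b % 2]
            for t_i in range(cfg.trials_per_block):
                targets = _paced_targets(
                    cursor, cfg.events_per_trial, me, cfg.movement_time_within_sd, rng_d
                )
                trials.append((b, t_i, executor, targets))
                cursor = targets[-1] + INTER_TRIAL_GAP_MS
            cursor += INTER_BLOCK_GAP_MS - INTER_TRIAL_GAP_MS
        span = cursor + LEAD_IN_MS

        for j, s in enumerate(s_ids):
            rng_s = np.random.default_rng(np.random.SeedSequence([int(seed), 2 * d, j]))
            rpeaks[s] = RPeakTrain(
                _rr_times_spanning(span, cfg.mean_rr, cfg.sd_rr, rng_s), subject=s
            )

        for b, t_i, executor, targets in trials:
            partner = s_ids[1 - s_ids.index(executor)]
            times, phases, _ = _place_events(rpeaks[executor].times, targets, cfg, rng_d)
            for tt, ph in zip(times, phases):
                all_events.append((d, executor, b, t_i, "execution", int(tt)))
                all_events.append((d, partner, b, t_i, "observation", int(tt)))
                all_truth.append((d, executor, b, t_i, int(tt), float(ph)))

    events = pd.DataFrame(
        all_events,
        columns=["dyad_id", "subject_id", "block", "trial", "role", "event_time_ms"],
    )
    truth = pd.DataFrame(
        all_truth,
        columns=["dyad_id", "subject_id", "block", "trial", "event_time_ms", "true_phase_deg"],
    )
    movement_times = pd.DataFrame(mt_rows, columns=["dyad_id", "subject_id", "true_mean_gap_ms"])
    return DyadDataset(
        config=cfg, rpeaks=rpeaks, events=events, truth=truth, movement_times=movement_times
    )


def generate_cohort(
    n_subjects: int,
    config: SimulationConfig,
    seed: int | None = None,
    n_paired: int = 14,
) -> tuple[DyadDataset, list[int]]:
    """Simulate a mixed analysis cohort of ``n_subjects``.

    The emulated study's cohort was not all mutual pairs: most dyads joined
    one analyzed subject with an unanalyzed partner (an experimenter), and
    only ``n_paired`` analyzed subjects sat in dyads whose *both* members
    were analyzed. The distinction matters because dyad partners share the
    physical movement events, which couples their alignment statistics; a
    cohort of exclusively mutual pairs would overstate that dependence.

    Returns the dataset and the list of analyzed subject ids.
    """
    n_paired = min(n_paired, n_subjects)
    n_paired -= n_paired % 2
    n_pair_dyads = n_paired // 2
    n_solo_dyads = n_subjects - n_paired
    ds = generate_dyad_dataset(
        replace(config, n_dyads=n_pair_dyads + n_solo_dyads), seed=seed
    )
    subjects = [2 * d + j for d in range(n_pair_dyads) for j in (0, 1)]
    subjects += [2 * d for d in range(n_pair_dyads, n_pair_dyads + n_solo_dyads)]
    return ds, subjects
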