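"""Time-domain analysis: R-peak-locked window assignment of movement endpoints.

Each endpoint is assigned to one of four 200-ms windows defined relative to
the nearest heartbeat: -100..100 ms (centered on the R-peak itself), 100..300,
300..500 and 500..700 ms after the R-peak. Because the first window straddles
the R-peak, an endpoint falling within 100 ms *before* the next beat is
re-referenced to that beat and counts as window 0; this re-referencing takes
precedence over window 600 when an R-R interval is short enough for the two
to overlap, so the assignment is single-valued. Endpoints whose latency falls
in the residual band [700, RR-100) belong to no window and stay unassigned.

Intervals are half-open with the lower edge included (latency 100 ms falls in
the 200-ms window). By default proportions are computed against *all* of a
subject's endpoints (assigned + unassigned + QC-excluded); a denominator over
assigned events only is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .ecg import QCReport, RPeakTrain
from .errors import InvalidParameterError

__all__ = [
    "WINDOW_CENTERS",
    "UNASSIGNED",
    "EXCLUDED",
    "TimeWindowSummary",
    "assign_window",
    "assign_windows",
    "window_proportions",
    "condition_table",
]

WINDOW_CENTERS = (0, 200, 400, 600)
UNASSIGNED = -1
EXCLUDED = -2


@dataclass
class TimeWindowSummary:
    """Per subject x condition proportions of endpoints in the four windows."""

    subject: Any
    condition: str
    proportions: np.ndarray  # aligned with WINDOW_CENTERS
    n_assigned: int
    n_total: int

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (4,):
            raise InvalidParameterError("proportions must have length 4")


def _flagged_mask(events: np.ndarray, idx: np.ndarray, qc: QCReport | None) -> np.ndarray:
    if qc is None or not qc.flagged_intervals:
        return np.zeros(events.size, dtype=bool)
    flagged = qc.flagged_indices
    return np.isin(idx, flagged)


def assign_windows(
    events_ms: np.ndarray, train: RPeakTrain, qc: QCReport | None = None
) -> np.ndarray:
    """Vectorized window assignment.

    Returns an int array aligned with ``events_ms``: a window center
    (0/200/400/600), ``UNASSIGNED`` (-1) for the residual band, or
    ``EXCLUDED`` (-2) for endpoints inside a QC-flagged interval. Endpoints
    outside the train's span raise.
    """
    events = np.asarray(events_ms, dtype=np.int64)
    rt = train.times
    if rt.size < 2:
        raise InvalidParameterError("R-peak train must contain at least 2 peaks")
    if events.size and (events.min() < rt[0] or events.max() > rt[-1]):
        raise InvalidParameterError("event outside the span of the R-peak train")
    idx = np.clip(np.searchsorted(rt, events, side="right") - 1, 0, rt.size - 2)
    lam = (events - rt[idx]).astype(float)
    rr = (rt[idx + 1] - rt[idx]).astype(float)

    out = np.full(events.size, UNASSIGNED, dtype=np.int64)
    # precedence: within 100 ms of the *next* peak -> re-reference, window 0
    renext = lam >= rr - 100.0
    out[renext] = 0
    free = ~renext
    out[free & (lam < 100.0)] = 0
    out[free & (lam >= 100.0) & (lam < 300.0)] = 200
    out[free & (lam >= 300.0) & (lam < 500.0)] = 400
    out[free & (lam >= 500.0) & (lam < 700.0)] = 600
    out[_flagged_mask(events, idx, qc)] = EXCLUDED
    return out


def assign_window(event_ms: float, train: RPeakTrain, qc: QCReport | None = None):
    """Scalar convenience wrapper; returns a window center or None (unassigned).

    Raises on events outside the train span; QC-excluded events return None
    as well (they contribute to totals but never to a window).
    """
    code = int(assign_windows(np.asarray([event_ms]), train, qc)[0])
    return None if code in (UNASSIGNED, EXCLUDED) else code


def window_proportions(
    events_ms: np.ndarray,
    train: RPeakTrain,
    qc: QCReport | None = None,
    subject: Any = None,
    condition: str = "",
    denominator: str = "total",
) -> TimeWindowSummary:
    """Proportion of a subject's endpoints in each of the four windows.

    ``denominator='total'`` divides by all endpoints (the default reading of
    a "proportion of motor events"); ``'assigned'`` renormalizes over the
    endpoints that landed in some window.
    """
    events = np.asarray(events_ms)
    if events.size == 0:
        raise InvalidParameterError("window_proportions requires at least one event")
    if denominator not in ("total", "assigned"):
        raise InvalidParameterError("denominator must be 'total' or 'assigned'")
    codes = assign_windows(events, train, qc)
    counts = np.array([(codes == c).sum() for c in WINDOW_CENTERS], dtype=float)
    n_assigned = int(counts.sum())
    n_total = int(events.size)
    denom = n_total if denominator == "total" else max(n_assigned, 1)
    return TimeWindowSummary(
        subject=subject,
        condition=condition,
        proportions=counts / denom,
        n_assigned=n_assigned,
        n_total=n_total,
    )


def condition_table(summaries: Iterable[TimeWindowSummary]) -> pd.DataFrame:
    """Long-format table (subject, condition, window_center_ms, proportion).

    Every subject must contribute both an execution and an observation
    summary; the error lists offending subjects.
    """
    rows = []
    for s in summaries:
        for center, p in zip(WINDOW_CENTERS, s.proportions):
            rows.append((s.subject, s.condition, center, float(p)))
    table = pd.DataFrame(rows, columns=["subject", "condition", "window_center_ms", "proportion"])
    if table.empty:
        raise InvalidParameterError("no summaries supplied")
    have = table.groupby("subject")["condition"].agg(lambda c: frozenset(c))
    needed = frozenset({"execution", "observation"})
    bad = sorted(str(s) for s, conds in have.items() if conds != needed)
    if bad:
        raise InvalidParameterError(
            "subjects missing a condition (need both execution and observation): "
            + ", ".join(bad)
        )
    return table.sort_values(["subject", "condition", "window_center_ms"]).reset_index(drop=True)
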