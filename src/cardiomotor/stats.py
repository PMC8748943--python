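"""Group-level inference: paired comparisons, correlations, and the
Condition x Time repeated-measures ANOVA with Greenhouse-Geisser correction.

The ANOVA is the classical fully-within two-factor decomposition: each effect
is tested against its own effect-by-subject interaction term. Sphericity is
handled with the Greenhouse-Geisser epsilon computed from the covariance of
the orthonormally contrast-transformed subject data; corrected (possibly
fractional) degrees of freedom and the corrected p-value are reported for
every effect with more than one numerator degree of freedom, alongside the
uncorrected results. Post-hoc paired t-tests between time windows use a
paired Cohen's d (mean difference over the SD of the differences) and
Bonferroni correction with a family of the six pairwise contrasts within
each condition (optionally twelve pooled across conditions).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InvalidParameterError

__all__ = [
    "PairedTResult",
    "AnovaResult",
    "PosthocResult",
    "paired_t",
    "pearson",
    "rm_anova",
    "posthoc_windows",
    "gg_epsilon",
]

_EPS_SS = 1e-300  # a sum of squares below this is treated as exactly zero


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    d: float
    degenerate: bool = False  # all differences exactly zero


@dataclass
class AnovaResult:
    effect: str
    df1: float
    df2: float
    F: float
    p: float
    eps: float
    df1_corr: float
    df2_corr: float
    p_corr: float


@dataclass
class PosthocResult:
    condition: str
    window_a: int
    window_b: int
    t: float
    df: int
    d: float
    p_unc: float
    p_bonf: float


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Paired t-test with paired Cohen's d = mean(diff) / sd(diff).

    Identical inputs (every difference exactly zero) return t = 0, p = 1 with
    the ``degenerate`` flag set; a nonzero constant difference (zero variance
    but a real shift) is an error because no t statistic exists for it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("paired_t requires two equal-length 1-d arrays")
    n = x.size
    if n < 3:
        raise InvalidParameterError("paired_t requires n >= 3 pairs")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if np.all(diff == 0.0):
            return PairedTResult(t=0.0, df=n - 1, p=1.0, d=0.0, degenerate=True)
        raise DegenerateDataError("differences have zero variance but nonzero mean")
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return PairedTResult(t=float(t), df=n - 1, p=float(p), d=float(diff.mean() / sd))


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InvalidParameterError("pearson requires two equal-length 1-d arrays, n >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        raise DegenerateDataError("pearson is undefined for a constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1, k) orthonormal contrasts spanning the space orthogonal to the mean."""
    basis = np.vstack([np.ones(k), np.eye(k)[: k - 1]]).T
    q, _ = np.linalg.qr(basis)
    return q[:, 1:].T


def gg_epsilon(d: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from an (n_subjects, k) effect-score matrix.

    Epsilon is tr(M)^2 / ((k-1) tr(M^2)) where M is the covariance of the
    orthonormally contrast-transformed scores; it lies in [1/(k-1), 1].
    """
    d = np.asarray(d, dtype=float)
    k = d.shape[1]
    if k < 2:
        return 1.0
    c = _orthonormal_contrasts(k)
    m = c @ np.cov(d.T) @ c.T
    tr = np.trace(m)
    denom = (k - 1) * np.sum(m * m)
    if denom <= _EPS_SS:
        return 1.0
    return float(np.clip(tr * tr / denom, 1.0 / (k - 1), 1.0))


def _contrast_epsilon(cells: np.ndarray, contrasts: np.ndarray) -> float:
    """Epsilon from an (n, k) cell matrix and a (df, k) orthonormal contrast set."""
    m = contrasts @ np.cov(cells.T) @ contrasts.T
    df = contrasts.shape[0]
    denom = df * np.sum(m * m)
    if denom <= _EPS_SS:
        return 1.0
    return float(np.clip(np.trace(m) ** 2 / denom, 1.0 / df, 1.0))


def _effect_result(name: str, ss_eff: float, ss_err: float, df1: int, df2: int,
                   eps: float) -> AnovaResult:
    if ss_eff <= _EPS_SS:
        return AnovaResult(name, df1, df2, 0.0, 1.0, 1.0, float(df1), float(df2), 1.0)
    if ss_err <= _EPS_SS:
        raise DegenerateDataError(
            f"error term for effect {name!r} is zero; F is undefined"
        )
    f = (ss_eff / df1) / (ss_err / df2)
    p = float(sps.f.sf(f, df1, df2))
    d1c, d2c = eps * df1, eps * df2
    p_corr = float(sps.f.sf(f, d1c, d2c))
    return AnovaResult(name, df1, df2, float(f), p, eps, d1c, d2c, p_corr)


def rm_anova(
    table: pd.DataFrame,
    dv: str = "proportion",
    within: tuple[str, str] = ("condition", "window_center_ms"),
    subject: str = "subject",
) -> list[AnovaResult]:
    """Two-way fully within-subject ANOVA on a complete balanced long table.

    Returns results for the two main effects and their interaction, each
    tested against its effect-by-subject term. Greenhouse-Geisser corrected
    degrees of freedom (fractional) and p-values accompany every effect with
    more than one numerator df.
    """
    fa, fb = within
    for col in (dv, fa, fb, subject):
        if col not in table.columns:
            raise InvalidParameterError(f"table lacks required column {col!r}")
    pivot = table.pivot_table(index=subject, columns=[fa, fb], values=dv, aggfunc="mean")
    if pivot.isna().any().any():
        missing = pivot.columns[pivot.isna().any()].tolist()
        raise InvalidParameterError(f"missing cells in the design: {missing}")
    a_levels = sorted(table[fa].unique())
    b_levels = sorted(table[fb].unique())
    n, a, b = pivot.shape[0], len(a_levels), len(b_levels)
    if n < 2:
        raise InvalidParameterError("rm_anova requires at least 2 subjects")
    expected = a * b
    if pivot.shape[1] != expected:
        raise InvalidParameterError("design is not fully crossed")
    y = pivot.reindex(columns=pd.MultiIndex.from_product([a_levels, b_levels])).to_numpy()
    y = y.reshape(n, a, b)

    g = y.mean()
    mean_a = y.mean(axis=(0, 2))
    mean_b = y.mean(axis=(0, 1))
    mean_s = y.mean(axis=(1, 2))
    mean_ab = y.mean(axis=0)
    mean_as = y.mean(axis=2)
    mean_bs = y.mean(axis=1)

    ss_a = n * b * np.sum((mean_a - g) ** 2)
    ss_b = n * a * np.sum((mean_b - g) ** 2)
    ss_ab = n * np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + g) ** 2)
    ss_as = b * np.sum((mean_as - mean_a[None, :] - mean_s[:, None] + g) ** 2)
    ss_bs = a * np.sum((mean_bs - mean_b[None, :] - mean_s[:, None] + g) ** 2)
    resid = (
        y
        - mean_ab[None, :, :]
        - mean_as[:, :, None]
        - mean_bs[:, None, :]
        + mean_a[None, :, None]
        + mean_b[None, None, :]
        + mean_s[:, None, None]
        - g
    )
    ss_abs = np.sum(resid ** 2)

    # Greenhouse-Geisser epsilons: main effects from the per-subject factor
    # means, the interaction from Kronecker-product contrasts on raw cells
    eps_a = 1.0 if a == 2 else gg_epsilon(mean_as)
    eps_b = 1.0 if b == 2 else gg_epsilon(mean_bs)
    c_int = np.kron(_orthonormal_contrasts(a), _orthonormal_contrasts(b))
    eps_ab = 1.0 if (a - 1) * (b - 1) == 1 else _contrast_epsilon(y.reshape(n, a * b), c_int)
    results = [
        _effect_result(fa, ss_a, ss_as, a - 1, (a - 1) * (n - 1), eps_a),
        _effect_result(fb, ss_b, ss_bs, b - 1, (b - 1) * (n - 1), eps_b),
        _effect_result(
            f"{fa} * {fb}", ss_ab, ss_abs, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1),
            eps_ab,
        ),
    ]
    return results


def posthoc_windows(
    table: pd.DataFrame,
    dv: str = "proportion",
    condition_col: str = "condition",
    window_col: str = "window_center_ms",
    subject: str = "subject",
    family: str = "per_condition",
) -> list[PosthocResult]:
    """All pairwise paired t-tests between windows, within each condition.

    The contrast window_a vs window_b (a < b by center) uses differences
    a - b, so a deficit in the earlier window yields negative t and d.
    Bonferroni family is 6 per condition (``family='per_condition'``) or 12
    pooled (``family='pooled'``).
    """
    if family not in ("per_condition", "pooled"):
        raise InvalidParameterError("family must be 'per_condition' or 'pooled'")
    conditions = sorted(table[condition_col].unique())
    windows = sorted(table[window_col].unique())
    pairs = list(combinations(windows, 2))
    m = len(pairs) * (len(conditions) if family == "pooled" else 1)
    out: list[PosthocResult] = []
    for cond in conditions:
        sub = table[table[condition_col] == cond].pivot_table(
            index=subject, columns=window_col, values=dv, aggfunc="mean"
        )
        for wa, wb in pairs:
            res = paired_t(sub[wa].to_numpy(), sub[wb].to_numpy())
            out.append(
                PosthocResult(
                    condition=str(cond),
                    window_a=int(wa),
                    window_b=int(wb),
                    t=res.t,
                    df=res.df,
                    d=res.d,
                    p_unc=res.p,
                    p_bonf=float(min(1.0, m * res.p)),
                )
            )
    return out
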