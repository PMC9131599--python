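"""Normality screening and one-way repeated-measures ANOVA with partial eta^2.

The COI of each muscle pair is compared across the four feedback conditions
with a one-way within-subject (repeated-measures) ANOVA on the balanced
participants x conditions table:

    SS_total = SS_subjects + SS_conditions + SS_error
    F = (SS_cond / (k-1)) / (SS_err / ((n-1)(k-1)))
    partial eta^2 = SS_cond / (SS_cond + SS_err)

The sphericity-assumed p-value is primary; the Greenhouse-Geisser epsilon
and corrected p are always computed alongside.  Samples are screened with
the Shapiro-Wilk test beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class RmAnovaResult:
    f_value: float
    df_effect: int
    df_error: int
    p_value: float
    partial_eta_sq: float
    gg_epsilon: float
    p_value_gg: float
    ss_conditions: float
    ss_subjects: float
    ss_error: float
    ss_total: float

    def __post_init__(self) -> None:
        if self.f_value < 0 or not (0 <= self.partial_eta_sq <= 1):
            raise ValueError("invalid RM-ANOVA result")


def shapiro_wilk(x: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value for a sample (3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("W is undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _gg_epsilon(table: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centered covariance."""
    k = table.shape[1]
    s = np.cov(table, rowvar=False)
    s_dc = (s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True)
            + s.mean())
    num = np.trace(s_dc) ** 2
    den = (k - 1) * np.sum(s_dc ** 2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova(table: np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a participants x conditions table.

    The table must be complete and balanced (no missing cells; no
    imputation).  Returns the sphericity-assumed F and p, partial eta^2, the
    Greenhouse-Geisser epsilon and the GG-corrected p.
    """
    y = np.asarray(table, dtype=float)
    if y.ndim != 2:
        raise ValueError("table must be 2-D (participants x conditions)")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 participants and >= 2 conditions, got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("missing or non-finite cells; no imputation is done")

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_subj = float(k * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_cond = float(n * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_err = max(ss_total - ss_subj - ss_cond, 0.0)

    df_e = k - 1
    df_err = (n - 1) * (k - 1)
    if ss_cond == 0.0:
        f = 0.0
        p = 1.0
        peta = 0.0
    elif ss_err == 0.0:
        f = np.inf
        p = 0.0
        peta = 1.0
    else:
        f = (ss_cond / df_e) / (ss_err / df_err)
        p = float(sps.f.sf(f, df_e, df_err))
        peta = ss_cond / (ss_cond + ss_err)

    eps = _gg_epsilon(y)
    if np.isfinite(f) and f > 0:
        p_gg = float(sps.f.sf(f, eps * df_e, eps * df_err))
    else:
        p_gg = p
    return RmAnovaResult(f_value=float(f), df_effect=df_e, df_error=df_err,
                         p_value=p, partial_eta_sq=float(peta),
                         gg_epsilon=eps, p_value_gg=p_gg,
                         ss_conditions=ss_cond, ss_subjects=ss_subj,
                         ss_error=ss_err, ss_total=ss_total)
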