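"""Group-level statistics: classical pooled-variance t-test and the
D'Agostino–Pearson K² normality test, computed from their moment formulas.

The statistical unit is the cell (one imaging session), not the event.
No multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = ["GroupComparison", "compare_groups", "dagostino_pearson"]


@dataclass
class GroupComparison:
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    df: float
    p_value: float
    significant: bool
    normality_p_a: float | None = None
    normality_p_b: float | None = None
    welch: bool = False
    degenerate: bool = False


def dagostino_pearson(x: np.ndarray) -> tuple[float, float]:
    """D'Agostino–Pearson K² omnibus normality test.

    Combines the transformed sample skewness (D'Agostino 1970) and
    kurtosis (Anscombe & Glynn 1983) Z scores; K² = Z1² + Z2² is referred
    to a chi-squared distribution with 2 df.  Requires n >= 8.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 8:
        raise ValueError("normality test requires n >= 8")
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    m3 = np.mean((x - m) ** 3)
    m4 = np.mean((x - m) ** 4)
    g1 = m3 / m2**1.5
    g2 = m4 / m2**2 - 3.0

    # skewness transform
    y = g1 * np.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = 3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / (
        (n - 2.0) * (n + 5) * (n + 7) * (n + 9)
    )
    w2 = -1.0 + np.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / np.sqrt(0.5 * np.log(w2))
    alpha = np.sqrt(2.0 / (w2 - 1.0))
    y = np.where(y == 0, 1e-30, y)
    z1 = delta * np.log(y / alpha + np.sqrt((y / alpha) ** 2 + 1.0))

    # kurtosis transform
    e_g2 = -6.0 / (n + 1)
    var_g2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1.0) ** 2 * (n + 3) * (n + 5))
    xg = (g2 - e_g2) / np.sqrt(var_g2)
    sqrt_b1 = 6.0 * (n**2 - 5 * n + 2) / ((n + 7.0) * (n + 9)) * np.sqrt(
        6.0 * (n + 3) * (n + 5) / (n * (n - 2.0) * (n - 3))
    )
    a = 6.0 + 8.0 / sqrt_b1 * (2.0 / sqrt_b1 + np.sqrt(1.0 + 4.0 / sqrt_b1**2))
    denom = 1.0 + xg * np.sqrt(2.0 / (a - 4.0))
    denom = np.where(denom <= 0, 1e-30, denom)
    z2 = ((1.0 - 2.0 / (9.0 * a)) - ((1.0 - 2.0 / a) / denom) ** (1.0 / 3.0)) / np.sqrt(
        2.0 / (9.0 * a)
    )

    k2 = float(z1**2 + z2**2)
    p = float(sstats.chi2.sf(k2, df=2))
    return k2, p


def compare_groups(
    values_a,
    values_b,
    welch: bool = False,
    alpha: float = 0.05,
) -> GroupComparison:
    """Unpaired two-tailed t-test between two groups of per-cell values.

    Classical pooled-variance Student's t by default (Welch via flag),
    computed from the textbook formulas.  D'Agostino–Pearson normality is
    reported per group when n >= 8, otherwise skipped with a warning.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 values per group")
    m1, m2 = a.mean(), b.mean()
    v1 = a.var(ddof=1)
    v2 = b.var(ddof=1)

    degenerate = False
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0:
            degenerate = True
            t = 0.0 if m1 == m2 else np.inf * np.sign(m1 - m2)
            df = n1 + n2 - 2.0
        else:
            t = (m1 - m2) / np.sqrt(se2)
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        df = n1 + n2 - 2.0
        if sp2 == 0:
            degenerate = True
            t = 0.0 if m1 == m2 else np.inf * np.sign(m1 - m2)
        else:
            t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))

    if degenerate:
        p = 1.0 if m1 == m2 else 0.0
        warnings.warn("zero pooled variance; degenerate t-test", stacklevel=2)
    else:
        p = float(2.0 * sstats.t.sf(abs(t), df))

    def norm_p(x: np.ndarray) -> float | None:
        if x.size >= 8:
            return dagostino_pearson(x)[1]
        warnings.warn("normality test skipped (n < 8)", stacklevel=3)
        return None

    return GroupComparison(
        n_a=n1, n_b=n2, mean_a=float(m1), mean_b=float(m2),
        t_statistic=float(t), df=float(df), p_value=float(p),
        significant=bool(p < alpha),
        normality_p_a=norm_p(a), normality_p_b=norm_p(b),
        welch=welch, degenerate=degenerate,
    )
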